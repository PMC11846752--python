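"""Sampling plans, load-case plumbing, model persistence and configuration.

The training design is the tensor grid the study prescribes (three
equidistant points per pose dimension, endpoints included, lexicographic
column order); test sets are seeded pseudorandom uniform samples within the
same bounds.  Surrogate models persist to a single HDF5 container with a
version tag, an integrity checksum and a provenance record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List
import hashlib
import json

import numpy as np

from .geometry import SimplexMesh, DomainSpec
from .morphing import build_morph_operator
from .remodelling import LoadCase, MaterialParams, RemodellingConfig
from .surrogate import PODRBFSurrogate, SurrogateConfig

__all__ = [
    "SamplingPlan",
    "sample_training_grid",
    "sample_test_set",
    "plate_load_case",
    "initial_density_field",
    "save_model",
    "load_model",
    "load_config",
]

_CONTAINER_VERSION = 1
_MAX_GRID = 100_000


@dataclass
class SamplingPlan:
    """Design of the pose-parameter samples.

    ``mode='grid'``: full tensor product with ``points_per_dim`` equidistant
    points per dimension (endpoints included; a single point sits at the
    interval midpoint).  ``mode='pseudorandom'``: ``n_samples`` uniform
    i.i.d. draws reproducible from ``seed``.
    """

    bounds: Dict[str, tuple]
    mode: str = "grid"
    points_per_dim: int = 3
    n_samples: int = 20
    seed: int = 0

    def __post_init__(self):
        for k, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"bounds for {k} must be finite")
            if hi < lo:
                raise ValueError(f"bounds for {k} are reversed")
        if self.mode == "grid" and self.points_per_dim < 1:
            raise ValueError("need at least 1 grid point per dimension")

    @property
    def param_names(self) -> List[str]:
        return list(self.bounds)

    def bounds_array(self) -> np.ndarray:
        return np.array([self.bounds[k] for k in self.bounds], dtype=float)


def sample_training_grid(plan: SamplingPlan) -> np.ndarray:
    """Full tensor training grid as an (n_p, n_s) column matrix.

    Columns are in lexicographic order (last dimension varies fastest);
    three points per dimension over six pose parameters yields 3^6 = 729
    columns.
    """
    if plan.mode != "grid":
        raise ValueError("plan is not in grid mode")
    b = plan.bounds_array()
    axes = []
    for lo, hi in b:
        if plan.points_per_dim == 1:
            axes.append(np.array([(lo + hi) / 2.0]))
        else:
            if hi == lo:
                raise ValueError(
                    "zero-size bounds with more than one grid point: "
                    "degenerate parameter dimension")
            axes.append(np.linspace(lo, hi, plan.points_per_dim))
    count = int(np.prod([len(a) for a in axes]))
    if count > _MAX_GRID:
        raise ValueError(f"grid of {count} poses exceeds the safety limit")
    grids = np.meshgrid(*axes, indexing="ij")
    return np.vstack([g.ravel() for g in grids])


def sample_test_set(plan: SamplingPlan, training: np.ndarray | None = None
                    ) -> np.ndarray:
    """Seeded uniform pseudorandom poses, (n_p, n) columns.

    Any draw coinciding with a training column (exact match) is resampled.
    """
    if plan.mode != "pseudorandom":
        raise ValueError("plan is not in pseudorandom mode")
    rng = np.random.default_rng(plan.seed)
    b = plan.bounds_array()
    cols = []
    train_set = set()
    if training is not None:
        train_set = {tuple(training[:, j]) for j in range(training.shape[1])}
    while len(cols) < plan.n_samples:
        draw = rng.uniform(b[:, 0], b[:, 1])
        if tuple(draw) in train_set:
            continue
        cols.append(draw)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# synthetic campaign plumbing


def plate_load_case(mesh: SimplexMesh, traction=(0.0, -5.0)) -> LoadCase:
    """Default load case for the synthetic plate: compressive traction on the
    top edge, roller support (zero normal displacement) along the bottom with
    one central node pinned laterally.

    The roller avoids the corner stress singularities of a full clamp.  The
    joint load is identical for every pose; with the morphing approach it
    applies directly to the morphed mesh (the loaded facets never move).
    """
    tol = 1e-9
    vert = mesh.dim - 1  # vertical axis: y in 2D, z in 3D
    v_max = mesh.nodes[:, vert].max()
    x_mid = 0.5 * (mesh.nodes[:, 0].min() + mesh.nodes[:, 0].max())
    bottom = np.flatnonzero(mesh.nodes[:, vert] < tol)
    pin = bottom[np.argmin(np.abs(mesh.nodes[bottom, 0] - x_mid))]
    facets = mesh.boundary_facets()
    top = facets[np.all(mesh.nodes[facets][:, :, vert] > v_max - tol, axis=1)]
    dirichlet = [(bottom, mesh.dim - 1, 0.0), (np.array([pin]), 0, 0.0)]
    if mesh.dim == 3:
        # pin a second bottom node against rotation about the vertical axis
        far = bottom[np.argmax(mesh.nodes[bottom, 0])]
        dirichlet += [(np.array([pin]), 1, 0.0), (np.array([far]), 1, 0.0)]
    t = np.zeros(mesh.dim)
    t[: len(traction)] = traction[: mesh.dim]
    return LoadCase(dirichlet=dirichlet, tractions=[(top, t)])


def initial_density_field(mesh: SimplexMesh, rho_surface: float = 1.4,
                          rho_core: float = 0.8, decay: float = 2.5
                          ) -> np.ndarray:
    """Heterogeneous initial BMD, dense near the outer boundary (a
    cortical-shell analogue) decaying smoothly to a trabecular core value.

    Returns per-element densities; implant elements carry ``rho_core`` as a
    placeholder (their density is frozen and never enters the elasticity).
    """
    centroids = mesh.nodes[mesh.elements].mean(axis=1)
    ext = np.array([mesh.nodes[:, k].max() for k in range(mesh.dim)])
    dist = np.minimum(centroids, ext - centroids).min(axis=1)
    rho = rho_core + (rho_surface - rho_core) * np.exp(-dist / decay)
    rho[mesh.element_material == "implant"] = rho_core
    return rho


# ---------------------------------------------------------------------------
# persistence


def _checksum(arrays: Dict[str, np.ndarray], meta: str) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arrays[name]).tobytes())
    h.update(meta.encode())
    return h.hexdigest()


def save_model(model: PODRBFSurrogate, path) -> None:
    """Persist a fitted campaign surrogate to one HDF5 container.

    Stores the POD basis, the RBF interpolant, the reference mesh and the
    provenance record; the morph operator is rebuilt deterministically from
    the mesh at load time.  The file carries a version tag and a SHA-256
    checksum over all payload arrays.
    """
    import h5py

    mesh = model.mesh_
    node_set_code = np.zeros(mesh.n_nodes, dtype=np.int64)
    for name, code in (("implant", 2), ("fixed_boundary", 1)):
        node_set_code[mesh.node_sets[name]] = code
    arrays = {
        "pod/components": model.pod_.components_,
        "pod/singular_values": model.pod_.singular_values_,
        "rbf/centers": model.interpolant_.centers_,
        "rbf/coef": model.interpolant_.coef_,
        "rbf/bounds": model.interpolant_.bounds_,
        "mesh/nodes": mesh.nodes,
        "mesh/elements": mesh.elements,
        "mesh/node_set_code": node_set_code,
        "mesh/material_code": (mesh.element_material == "implant").astype(np.int64),
    }
    if model.interpolant_.poly_coef_ is not None:
        arrays["rbf/poly_coef"] = model.interpolant_.poly_coef_
    provenance = dict(model.provenance_)
    if not provenance:
        raise ValueError("refusing to save a model without provenance")
    meta = json.dumps(
        {
            "version": _CONTAINER_VERSION,
            "params": model.get_params(),
            "provenance": provenance,
            "n_modes": int(model.n_modes_),
            "dim": int(model.dim_),
        },
        sort_keys=True, default=_json_default,
    )
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["meta"] = meta
        f.attrs["checksum"] = _checksum(arrays, meta)
        for name, arr in arrays.items():
            f.create_dataset(name, data=np.asarray(arr), track_times=False)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_model(path) -> PODRBFSurrogate:
    """Load a container written by :func:`save_model`, verifying version,
    checksum and structural invariants."""
    import h5py

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"unreadable model container {path}: {exc}") from None
    with f:
        meta = f.attrs["meta"]
        arrays = {}

        def collect(name, obj):
            if isinstance(obj, h5py.Dataset):
                arrays[name] = obj[()]

        f.visititems(collect)
        if f.attrs["checksum"] != _checksum(arrays, meta):
            raise ValueError("model container checksum mismatch (corrupt file)")
    info = json.loads(meta)
    if info["version"] != _CONTAINER_VERSION:
        raise ValueError(
            f"container version {info['version']} != {_CONTAINER_VERSION}")

    from .pod import PODReducer
    from .rbf import RBFInterpolant

    params = info["params"]
    if params.get("bounds") is not None:
        params["bounds"] = np.asarray(params["bounds"], float)
    model = PODRBFSurrogate(**params)
    pod = PODReducer(energy_tol=params["energy_tol"])
    pod.components_ = arrays["pod/components"]
    pod.singular_values_ = arrays["pod/singular_values"]
    pod.n_modes_ = pod.components_.shape[0]
    pod.n_features_in_ = pod.components_.shape[1]
    interp = RBFInterpolant(kernel=params["kernel"], shape=params["shape"],
                            augment=params["augment"])
    interp.centers_ = arrays["rbf/centers"]
    interp.coef_ = arrays["rbf/coef"]
    interp.bounds_ = arrays["rbf/bounds"]
    interp.poly_coef_ = arrays.get("rbf/poly_coef")
    interp.n_features_in_ = interp.centers_.shape[1]
    code = arrays["mesh/node_set_code"]
    mesh = SimplexMesh(
        nodes=arrays["mesh/nodes"],
        elements=arrays["mesh/elements"],
        node_sets={
            "interior": np.flatnonzero(code == 0).astype(np.int64),
            "fixed_boundary": np.flatnonzero(code == 1).astype(np.int64),
            "implant": np.flatnonzero(code == 2).astype(np.int64),
        },
        element_material=np.where(arrays["mesh/material_code"] == 1,
                                  "implant", "bone").astype("U7"),
    )
    mesh.validate()
    model.pod_ = pod
    model.interpolant_ = interp
    model.n_modes_ = info["n_modes"]
    model.dim_ = info["dim"]
    model.n_features_in_ = interp.n_features_in_
    model.mesh_ = mesh
    model.morph_operator_ = build_morph_operator(mesh)
    model.provenance_ = info["provenance"]
    model.param_names_ = model.provenance_.get("param_names")
    if not model.provenance_:
        raise ValueError("container provenance record is empty")
    if pod.components_.shape[1] != mesh.n_nodes:
        raise ValueError("basis row dimension does not match mesh node count")
    return model


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> dict:
    """Read a YAML configuration covering domain, material, solver, sampling
    and surrogate settings; missing sections fall back to defaults."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    domain = DomainSpec(**raw.get("domain", {}))
    material = MaterialParams(**raw.get("material", {}))
    solver = RemodellingConfig(**raw.get("solver", {}))
    sur = raw.get("surrogate", {})
    config = SurrogateConfig(
        domain=domain, material=material, solver=solver,
        energy_tol=sur.get("energy_tol", 0.9999),
        kernel=sur.get("kernel", "MC0"),
        shape=sur.get("shape", 1e-4),
        augment=sur.get("augment", True),
    )
    sampling = raw.get("sampling", {})
    plan = SamplingPlan(
        bounds={k: tuple(v) for k, v in sampling.get(
            "bounds", domain.pose_bounds).items()},
        mode=sampling.get("mode", "grid"),
        points_per_dim=sampling.get("points_per_dim", 3),
        n_samples=sampling.get("n_samples", 20),
        seed=sampling.get("seed", 0),
    )
    return {"config": config, "plan": plan, "raw": raw}
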