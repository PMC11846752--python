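"""Reference-domain construction and mesh utilities.

The package operates on a parameterised reference simplex mesh (triangles in
2D, linear tetrahedra in 3D) whose node set is partitioned into

* ``fixed_boundary`` -- the outer boundary of the bone domain; these nodes
  never move during morphing,
* ``implant`` -- every node of every implant-labelled element plus a
  one-element-deep interface ring of bone nodes; this set moves rigidly with
  the implant pose,
* ``interior`` -- all remaining nodes, relocated by harmonic extension.

The real patient geometry (a femur with an embedded stem) is not part of the
package; :func:`build_reference_domain` generates a synthetic analogue -- a
rectangular bone plate with a convex polygonal implant inclusion -- that
exercises exactly the same code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence
import warnings

import numpy as np

__all__ = [
    "SimplexMesh",
    "DomainSpec",
    "RegionMap",
    "build_reference_domain",
    "element_volumes",
    "check_mesh_quality",
    "repair_inverted_elements",
    "define_regions",
]


class GeometryError(ValueError):
    """Invalid geometric specification (e.g. implant touching the boundary)."""


class MorphFailureError(RuntimeError):
    """A morphed configuration contains unrepairable inverted elements."""

    def __init__(self, message: str, failing: Sequence[int] = ()):
        super().__init__(message)
        self.failing = list(failing)


@dataclass
class SimplexMesh:
    """Unstructured simplex mesh with labelled node sets.

    Attributes
    ----------
    nodes : (N, d) float array
        Nodal coordinates in mm.
    elements : (M, d+1) int array
        Node-index tuples; positively oriented in the reference configuration.
    node_sets : dict of str -> int array
        Disjoint sets ``fixed_boundary`` / ``implant`` / ``interior``
        partitioning ``range(N)``.
    element_material : (M,) str array
        Per-element label, ``"bone"`` or ``"implant"``.
    """

    nodes: np.ndarray
    elements: np.ndarray
    node_sets: Dict[str, np.ndarray]
    element_material: np.ndarray

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def bone_elements(self) -> np.ndarray:
        return np.flatnonzero(self.element_material == "bone")

    @property
    def implant_elements(self) -> np.ndarray:
        return np.flatnonzero(self.element_material == "implant")

    def copy(self) -> "SimplexMesh":
        return SimplexMesh(
            nodes=self.nodes.copy(),
            elements=self.elements.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            element_material=self.element_material.copy(),
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        n = self.n_nodes
        if self.elements.min() < 0 or self.elements.max() >= n:
            raise ValueError("element indices out of range")
        all_idx = np.concatenate([np.asarray(v) for v in self.node_sets.values()])
        if len(np.unique(all_idx)) != len(all_idx) or len(all_idx) != n:
            raise ValueError("node_sets must partition the node indices")
        if np.any(element_volumes(self) <= 0):
            raise ValueError("reference mesh contains non-positive element volumes")

    def boundary_facets(self) -> np.ndarray:
        """Facets (edges in 2D, triangles in 3D) on the mesh boundary.

        A facet is on the boundary iff it belongs to exactly one element.
        """
        d = self.dim
        m = self.elements.shape[0]
        # all facets: drop one local vertex at a time
        facets = []
        for drop in range(d + 1):
            keep = [i for i in range(d + 1) if i != drop]
            facets.append(self.elements[:, keep])
        facets = np.vstack(facets)  # (M*(d+1), d)
        key = np.sort(facets, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return facets[counts[inv] == 1]


@dataclass
class DomainSpec:
    """Synthetic reference-domain specification.

    A rectangular outer bone domain ``[0, extents[0]] x [0, extents[1]]``
    (times ``extents[2]`` in 3D) with a convex polygonal (2D) or box (3D)
    implant inclusion.  ``element_size`` controls the structured background
    grid; elements whose centroid falls inside the implant polygon are
    labelled ``implant``.

    ``pose_bounds`` maps parameter names (``dx, dy[, dz], alpha[, beta],
    gamma``) to ``(lo, hi)`` tuples; the implant clearance to the outer
    boundary must exceed the largest translation magnitude.
    """

    extents: Sequence[float] = (20.0, 20.0)
    implant_polygon: np.ndarray | None = None  # (k, d) convex vertices, CCW
    element_size: float = 0.625
    pose_bounds: Dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        self.extents = tuple(float(e) for e in self.extents)
        if self.implant_polygon is None:
            if len(self.extents) == 2:
                self.implant_polygon = np.array(
                    [[7.5, 5.0], [12.5, 5.0], [12.5, 15.0], [7.5, 15.0]]
                )
            else:
                self.implant_polygon = np.array([[7.5, 5.0, 7.5], [12.5, 15.0, 12.5]])
        self.implant_polygon = np.asarray(self.implant_polygon, dtype=float)
        if self.implant_polygon.size == 0:
            self.implant_polygon = self.implant_polygon.reshape(0, len(self.extents))
        if not self.pose_bounds:
            names = ("dx", "dy", "gamma") if len(self.extents) == 2 else (
                "dx", "dy", "dz", "alpha", "beta", "gamma")
            self.pose_bounds = {k: (-1.0, 1.0) for k in names}

    @property
    def dim(self) -> int:
        return len(self.extents)

    @property
    def has_implant(self) -> bool:
        return self.implant_polygon.size > 0

    def clearance(self) -> float:
        """Minimum distance from the implant hull to the outer boundary."""
        if not self.has_implant:
            return float("inf")
        poly = self.implant_polygon
        lo = poly.min(axis=0)
        hi = poly.max(axis=0)
        ext = np.asarray(self.extents)
        return float(min(lo.min(), (ext - hi).min()))

    def max_translation(self) -> float:
        t = [max(abs(b[0]), abs(b[1]))
             for k, b in self.pose_bounds.items() if k.startswith("d")]
        return float(np.linalg.norm(t)) if t else 0.0


@dataclass
class RegionMap:
    """Partition of the bone elements into diagnostic zones.

    A synthetic analogue of the periprosthetic Gruen zones: one distal band
    below the implant tip plus equal-height bands along the implant axis,
    split medially/laterally about the implant centre.
    """

    regions: Dict[int, np.ndarray]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def validate(self, mesh: SimplexMesh) -> None:
        all_e = np.concatenate([np.asarray(v) for v in self.regions.values()])
        if len(np.unique(all_e)) != len(all_e):
            raise ValueError("regions overlap")
        if not np.array_equal(np.sort(all_e), mesh.bone_elements):
            raise ValueError("regions do not cover the bone elements")


def element_volumes(mesh: SimplexMesh) -> np.ndarray:
    """Signed simplex volumes (area in 2D), mm^d.

    Computed from the determinant of the edge matrix; positive for
    positively oriented node tuples.
    """
    return _signed_volumes(mesh.nodes, mesh.elements)


def _signed_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    d = nodes.shape[1]
    if np.any(
        np.sort(elements, axis=1)[:, :-1] == np.sort(elements, axis=1)[:, 1:]
    ):
        raise ValueError("degenerate element with repeated node index")
    x = nodes[elements]  # (M, d+1, d)
    edges = x[:, 1:, :] - x[:, :1, :]  # (M, d, d)
    det = np.linalg.det(edges)
    factorial = 2.0 if d == 2 else 6.0
    return det / factorial


def check_mesh_quality(
    mesh: SimplexMesh, tol: float = 0.01, reference: SimplexMesh | None = None
) -> list:
    """Indices of elements whose signed volume dropped below ``tol`` times
    the reference volume.

    With ``tol=0`` only strictly inverted (negative-volume) elements are
    reported.  ``reference`` defaults to the mesh itself (in which case only
    a degenerate reference could fail for tol < 1).
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    vol = element_volumes(mesh)
    ref_vol = element_volumes(reference) if reference is not None else vol
    if tol == 0:
        failing = np.flatnonzero(vol < 0)
    else:
        failing = np.flatnonzero(vol < tol * ref_vol)
    return failing.tolist()


def repair_inverted_elements(mesh: SimplexMesh, failing: Sequence[int]) -> SimplexMesh:
    """Flip the orientation of inverted elements by swapping two node indices.

    Only the listed elements are touched and only if their signed volume is
    negative (a transposition of the last two vertices flips the sign while
    keeping all node positions fixed); non-inverted entries trigger a warning
    and are left unchanged.
    """
    if len(failing) == 0:
        return mesh
    out = mesh.copy()
    vol = element_volumes(mesh)
    for e in failing:
        if vol[e] >= 0:
            warnings.warn(
                f"element {e} is not inverted (volume {vol[e]:.3g}); skipped",
                stacklevel=2,
            )
            continue
        out.elements[e, -2], out.elements[e, -1] = (
            mesh.elements[e, -1],
            mesh.elements[e, -2],
        )
    return out


def _points_in_convex_polygon(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Strict inclusion test for a convex CCW polygon (2D)."""
    inside = np.ones(len(pts), dtype=bool)
    k = len(poly)
    for i in range(k):
        a, b = poly[i], poly[(i + 1) % k]
        cross = (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])
        inside &= cross > 0
    return inside


def build_reference_domain(spec: DomainSpec) -> SimplexMesh:
    """Generate the synthetic reference mesh from a :class:`DomainSpec`.

    A structured grid of squares (cubes) split into 2 triangles (6 tets),
    with elements labelled ``implant`` when their centroid falls inside the
    implant hull.  The implant node set is the union of the implant-element
    nodes and a one-element-deep ring of adjacent bone nodes.
    """
    d = spec.dim
    if spec.clearance() <= 0:
        raise GeometryError("implant intersects or touches the outer boundary")
    if spec.clearance() < spec.max_translation():
        raise GeometryError(
            "implant clearance smaller than the maximum pose translation")
    h = spec.element_size
    ncell = [int(round(e / h)) for e in spec.extents]
    if any(n < 3 for n in ncell):
        raise GeometryError("element size too coarse for the domain")

    if d == 2:
        nodes, elements = _structured_triangles(spec.extents, ncell)
    else:
        nodes, elements = _structured_tets(spec.extents, ncell)

    centroids = nodes[elements].mean(axis=1)
    if not spec.has_implant:
        impl = np.zeros(len(elements), dtype=bool)
    elif d == 2:
        impl = _points_in_convex_polygon(centroids, spec.implant_polygon)
    else:
        lo, hi = spec.implant_polygon[0], spec.implant_polygon[1]
        impl = np.all((centroids > lo) & (centroids < hi), axis=1)
    if spec.has_implant and not impl.any():
        raise GeometryError("element size too coarse to resolve the implant")
    material = np.where(impl, "implant", "bone").astype(object)
    material = np.asarray(material, dtype="U7")

    mesh = SimplexMesh(
        nodes=nodes,
        elements=elements,
        node_sets={},
        element_material=material,
    )
    mesh.node_sets = _label_node_sets(mesh)
    mesh.validate()
    return mesh


def _structured_triangles(extents, ncell):
    nx, ny = ncell
    xs = np.linspace(0.0, extents[0], nx + 1)
    ys = np.linspace(0.0, extents[1], ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b = nid(i, j), nid(i + 1, j)
            c, e = nid(i + 1, j + 1), nid(i, j + 1)
            # alternate the diagonal for isotropy
            if (i + j) % 2 == 0:
                tris.append([a, b, c])
                tris.append([a, c, e])
            else:
                tris.append([a, b, e])
                tris.append([b, c, e])
    return nodes, np.asarray(tris, dtype=np.int64)


def _structured_tets(extents, ncell):
    nx, ny, nz = ncell
    xs = np.linspace(0.0, extents[0], nx + 1)
    ys = np.linspace(0.0, extents[1], ny + 1)
    zs = np.linspace(0.0, extents[2], nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # Kuhn subdivision: 6 tets per cube, conforming across faces
    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                base = np.array([i, j, k])
                for p in perms:
                    verts = [base.copy()]
                    v = base.copy()
                    for axis in p:
                        v = v.copy()
                        v[axis] += 1
                        verts.append(v)
                    idx = [nid(*vv) for vv in verts]
                    tets.append(idx)
    tets = np.asarray(tets, dtype=np.int64)
    vols = _signed_volumes(nodes, tets)
    flip = vols < 0
    tets[flip, -2], tets[flip, -1] = tets[flip, -1].copy(), tets[flip, -2].copy()
    return nodes, tets


def _label_node_sets(mesh: SimplexMesh) -> Dict[str, np.ndarray]:
    n = mesh.n_nodes
    boundary = np.unique(mesh.boundary_facets())
    impl_elems = mesh.implant_elements
    impl_nodes = np.unique(mesh.elements[impl_elems]) if len(impl_elems) else np.array([], int)
    # one-element-deep interface ring: nodes of bone elements touching the implant
    if len(impl_nodes):
        mask = np.zeros(n, dtype=bool)
        mask[impl_nodes] = True
        touches = mask[mesh.elements].any(axis=1) & (mesh.element_material == "bone")
        ring = np.unique(mesh.elements[touches])
        omega2 = np.union1d(impl_nodes, ring)
    else:
        omega2 = impl_nodes
    if np.intersect1d(omega2, boundary).size:
        raise GeometryError("implant/interface nodes reach the outer boundary")
    omega1 = np.setdiff1d(boundary, omega2)
    interior = np.setdiff1d(np.arange(n), np.union1d(omega1, omega2))
    return {
        "fixed_boundary": omega1.astype(np.int64),
        "implant": omega2.astype(np.int64),
        "interior": interior.astype(np.int64),
    }


def define_regions(mesh: SimplexMesh, n_regions: int = 7) -> RegionMap:
    """Partition bone elements into periprosthetic zones.

    One distal band below the implant tip (for odd ``n_regions`` > 1), the
    rest of the height split into equal bands, each split laterally/medially
    about the implant centre -- a testable stand-in for the clinical zone
    definition on the real femur.
    """
    bone = mesh.bone_elements
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_regions > len(bone):
        raise ValueError("more regions than bone elements")
    if n_regions == 1:
        return RegionMap(regions={0: bone})

    centroids = mesh.nodes[mesh.elements[bone]].mean(axis=1)
    axis = 1  # implant long axis (y) in the synthetic domain
    impl_nodes = mesh.node_sets["implant"]
    impl_lo = mesh.nodes[impl_nodes, axis].min()
    cx = mesh.nodes[impl_nodes, 0].mean()

    labels = np.full(len(bone), -1, dtype=int)
    next_id = 0
    has_distal = n_regions % 2 == 1
    if has_distal:
        distal = centroids[:, axis] < impl_lo
        labels[distal] = next_id
        next_id += 1
        rest = ~distal
    else:
        rest = np.ones(len(bone), dtype=bool)
    n_bands = (n_regions - next_id) // 2
    y = centroids[:, axis]
    y_lo = y[rest].min()
    y_hi = y[rest].max() + 1e-12
    edges = np.linspace(y_lo, y_hi, n_bands + 1)
    band = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, n_bands - 1)
    lateral = centroids[:, 0] < cx
    for b in range(n_bands):
        for lat in (True, False):
            sel = rest & (band == b) & (lateral == lat)
            labels[sel] = next_id
            next_id += 1
    regions = {r: bone[labels == r] for r in range(n_regions)}
    if any(len(v) == 0 for v in regions.values()):
        raise ValueError("empty region; reduce n_regions or refine the mesh")
    rm = RegionMap(regions=regions)
    rm.validate(mesh)
    return rm
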