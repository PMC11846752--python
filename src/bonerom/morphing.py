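"""Pose-parameterised mesh morphing via Laplace's equation.

The implant node set moves rigidly with the pose parameters
``mu = [dx, dy, dz, alpha, beta, gamma]`` (translations in mm, rotations in
degrees; a 2D mesh uses ``[dx, dy, gamma]``).  The fixed outer boundary stays
put, and every remaining node coordinate solves the discrete Laplace equation
with those two sets as Dirichlet data -- a harmonic extension that preserves
connectivity, node numbering and DOF count across poses.

Static condensation makes the per-pose cost trivial: the interior block of
the Laplace stiffness is factorised once, the boundary couplings are
precomputed, and each new pose only requires evaluating the 4x4 (3x3 in 2D)
homogeneous transformation matrix and a handful of small matrix-vector
products per coordinate direction.

Conventions
-----------
* The homogeneous transform composes rotations and translation as
  ``T = R_x R_y R_z D`` (the translation is applied first and therefore
  rotated); rotations act about the centroid of the implant node set, so
  small rotations produce small displacements.
* Rotation angles are taken in degrees at every interface.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (
    SimplexMesh,
    MorphFailureError,
    check_mesh_quality,
    element_volumes,
    repair_inverted_elements,
)

__all__ = [
    "ImplantPose",
    "MorphOperator",
    "transformation_matrix",
    "assemble_laplace_operator",
    "build_morph_operator",
    "morph",
    "morph_mesh",
]


@dataclass(frozen=True)
class ImplantPose:
    """Rigid-body pose of the implant relative to its reference position.

    Translations in mm, rotations in degrees.  In 2D only ``dx, dy, gamma``
    are meaningful.
    """

    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        vec = self.as_vector(3)
        if not np.all(np.isfinite(vec)):
            raise ValueError("pose entries must be finite")

    def as_vector(self, dim: int = 3) -> np.ndarray:
        if dim == 2:
            return np.array([self.dx, self.dy, self.gamma], dtype=float)
        return np.array(
            [self.dx, self.dy, self.dz, self.alpha, self.beta, self.gamma],
            dtype=float,
        )

    @classmethod
    def from_vector(cls, vec, dim: int | None = None) -> "ImplantPose":
        vec = np.asarray(vec, dtype=float).ravel()
        if dim == 2 or (dim is None and len(vec) == 3):
            return cls(dx=vec[0], dy=vec[1], gamma=vec[2])
        return cls(*vec)


def _rotation_deg(angle_deg: float):
    a = np.deg2rad(angle_deg)
    return np.cos(a), np.sin(a)


def transformation_matrix(pose: ImplantPose, dim: int = 3,
                          center: np.ndarray | None = None) -> np.ndarray:
    """Homogeneous transformation matrix ``T = R_x R_y R_z D``.

    ``center`` shifts the rotation origin (the rigid map becomes
    ``x -> c + R((x - c) + delta)``); with ``center=None`` rotations act
    about the coordinate origin, exactly the printed composition.
    Returns a (4, 4) matrix in 3D, (3, 3) in 2D.
    """
    if dim == 3:
        ca, sa = _rotation_deg(pose.alpha)
        cb, sb = _rotation_deg(pose.beta)
        cg, sg = _rotation_deg(pose.gamma)
        Rx = np.array(
            [[1, 0, 0, 0], [0, ca, -sa, 0], [0, sa, ca, 0], [0, 0, 0, 1]], float
        )
        Ry = np.array(
            [[cb, 0, sb, 0], [0, 1, 0, 0], [-sb, 0, cb, 0], [0, 0, 0, 1]], float
        )
        Rz = np.array(
            [[cg, sg, 0, 0], [-sg, cg, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]], float
        )
        D = np.eye(4)
        D[:3, 3] = [pose.dx, pose.dy, pose.dz]
        T = Rx @ Ry @ Rz @ D
    elif dim == 2:
        cg, sg = _rotation_deg(pose.gamma)
        Rz = np.array([[cg, sg, 0], [-sg, cg, 0], [0, 0, 1]], float)
        D = np.eye(3)
        D[:2, 2] = [pose.dx, pose.dy]
        T = Rz @ D
    else:
        raise ValueError("dim must be 2 or 3")
    if center is not None:
        c = np.asarray(center, float)
        shift_in = np.eye(dim + 1)
        shift_in[:dim, dim] = -c
        shift_out = np.eye(dim + 1)
        shift_out[:dim, dim] = c
        T = shift_out @ T @ shift_in
    return T


def assemble_laplace_operator(mesh: SimplexMesh):
    """Scalar Laplace stiffness matrix, partitioned by node sets.

    Linear simplex FEM assembly of ``K_ab = int grad(N_a) . grad(N_b)``.
    Returns ``(K, index_sets)`` with ``K`` the full sparse matrix and
    ``index_sets = (omega1, omega2, interior)``; sub-blocks are sliced by
    the caller.  Row sums vanish (constants are harmonic) and the interior
    block is symmetric positive definite whenever Dirichlet nodes exist.
    """
    omega1 = mesh.node_sets["fixed_boundary"]
    omega2 = mesh.node_sets["implant"]
    interior = mesh.node_sets["interior"]
    if len(interior) == 0:
        raise ValueError("empty interior node set: nothing to morph")
    K = _scalar_stiffness(mesh.nodes, mesh.elements)
    return K, (omega1, omega2, interior)


def _shape_gradients(nodes: np.ndarray, elements: np.ndarray):
    """Per-element constant gradients of the linear shape functions.

    Returns ``(grads, vols)`` with ``grads`` of shape (M, d+1, d) and
    ``vols`` the (positive) element volumes.
    """
    d = nodes.shape[1]
    x = nodes[elements]  # (M, d+1, d)
    edges = np.transpose(x[:, 1:, :] - x[:, :1, :], (0, 2, 1))  # (M, d, d) columns=edges
    inv = np.linalg.inv(edges)  # rows of inv are gradients of N_1..N_d
    grads = np.empty((elements.shape[0], d + 1, d))
    grads[:, 1:, :] = np.transpose(inv, (0, 1, 2))
    grads[:, 0, :] = -inv.sum(axis=1)
    det = np.linalg.det(edges)
    vols = np.abs(det) / (2.0 if d == 2 else 6.0)
    return grads, vols


def _scalar_stiffness(nodes: np.ndarray, elements: np.ndarray) -> sp.csr_matrix:
    grads, vols = _shape_gradients(nodes, elements)
    ke = np.einsum("mad,mbd,m->mab", grads, grads, vols)
    nn = elements.shape[1]
    rows = np.repeat(elements, nn, axis=1).ravel()
    cols = np.tile(elements, (1, nn)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(len(nodes), len(nodes)))
    return K.tocsr()


@dataclass
class MorphOperator:
    """Precomputed static-condensation operator for one reference mesh.

    For each coordinate direction ``x3 = x3_fixed - W @ t_dir`` where
    ``t_dir`` is the corresponding row of the homogeneous transform,
    ``x3_fixed = -K33^-1 K31 p_omega1`` and ``W = K33^-1 K32 H^T`` with
    ``H`` the homogeneous reference coordinates of the implant node set.
    Only the transform varies between poses.
    """

    mesh: SimplexMesh
    omega1: np.ndarray
    omega2: np.ndarray
    interior: np.ndarray
    x3_fixed: np.ndarray       # (n3, d)
    coupling: np.ndarray       # (n3, d+1) = K33^-1 K32 H^T
    H2: np.ndarray             # (d+1, n2) homogeneous implant reference coords
    rotation_center: np.ndarray
    _solve33: object = None    # factorisation handle for K33
    K: sp.csr_matrix = None

    @property
    def dim(self) -> int:
        return self.mesh.dim


def build_morph_operator(mesh: SimplexMesh) -> MorphOperator:
    """Assemble, partition and factorise the Laplace system once (Eq-12 style).

    Raises on a singular interior block (disconnected interior).
    """
    K, (omega1, omega2, interior) = assemble_laplace_operator(mesh)
    d = mesh.dim
    K33 = K[np.ix_(interior, interior)].tocsc()
    K31 = K[np.ix_(interior, omega1)]
    K32 = K[np.ix_(interior, omega2)]
    try:
        solve33 = spla.splu(K33)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise ValueError(f"singular interior Laplace block: {exc}") from None

    p1 = mesh.nodes[omega1]            # (n1, d)
    p2 = mesh.nodes[omega2]            # (n2, d)
    H2 = np.vstack([p2.T, np.ones(len(omega2))])  # (d+1, n2)

    x3_fixed = -solve33.solve(K31 @ p1)           # (n3, d)
    coupling = solve33.solve(K32 @ H2.T)          # (n3, d+1)
    center = p2.mean(axis=0)

    return MorphOperator(
        mesh=mesh,
        omega1=omega1,
        omega2=omega2,
        interior=interior,
        x3_fixed=x3_fixed,
        coupling=coupling,
        H2=H2,
        rotation_center=center,
        _solve33=solve33,
        K=K,
    )


def morph(op: MorphOperator, pose: ImplantPose) -> np.ndarray:
    """New coordinates of all N nodes for the given pose.

    The fixed boundary is copied bit-identically from the reference, the
    implant node set is transformed rigidly, and the interior follows from
    the precomputed condensed solve.
    """
    d = op.dim
    T = transformation_matrix(pose, dim=d, center=op.rotation_center)
    new = op.mesh.nodes.copy()
    G = (T @ op.H2)[:d, :].T                      # (n2, d) rigid motion
    new[op.omega2] = G
    # x3 = x3_fixed - K33^-1 K32 G  with  G = H^T T_dir^T  per direction
    new[op.interior] = op.x3_fixed - op.coupling @ T[:d, :].T
    return new


def morph_mesh(mesh_or_op, pose: ImplantPose, tol: float = 0.01) -> SimplexMesh:
    """Morph the reference mesh to a pose, check quality, repair inversions.

    Connectivity and node numbering are untouched; only coordinates change.
    Elements inverted by the morph get their node order swapped; if any
    element still fails the volume-fraction check ``tol`` afterwards a
    :class:`MorphFailureError` names the offenders.  The quality report is
    attached as ``mesh.quality_report``.
    """
    op = mesh_or_op if isinstance(mesh_or_op, MorphOperator) else build_morph_operator(mesh_or_op)
    reference = op.mesh
    new_nodes = morph(op, pose)
    morphed = SimplexMesh(
        nodes=new_nodes,
        elements=reference.elements.copy(),
        node_sets={k: v.copy() for k, v in reference.node_sets.items()},
        element_material=reference.element_material.copy(),
    )
    inverted = np.flatnonzero(element_volumes(morphed) < 0)
    if len(inverted):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            morphed = repair_inverted_elements(morphed, inverted)
    failing = check_mesh_quality(morphed, tol=tol, reference=reference)
    # fatal: elements that needed the node-order fix yet are still below the
    # volume tolerance (the swap restores orientation, not geometry), or any
    # element left with non-positive volume
    vols = element_volumes(morphed)
    unrepairable = sorted(
        set(np.flatnonzero(vols <= 0)) | (set(inverted) & set(failing))
    )
    if unrepairable:
        raise MorphFailureError(
            f"morph produced {len(unrepairable)} unrepairable degenerate "
            f"elements (e.g. {unrepairable[:5]})",
            failing=unrepairable,
        )
    morphed.quality_report = {
        "repaired": inverted.tolist(),
        "below_tolerance": list(failing),
        "tol": tol,
    }
    return morphed
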