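"""Strain-energy-driven bone remodelling finite-element solver.

The model couples small-strain linear elasticity with an evolving bone mass
density (BMD) field:

* stiffness scales quadratically with density,
  ``sigma = (rho/rho0)^2 C_LE : eps``,
* the strain energy density ``Psi = (rho/rho0)^2 psi_LE(eps)`` drives a
  first-order mass source ``rho_dot = c (Psi - Psi_ref)``: overloaded bone
  densifies, underloaded bone resorbs (Wolff's law),
* density is clamped to physiological limits ``[rho_min, rho_max]``,
* a gradient enhancement couples the element-level density ``rho`` to a
  smooth nodal field ``phi`` through the energy penalty
  ``alpha_GE/2 (phi - rho)^2 + beta_GE/2 |grad phi|^2``, suppressing
  mesh-scale checkerboarding.

The quasi-static process is integrated by a staggered scheme: at each
pseudo-time step the mechanical equilibrium is solved at frozen density (the
problem is then linear, so the Newton loop converges in one iteration), the
nodal field ``phi`` is projected, and the density is updated by an implicit
Euler step evaluated at the new strain and new ``phi``, then clamped.
Iterations continue until the relative L2 change of ``phi`` drops below a
tolerance.

Units follow the mixed mm-N-(g/cm^3) convention of the material table; the
gradient-enhancement coefficients are used verbatim as in-context
coefficients (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List
import warnings

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import SimplexMesh
from .morphing import _shape_gradients, _scalar_stiffness

__all__ = [
    "MaterialParams",
    "LoadCase",
    "RemodellingConfig",
    "BoneState",
    "lame_parameters",
    "strain_energy_density",
    "stress",
    "mass_source",
    "gradient_enhanced_projection",
    "mechanical_solve",
    "density_update",
    "run_remodelling",
]


def lame_parameters(E: float, nu: float):
    """First and second Lamé parameters from Young's modulus and Poisson ratio."""
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if not (-1.0 < nu < 0.5):
        raise ValueError("Poisson ratio must lie in (-1, 0.5)")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


@dataclass
class MaterialParams:
    """Bone-remodelling material parameters (mm-N-(g/cm^3) units).

    Defaults are the calibrated values for trabecular/cortical bone with a
    titanium implant: ``E0`` reference Young's modulus at density ``rho0``,
    ``Psi_ref`` the homeostatic strain-energy target, ``c`` the remodelling
    speed, and ``alpha_GE``/``beta_GE`` the gradient-enhancement coupling and
    penalty coefficients.
    """

    E0: float = 6500.0          # N/mm^2
    nu: float = 0.3
    rho0: float = 1.0           # g/cm^3
    Psi_ref: float = 0.002      # N/mm^2
    c: float = 0.01             # s/m^2 (in-context rate coefficient)
    rho_min: float = 0.001      # g/cm^3
    rho_max: float = 2.0        # g/cm^3
    alpha_GE: float = 0.01
    beta_GE: float = 1e-8
    E_implant: float = 105000.0  # N/mm^2 (titanium)
    nu_implant: float = 0.3

    def __post_init__(self):
        if not (self.rho_min < self.rho0 <= self.rho_max):
            raise ValueError("require rho_min < rho0 <= rho_max")
        for name in ("E0", "rho0", "Psi_ref", "c", "rho_min", "rho_max", "E_implant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lame_parameters(self.E0, self.nu)  # validates nu

    @property
    def lame(self):
        return lame_parameters(self.E0, self.nu)


@dataclass
class LoadCase:
    """Dirichlet constraints and surface tractions.

    ``dirichlet`` is a list of ``(node_indices, component, value)`` tuples;
    ``tractions`` a list of ``(facets, traction_vector)`` with ``facets`` an
    (F, d) int array of boundary facet node tuples and the traction a
    per-unit-area vector (N/mm^2), integrated with linear shape functions.
    """

    dirichlet: List[tuple] = field(default_factory=list)
    tractions: List[tuple] = field(default_factory=list)

    def scaled(self, factor: float) -> "LoadCase":
        return LoadCase(
            dirichlet=[(n, c, v * factor) for (n, c, v) in self.dirichlet],
            tractions=[(f, np.asarray(t, float) * factor) for (f, t) in self.tractions],
        )


@dataclass
class RemodellingConfig:
    """Solver configuration for the quasi-static remodelling loop."""

    dt: float = 10.0
    max_steps: int = 500
    density_tol: float = 1e-5   # relative L2 change of phi
    newton_tol: float = 1e-8
    newton_max_iter: int = 5

    def __post_init__(self):
        for name in ("dt", "max_steps", "density_tol", "newton_tol", "newton_max_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BoneState:
    """State of the coupled problem: displacements, densities, process time."""

    u: np.ndarray            # (N, d) nodal displacement, mm
    rho: np.ndarray          # (M,) integration-point (element) density, g/cm^3
    phi: np.ndarray          # (N,) nodal enhanced density field, g/cm^3
    step: int = 0
    time: float = 0.0
    converged: bool = False
    history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# constitutive pointwise operations


def _as_tensor(eps: np.ndarray) -> np.ndarray:
    eps = np.asarray(eps, dtype=float)
    if eps.ndim != 2 or eps.shape[0] != eps.shape[1]:
        raise ValueError("strain must be a square tensor")
    return eps


def strain_energy_density(eps: np.ndarray, rho: float, params: MaterialParams) -> float:
    """Strain energy density ``Psi = (rho/rho0)^2 [lam/2 tr(eps)^2 + mu tr(eps^2)]``."""
    if rho <= 0:
        raise ValueError("density must be positive")
    eps = _as_tensor(eps)
    lam, mu = params.lame
    psi_le = 0.5 * lam * np.trace(eps) ** 2 + mu * np.trace(eps @ eps)
    return (rho / params.rho0) ** 2 * psi_le


def stress(eps: np.ndarray, rho: float, params: MaterialParams) -> np.ndarray:
    """Cauchy stress ``sigma = (rho/rho0)^2 C_LE : eps`` (isotropic)."""
    if rho <= 0:
        raise ValueError("density must be positive")
    eps = _as_tensor(eps)
    lam, mu = params.lame
    d = eps.shape[0]
    return (rho / params.rho0) ** 2 * (lam * np.trace(eps) * np.eye(d) + 2.0 * mu * eps)


def mass_source(Psi, params: MaterialParams):
    """Remodelling rate ``rho_dot = c (Psi - Psi_ref)``; zero at homeostasis."""
    return params.c * (np.asarray(Psi, dtype=float) - params.Psi_ref)


def density_update(rho, rho_dot, dt: float, params: MaterialParams):
    """Implicit-Euler style update with clamping to the physiological limits."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rho_next = np.asarray(rho, dtype=float) + dt * np.asarray(rho_dot, dtype=float)
    return np.clip(rho_next, params.rho_min, params.rho_max)


# ---------------------------------------------------------------------------
# assembly


def _elastic_moduli(mesh: SimplexMesh, rho: np.ndarray, params: MaterialParams):
    """Per-element Lamé pair including the density scaling and implant phase."""
    lam_b, mu_b = params.lame
    lam_i, mu_i = lame_parameters(params.E_implant, params.nu_implant)
    scale = (np.asarray(rho) / params.rho0) ** 2
    lam = np.where(mesh.element_material == "bone", lam_b * scale, lam_i)
    mu = np.where(mesh.element_material == "bone", mu_b * scale, mu_i)
    return lam, mu


def _assemble_stiffness(mesh: SimplexMesh, rho: np.ndarray, params: MaterialParams):
    """Vectorised linear-simplex elasticity stiffness (plane strain in 2D)."""
    d = mesh.dim
    grads, vols = _shape_gradients(mesh.nodes, mesh.elements)
    lam, mu = _elastic_moduli(mesh, rho, params)
    nn = d + 1
    M = mesh.n_elements
    # K_e[(a i),(b j)] = vol * (lam ga_i gb_j + mu gb_i ga_j + mu delta_ij ga.gb)
    ga_gb = np.einsum("mad,mbd->mab", grads, grads)          # (M, nn, nn)
    term1 = np.einsum("m,mai,mbj->maibj", lam * vols, grads, grads)
    term2 = np.einsum("m,maj,mbi->maibj", mu * vols, grads, grads)
    term3 = np.einsum("m,mab,ij->maibj", mu * vols, ga_gb, np.eye(d))
    ke = term1 + term2 + term3                               # (M, nn, d, nn, d)
    dof = (mesh.elements[:, :, None] * d + np.arange(d)).reshape(M, nn * d)
    ke = ke.reshape(M, nn * d, nn * d)
    rows = np.repeat(dof, nn * d, axis=1).ravel()
    cols = np.tile(dof, (1, nn * d)).ravel()
    ndof = mesh.n_nodes * d
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


def _traction_vector(mesh: SimplexMesh, loads: LoadCase) -> np.ndarray:
    d = mesh.dim
    f = np.zeros(mesh.n_nodes * d)
    for facets, t in loads.tractions:
        facets = np.asarray(facets, dtype=int)
        t = np.asarray(t, dtype=float)
        pts = mesh.nodes[facets]  # (F, d, d)
        if d == 2:
            measure = np.linalg.norm(pts[:, 1] - pts[:, 0], axis=1)
        else:
            measure = 0.5 * np.linalg.norm(
                np.cross(pts[:, 1] - pts[:, 0], pts[:, 2] - pts[:, 0]), axis=1
            )
        share = measure / facets.shape[1]  # equal split for linear shapes
        for comp in range(d):
            np.add.at(f, facets.ravel() * d + comp, np.repeat(share * t[comp], facets.shape[1]))
    return f


def _dirichlet_arrays(mesh: SimplexMesh, loads: LoadCase):
    d = mesh.dim
    fixed = {}
    for nodes, comp, value in loads.dirichlet:
        nodes = np.asarray(nodes, dtype=int)
        vals = np.broadcast_to(np.asarray(value, float), nodes.shape)
        for nd, v in zip(nodes, vals):
            fixed[nd * d + comp] = v
    if not fixed:
        raise ValueError("no Dirichlet data: the system is singular")
    idx = np.fromiter(fixed.keys(), dtype=int)
    vals = np.fromiter((fixed[i] for i in idx), dtype=float)
    return idx, vals


def mechanical_solve(
    mesh: SimplexMesh,
    rho: np.ndarray,
    loads: LoadCase,
    params: MaterialParams,
    config: RemodellingConfig | None = None,
) -> np.ndarray:
    """Solve mechanical equilibrium at frozen density.

    Newton-Raphson on the residual ``r(u) = f_ext - K(rho) u``; at fixed
    density the problem is linear, so convergence in a single iteration is
    asserted.  Returns the (N, d) nodal displacement field.
    """
    config = config or RemodellingConfig()
    d = mesh.dim
    ndof = mesh.n_nodes * d
    K = _assemble_stiffness(mesh, rho, params)
    f = _traction_vector(mesh, loads)
    fixed_idx, fixed_vals = _dirichlet_arrays(mesh, loads)
    free = np.setdiff1d(np.arange(ndof), fixed_idx)

    u = np.zeros(ndof)
    u[fixed_idx] = fixed_vals
    Kff = K[np.ix_(free, free)].tocsc()
    solve = spla.factorized(Kff)
    residual_history = []
    ref = max(np.linalg.norm(f), np.linalg.norm(K @ u), 1.0)
    for it in range(config.newton_max_iter):
        r = f - K @ u
        rnorm = np.linalg.norm(r[free]) / ref
        residual_history.append(rnorm)
        if rnorm < config.newton_tol:
            break
        du = solve(r[free])
        u[free] += du
    else:
        raise RuntimeError(
            f"Newton did not converge; residual history {residual_history}"
        )
    return u.reshape(mesh.n_nodes, d)


def _element_strain_energy_le(mesh: SimplexMesh, u: np.ndarray, params: MaterialParams):
    """Reference linear-elastic energy density ``psi_LE`` per element."""
    d = mesh.dim
    grads, _ = _shape_gradients(mesh.nodes, mesh.elements)
    ue = u[mesh.elements]  # (M, d+1, d)
    grad_u = np.einsum("mai,maj->mij", ue, grads)  # careful: sum over a
    eps = 0.5 * (grad_u + np.transpose(grad_u, (0, 2, 1)))
    lam, mu = params.lame
    tr = np.trace(eps, axis1=1, axis2=2)
    tr2 = np.einsum("mij,mji->m", eps, eps)
    return 0.5 * lam * tr**2 + mu * tr2, eps


def _lumped_density_rhs(mesh: SimplexMesh, rho: np.ndarray) -> np.ndarray:
    """RHS ``b_a = int N_a rho dOmega`` for element-wise constant rho."""
    _, vols = _shape_gradients(mesh.nodes, mesh.elements)
    b = np.zeros(mesh.n_nodes)
    contrib = rho * vols / (mesh.dim + 1)
    for a in range(mesh.dim + 1):
        np.add.at(b, mesh.elements[:, a], contrib)
    return b


def _mass_matrix(mesh: SimplexMesh) -> sp.csr_matrix:
    """Consistent mass matrix ``M_ab = int N_a N_b dOmega``."""
    d = mesh.dim
    nn = d + 1
    _, vols = _shape_gradients(mesh.nodes, mesh.elements)
    base = (np.ones((nn, nn)) + np.eye(nn)) / ((nn) * (nn + 1))
    ke = vols[:, None, None] * base[None, :, :]
    rows = np.repeat(mesh.elements, nn, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, nn)).ravel()
    return sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()


def gradient_enhanced_projection(
    mesh: SimplexMesh,
    rho: np.ndarray,
    params: MaterialParams,
    factor=None,
) -> np.ndarray:
    """Project element densities to the smooth nodal field ``phi``.

    Stationarity of the enhancement energy yields the screened projection
    ``(M + (beta_GE/alpha_GE) K_lap) phi = b`` with ``b_a = int N_a rho``.
    ``beta_GE = 0`` recovers the plain consistent L2 projection; a pre-built
    sparse factorisation can be passed as ``factor`` for reuse across steps.
    """
    if params.alpha_GE <= 0:
        raise ValueError("alpha_GE must be positive (coupling lost at zero)")
    if factor is None:
        factor = build_projection_factor(mesh, params)
    b = _lumped_density_rhs(mesh, rho)
    return factor(b)


def build_projection_factor(mesh: SimplexMesh, params: MaterialParams):
    """Factorise the screened-projection operator once per mesh."""
    M = _mass_matrix(mesh)
    A = M
    if params.beta_GE != 0:
        A = M + (params.beta_GE / params.alpha_GE) * _scalar_stiffness(
            mesh.nodes, mesh.elements
        )
    return spla.factorized(A.tocsc())


def _phi_at_elements(mesh: SimplexMesh, phi: np.ndarray) -> np.ndarray:
    return phi[mesh.elements].mean(axis=1)


def run_remodelling(
    mesh: SimplexMesh,
    loads: LoadCase,
    params: MaterialParams,
    config: RemodellingConfig | None = None,
    rho_init: np.ndarray | float | None = None,
) -> BoneState:
    """Quasi-static remodelling to a converged BMD field.

    Two-phase protocol: a load-application equilibrium solve, then staggered
    pseudo-time steps (mechanics -> projection -> density update) until the
    relative L2 change of ``phi`` drops below ``config.density_tol``.
    Implant elements are linear elastic with frozen density.

    Returns the final :class:`BoneState`; ``state.history`` holds the
    relative change per step, ``state.converged`` the termination status.
    """
    config = config or RemodellingConfig()
    bone = mesh.element_material == "bone"
    if rho_init is None:
        rho_init = params.rho0
    rho = np.broadcast_to(np.asarray(rho_init, dtype=float), (mesh.n_elements,)).copy()
    if np.any((rho[bone] < params.rho_min) | (rho[bone] > params.rho_max)):
        raise ValueError("rho_init outside physiological bounds")

    proj = build_projection_factor(mesh, params)
    # phase 1: load application at the initial density
    u = mechanical_solve(mesh, rho, loads, params, config)
    phi = gradient_enhanced_projection(mesh, rho, params, factor=proj)
    history = []
    converged = False
    grow_streak = 0
    step = 0
    for step in range(1, config.max_steps + 1):
        psi_le, _ = _element_strain_energy_le(mesh, u, params)
        phi_e = _phi_at_elements(mesh, phi)
        # source at the new strain and the enhanced density field
        Psi = (np.clip(phi_e, params.rho_min, None) / params.rho0) ** 2 * psi_le
        rho_dot = mass_source(Psi, params)
        rho_new = rho.copy()
        rho_new[bone] = density_update(rho[bone], rho_dot[bone], config.dt, params)
        u = mechanical_solve(mesh, rho_new, loads, params, config)
        phi_new = gradient_enhanced_projection(mesh, rho_new, params, factor=proj)
        denom = max(np.linalg.norm(phi_new), 1e-30)
        change = np.linalg.norm(phi_new - phi) / denom
        history.append(change)
        rho, phi = rho_new, phi_new
        if change < config.density_tol:
            converged = True
            break
        if len(history) > 1 and change > history[-2] * (1.0 + 1e-12):
            grow_streak += 1
            if grow_streak >= 25 and change > 10.0 * history[0]:
                raise RuntimeError(
                    "density oscillation growth detected; "
                    f"last changes {history[-5:]}"
                )
        else:
            grow_streak = 0
    if not converged:
        warnings.warn(
            f"remodelling not converged after {config.max_steps} steps "
            f"(last change {history[-1]:.3e})",
            stacklevel=2,
        )
    return BoneState(
        u=u,
        rho=rho,
        phi=phi,
        step=step,
        time=step * config.dt,
        converged=converged,
        history=history,
    )
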