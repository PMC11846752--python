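import numpy as np
import pytest

import bonerom as br
from bonerom.remodelling import (
    density_update,
    gradient_enhanced_projection,
    lame_parameters,
    mass_source,
    mechanical_solve,
    strain_energy_density,
    stress,
    _lumped_density_rhs,
    _mass_matrix,
)
from .conftest import bar_traction_loads, make_bar

RHO_STAR = 4.0 / np.sqrt(35.0)  # confined-bar equilibrium at 4 N/mm^2


class TestLame:
    def test_reference_values(self):
        lam, mu = lame_parameters(6500.0, 0.3)
        assert lam == pytest.approx(3750.0)
        assert mu == pytest.approx(2500.0)

    def test_zero_poisson(self):
        lam, mu = lame_parameters(1000.0, 0.0)
        assert lam == 0.0
        assert mu == 500.0

    @pytest.mark.parametrize("E,nu", [(-1.0, 0.3), (0.0, 0.3), (6500.0, 0.5), (6500.0, -1.0)])
    def test_invalid_inputs_rejected(self, E, nu):
        with pytest.raises(ValueError):
            lame_parameters(E, nu)


class TestConstitutive:
    def test_zero_strain_zero_energy_and_stress(self, table_params):
        eps = np.zeros((2, 2))
        assert strain_energy_density(eps, 1.0, table_params) == 0.0
        assert np.all(stress(eps, 1.0, table_params) == 0.0)

    def test_confined_uniaxial_energy(self, table_params):
        eps = np.diag([1e-3, 0.0, 0.0])
        psi = strain_energy_density(eps, table_params.rho0, table_params)
        assert psi == pytest.approx(0.004375, rel=1e-12)

    def test_quadratic_density_scaling(self, table_params):
        eps = np.diag([1e-3, 0.0, 0.0])
        half = strain_energy_density(eps, 0.5 * table_params.rho0, table_params)
        assert half == pytest.approx(0.25 * 0.004375, rel=1e-12)

    def test_reference_density_recovers_linear_elasticity(self, table_params):
        lam, mu = table_params.lame
        eps = np.array([[1e-3, 2e-4], [2e-4, -5e-4]])
        sig = stress(eps, table_params.rho0, table_params)
        expect = lam * np.trace(eps) * np.eye(2) + 2 * mu * eps
        assert np.allclose(sig, expect, rtol=1e-14)

    def test_stress_strain_energy_identity(self, table_params):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=(3, 3)) * 1e-3
            eps = 0.5 * (a + a.T)
            rho = rng.uniform(0.1, 2.0)
            sig = stress(eps, rho, table_params)
            psi = strain_energy_density(eps, rho, table_params)
            assert np.tensordot(sig, eps) == pytest.approx(2 * psi, rel=1e-12)


class TestMassSourceAndUpdate:
    def test_equilibrium_source_vanishes(self, table_params):
        assert mass_source(table_params.Psi_ref, table_params) == 0.0

    def test_rate_arithmetic(self, table_params):
        assert mass_source(0.004, table_params) == pytest.approx(2e-5, rel=1e-12)

    def test_zero_speed(self):
        params = br.MaterialParams(c=0.0)
        assert mass_source(0.123, params) == 0.0

    def test_update_arithmetic(self, table_params):
        assert density_update(1.0, 2e-5, 10.0, table_params) == pytest.approx(1.0002)

    def test_update_clamps_to_physiological_limits(self, table_params):
        assert density_update(1.9, 1.0, 10.0, table_params) == 2.0
        assert density_update(0.01, -1.0, 10.0, table_params) == 0.001

    def test_update_fixed_at_equilibrium(self, table_params):
        rate = mass_source(table_params.Psi_ref, table_params)
        assert density_update(0.7, rate, 10.0, table_params) == 0.7


class TestGradientEnhancement:
    def test_uniform_density_projects_to_itself(self, small_mesh, table_params):
        rho = np.ones(small_mesh.n_elements)
        phi = gradient_enhanced_projection(small_mesh, rho, table_params)
        assert np.allclose(phi, 1.0, atol=1e-10)

    def test_beta_zero_recovers_l2_projection(self, small_mesh, table_params):
        """Independent oracle: dense solve of the consistent-mass projection."""
        rng = np.random.default_rng(5)
        rho = rng.uniform(0.2, 1.8, size=small_mesh.n_elements)
        params = br.MaterialParams(beta_GE=0.0)
        phi = gradient_enhanced_projection(small_mesh, rho, params)
        M = _mass_matrix(small_mesh).toarray()
        b = _lumped_density_rhs(small_mesh, rho)
        oracle = np.linalg.solve(M, b)
        assert np.abs(phi - oracle).max() < 1e-10

    def test_checkerboard_variance_reduced_by_enhancement(self, table_params):
        spec = br.DomainSpec(
            extents=(1.0, 1.0), implant_polygon=np.empty((0, 2)),
            element_size=0.1, pose_bounds={"dx": (-0.1, 0.1)},
        )
        mesh = br.build_reference_domain(spec)
        parity = np.arange(mesh.n_elements) % 2
        rho = 1.0 + 0.05 * (2 * parity - 1)
        phi_plain = gradient_enhanced_projection(
            mesh, rho, br.MaterialParams(beta_GE=0.0))
        phi_enh = gradient_enhanced_projection(
            mesh, rho, br.MaterialParams(beta_GE=1e-8))
        assert phi_enh.var() < phi_plain.var()

    def test_zero_coupling_rejected(self, small_mesh):
        params = br.MaterialParams()
        params.alpha_GE = 0.0
        with pytest.raises(ValueError, match="alpha_GE"):
            gradient_enhanced_projection(
                small_mesh, np.ones(small_mesh.n_elements), params)


class TestMechanicalSolve:
    def test_zero_load_zero_displacement(self, bar, table_params):
        mesh, left, right = bar
        loads = bar_traction_loads(mesh, left, right, sigma=0.0)
        u = mechanical_solve(mesh, np.ones(mesh.n_elements), loads, table_params)
        assert np.abs(u).max() == 0.0

    def test_prescribed_end_displacement_gives_uniform_strain(self, table_params):
        mesh, left, _ = make_bar()
        L, d = 10.0, 0.02
        rightn = np.flatnonzero(mesh.nodes[:, 0] > L - 1e-9)
        loads = br.LoadCase(dirichlet=[
            (left, 0, 0.0),
            (np.arange(mesh.n_nodes), 1, 0.0),
            (rightn, 0, d),
        ])
        u = mechanical_solve(mesh, np.ones(mesh.n_elements), loads, table_params)
        expect = (d / L) * mesh.nodes[:, 0]
        assert np.abs(u[:, 0] - expect).max() < 1e-10
        assert np.abs(u[:, 1]).max() < 1e-12

    def test_linearity_in_tractions(self, bar, table_params):
        mesh, left, right = bar
        rho = np.full(mesh.n_elements, 0.9)
        u1 = mechanical_solve(
            mesh, rho, bar_traction_loads(mesh, left, right, 2.0), table_params)
        u2 = mechanical_solve(
            mesh, rho, bar_traction_loads(mesh, left, right, 4.0), table_params)
        assert np.abs(u2 - 2 * u1).max() < 1e-10

    def test_missing_dirichlet_rejected(self, bar, table_params):
        mesh, _, right = bar
        loads = br.LoadCase(dirichlet=[], tractions=[(right, np.array([1.0, 0.0]))])
        with pytest.raises(ValueError, match="Dirichlet"):
            mechanical_solve(mesh, np.ones(mesh.n_elements), loads, table_params)


class TestRunRemodelling:
    def _bar_setup(self, sigma=4.0):
        mesh, left, right = make_bar()
        loads = bar_traction_loads(mesh, left, right, sigma=sigma)
        cfg = br.RemodellingConfig(dt=2000.0, max_steps=300, density_tol=1e-7)
        return mesh, loads, cfg

    def test_bar_converges_to_closed_form_density(self, table_params):
        """Load-controlled confined bar: the stable equilibrium has strain
        1e-3 and density rho0*sqrt(Psi_ref/psi_LE) = 4/sqrt(35)."""
        mesh, loads, cfg = self._bar_setup()
        state = br.run_remodelling(mesh, loads, table_params, cfg, rho_init=1.0)
        assert state.converged
        assert np.abs(state.rho - RHO_STAR).max() / RHO_STAR < 1e-4
        assert np.abs(state.phi - RHO_STAR).max() / RHO_STAR < 1e-4

    def test_bar_relaxation_is_monotone(self, table_params):
        mesh, loads, cfg = self._bar_setup()
        state = br.run_remodelling(mesh, loads, table_params, cfg, rho_init=1.0)
        h = np.array(state.history)
        assert np.all(np.diff(h) < 0)  # geometric decay, no oscillation

    def test_steady_start_converges_immediately(self, table_params):
        mesh, loads, cfg = self._bar_setup()
        state = br.run_remodelling(
            mesh, loads, table_params, cfg, rho_init=RHO_STAR)
        assert state.converged
        assert state.step <= 2
        assert np.abs(state.rho - RHO_STAR).max() / RHO_STAR < 1e-6

    def test_zero_load_decays_to_minimum_density(self, table_params):
        mesh, loads, cfg = self._bar_setup(sigma=0.0)
        state = br.run_remodelling(mesh, loads, table_params, cfg, rho_init=1.0)
        assert state.converged
        assert np.all(state.rho == table_params.rho_min)

    def test_density_bounds_preserved_each_step(self, table_params):
        mesh, left, right = make_bar()
        loads = bar_traction_loads(mesh, left, right, sigma=12.0)
        cfg = br.RemodellingConfig(dt=5000.0, max_steps=40, density_tol=1e-12)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = br.run_remodelling(mesh, loads, table_params, cfg, rho_init=1.0)
        assert state.rho.min() >= table_params.rho_min
        assert state.rho.max() <= table_params.rho_max

    def test_translation_objectivity(self, table_params):
        """Shifting the Dirichlet data by a rigid translation leaves the
        strain and density trajectories unchanged."""
        mesh, left, right = make_bar()
        cfg = br.RemodellingConfig(dt=2000.0, max_steps=50, density_tol=1e-12)
        import warnings
        loads_a = bar_traction_loads(mesh, left, right, sigma=4.0)
        loads_b = br.LoadCase(
            dirichlet=[(left, 0, 0.5), (np.arange(mesh.n_nodes), 1, 0.0)],
            tractions=[(right, np.array([4.0, 0.0]))],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sa = br.run_remodelling(mesh, loads_a, table_params, cfg, rho_init=1.0)
            sb = br.run_remodelling(mesh, loads_b, table_params, cfg, rho_init=1.0)
        assert np.abs(sa.rho - sb.rho).max() < 1e-10
        assert np.abs(sa.phi - sb.phi).max() < 1e-10
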