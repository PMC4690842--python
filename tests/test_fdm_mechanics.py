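"""Finite-difference mechanics: stencils, constitutive law, time stepping."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bresym import fdm_mechanics as fdm
from bresym._kernels import fused_step


def unit_grid(n=7, h=1.0):
    return fdm.SimulationGrid((n, n, n), (h, h, h))


def neo_hookean_energy(F, mu, lam):
    C = F.T @ F
    J = np.linalg.det(F)
    return mu / 2 * (np.trace(C) - 3) - mu * np.log(J) + lam / 2 * np.log(J) ** 2


def numeric_energy_gradient(F, mu, lam, eps=1e-6):
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += eps
            Fm[i, j] -= eps
            P[i, j] = (
                neo_hookean_energy(Fp, mu, lam) - neo_hookean_energy(Fm, mu, lam)
            ) / (2 * eps)
    return P


def stress_of_matrix(F, mu, lam):
    """Nominal stress of a single homogeneous deformation gradient."""
    kin = fdm.KinematicsField(
        F=F.reshape(3, 3, 1, 1, 1), J=np.array(np.linalg.det(F)).reshape(1, 1, 1)
    )
    return fdm.neo_hookean_stress(kin, mu, lam)[:, :, 0, 0, 0]


class TestSpatialDerivatives:
    def test_mixed_stencil_exact_on_bilinear_field(self):
        grid = unit_grid()
        idx = np.indices(grid.shape, dtype=float)
        u = np.zeros((3, *grid.shape))
        u[0] = idx[0] * idx[1]
        d = fdm.spatial_derivatives(u, grid)
        interior = (slice(1, -1),) * 3
        assert np.allclose(d.second[0, 0, 1][interior], 1.0)
        assert np.allclose(d.second[0, 1, 0][interior], 1.0)
        assert np.allclose(d.second[0, 0, 2][interior], 0.0)

    def test_constant_field_has_zero_derivatives(self):
        grid = unit_grid()
        u = np.full((3, *grid.shape), 3.7)
        d = fdm.spatial_derivatives(u, grid)
        assert np.allclose(d.first, 0.0)
        assert np.allclose(d.second, 0.0)

    @pytest.mark.parametrize("h", [1.0, 0.5, 2.0])
    def test_second_derivative_exact_on_quadratic(self, h):
        grid = unit_grid(h=h)
        idx = np.indices(grid.shape, dtype=float) * h
        u = np.zeros((3, *grid.shape))
        u[1] = idx[0] ** 2
        d = fdm.spatial_derivatives(u, grid)
        interior = (slice(1, -1),) * 3
        assert np.allclose(d.second[1, 0, 0][interior], 2.0)

    def test_degenerate_axis_raises(self):
        with pytest.raises(fdm.StencilError):
            fdm.SimulationGrid((2, 5, 5), (1, 1, 1))


class TestDeformationGradient:
    def test_zero_displacement_is_reference(self):
        grid = unit_grid()
        kin = fdm.deformation_gradient(np.zeros((3, *grid.shape)), grid)
        assert np.allclose(kin.F[0, 0], 1) and np.allclose(kin.F[0, 1], 0)
        assert np.allclose(kin.J, 1.0)
        assert np.allclose(kin.C[1, 1], 1.0)

    def test_linear_field_recovered_exactly(self, rng):
        grid = unit_grid()
        A = 0.05 * rng.standard_normal((3, 3))
        idx = np.indices(grid.shape, dtype=float)
        u = np.einsum("ab,b...->a...", A, idx)
        kin = fdm.deformation_gradient(u, grid)
        interior = (slice(1, -1),) * 3
        for a in range(3):
            for b in range(3):
                expected = (a == b) + A[a, b]
                assert np.allclose(kin.F[a, b][interior], expected, atol=1e-12)

    def test_rotation_field_preserves_volume(self):
        grid = unit_grid(n=9, h=0.1)
        R = Rotation.from_euler("xyz", [5, -3, 8], degrees=True).as_matrix()
        idx = np.indices(grid.shape, dtype=float) * 0.1
        u = np.einsum("ab,b...->a...", R - np.eye(3), idx)
        kin = fdm.deformation_gradient(u, grid)
        interior = (slice(1, -1),) * 3
        assert np.allclose(kin.J[interior], 1.0, atol=1e-10)


class TestNeoHookeanStress:
    def test_reference_state_is_stress_free(self):
        assert np.allclose(stress_of_matrix(np.eye(3), 1.0, 1.0), 0.0)

    def test_objectivity_rotations_stress_free(self):
        rot = Rotation.random(20, rng=np.random.default_rng(7))
        for R in rot.as_matrix():
            N = stress_of_matrix(R, 357.1, 1000.0)
            assert np.abs(N).max() < 1e-10 * 357.1

    def test_uniaxial_stretch_matches_closed_form(self):
        N = stress_of_matrix(np.diag([2.0, 1.0, 1.0]), 1.0, 1.0)
        assert N[0, 0] == pytest.approx(2 * (0.75 + 0.25 * np.log(2)), rel=1e-12)
        assert N[1, 1] == pytest.approx(np.log(2), rel=1e-12)
        assert N[2, 2] == pytest.approx(np.log(2), rel=1e-12)
        off = N - np.diag(np.diag(N))
        assert np.allclose(off, 0.0)

    def test_matches_numeric_energy_gradient(self, rng):
        """Nominal stress equals the transposed energy gradient dW/dF."""
        n_ok = 0
        while n_ok < 100:
            F = np.eye(3) + 0.25 * rng.standard_normal((3, 3))
            if np.linalg.det(F) < 0.3:
                continue
            mu, lam = rng.uniform(0.5, 3.0, 2)
            N = stress_of_matrix(F, mu, lam)
            P = numeric_energy_gradient(F, mu, lam)
            assert np.abs(N.T - P).max() < 1e-5 * max(np.abs(P).max(), 1.0)
            n_ok += 1

    def test_inverted_element_raises_with_location(self):
        grid = unit_grid()
        u = np.zeros((3, *grid.shape))
        u[0, 3, 3, 3] = 2.5  # fold the centre node over its neighbours
        kin = fdm.deformation_gradient(u, grid)
        with pytest.raises(fdm.ElementInversionError):
            fdm.neo_hookean_stress(kin, 1.0, 1.0)


class TestNodalForce:
    def test_zero_state_zero_force(self):
        grid = unit_grid()
        K = fdm.assemble_nodal_force(np.zeros((3, *grid.shape)), grid, 1.0, 1.0, 1.0)
        assert np.allclose(K, 0.0)

    def test_pure_body_force_passes_through(self):
        grid = unit_grid()
        f = np.zeros((3, *grid.shape))
        f[2] = 9.81
        K = fdm.assemble_nodal_force(np.zeros((3, *grid.shape)), grid, 1.0, 1.0, 1.0, f)
        assert np.allclose(K[2], 9.81) and np.allclose(K[0], 0.0)

    def test_homogeneous_linear_field_is_divergence_free(self, rng):
        """Constant stress (linear displacement, uniform material) has zero
        divergence at interior nodes."""
        grid = unit_grid(n=9, h=0.5)
        A = 0.02 * rng.standard_normal((3, 3))
        idx = np.indices(grid.shape, dtype=float) * 0.5
        u = np.einsum("ab,b...->a...", A, idx)
        K = fdm.assemble_nodal_force(u, grid, 2.0, 3.0, 1.0)
        interior = (slice(None),) + (slice(2, -2),) * 3
        assert np.abs(K[interior]).max() < 1e-9


class TestExplicitStep:
    def test_undamped_inertia(self):
        st = fdm.DisplacementState(
            u=np.full((3, 3, 3, 3), 1.0), u_prev=np.full((3, 3, 3, 3), 0.9), h_t=0.1
        )
        out = fdm.explicit_step(st, np.zeros((3, 3, 3, 3)), 1.0, 0.0)
        assert np.allclose(out.u, 1.1)

    def test_damped_update_matches_hand_calculation(self):
        # (2*1 + 0.1*10)*1 - 1*0.9 + 0  over  1 + 0.1*10  ->  1.05
        st = fdm.DisplacementState(
            u=np.full((3, 3, 3, 3), 1.0), u_prev=np.full((3, 3, 3, 3), 0.9), h_t=0.1
        )
        out = fdm.explicit_step(st, np.zeros((3, 3, 3, 3)), 1.0, 10.0)
        assert np.allclose(out.u, 1.05)

    def test_dirichlet_nodes_forced_to_zero(self):
        st = fdm.DisplacementState(
            u=np.full((3, 3, 3, 3), 1.0), u_prev=np.full((3, 3, 3, 3), 1.0), h_t=0.1
        )
        mask = fdm.boundary_mask((3, 3, 3))
        out = fdm.explicit_step(st, np.zeros((3, 3, 3, 3)), 1.0, 0.0, mask)
        assert np.all(out.u[:, mask] == 0.0)

    @staticmethod
    def _oscillator_error(h_t, T=2.0, rho=1.0, r=0.8, omega=2 * np.pi, u0=0.01):
        st = fdm.DisplacementState(
            u=np.full((3, 1, 1, 1), u0), u_prev=np.full((3, 1, 1, 1), u0), h_t=h_t
        )
        for _ in range(int(round(T / h_t))):
            st = fdm.explicit_step(st, -(omega**2) * st.u, rho, r)
        zeta = r / (2 * rho * omega)
        wd = omega * np.sqrt(1 - zeta**2)
        exact = u0 * np.exp(-zeta * omega * T) * (
            np.cos(wd * T) + zeta * omega / wd * np.sin(wd * T)
        )
        return abs(st.u[0, 0, 0, 0] - exact), abs(u0)

    def test_single_node_tracks_damped_oscillator(self):
        """The update converges to the analytic damped harmonic oscillator
        under step refinement and is accurate at ~100 steps/period."""
        e1, amp = self._oscillator_error(0.01)
        e2, _ = self._oscillator_error(0.005)
        assert e1 < 5e-3 * amp
        assert e2 < 0.6 * e1  # consistent: error vanishes with h_t

    def test_zero_everything_stays_zero(self):
        grid = unit_grid()
        st = fdm.DisplacementState.zeros(grid, 1e-3)
        for _ in range(50):
            K = fdm.assemble_nodal_force(st.u, grid, 1.0, 1.0, 1.0)
            st = fdm.explicit_step(st, K, 1.0, 1.0)
        assert np.all(st.u == 0.0)


class TestCriticalTimeStep:
    def test_linear_in_spacing(self):
        g1 = unit_grid(h=1.0)
        g2 = unit_grid(h=2.0)
        assert fdm.critical_time_step(1.0, 1.0, 1.0, g2) == pytest.approx(
            2 * fdm.critical_time_step(1.0, 1.0, 1.0, g1)
        )

    def test_sqrt_scaling_with_stiffness(self):
        g = unit_grid()
        h1 = fdm.critical_time_step(1.0, 1.0, 1.0, g)
        h2 = fdm.critical_time_step(4.0, 4.0, 1.0, g)
        assert h2 == pytest.approx(h1 / 2)

    def test_soft_tissue_value(self):
        mu = 357.1
        lam = fdm.lame_lambda_from_mu(mu, 0.49)
        g = fdm.SimulationGrid((5, 5, 5), (8e-3, 8e-3, 8e-3))
        expected = 0.5 * 8e-3 / np.sqrt((lam + 2 * mu) / 1000.0)
        assert fdm.critical_time_step(mu, lam, 1000.0, g) == pytest.approx(expected)

    def test_zero_stiffness_rejected(self):
        with pytest.raises(ValueError):
            fdm.critical_time_step(0.0, 0.0, 1.0, unit_grid())


class TestQuasiStaticSettling:
    def test_damped_block_under_constant_load_settles(self):
        """With speed-proportional damping and a constant body force, the
        maximum nodal speed decays below tolerance (quasi-static reachability)."""
        grid = fdm.SimulationGrid((7, 7, 7), (5e-3,) * 3)
        mu, rho = 500.0, 1000.0
        lam = fdm.lame_lambda_from_mu(mu)
        h_t = fdm.critical_time_step(mu, lam, rho, grid)
        f = np.zeros((3, *grid.shape))
        f[2] = 0.5
        fixed = fdm.boundary_mask(grid.shape)
        damping = 2 * rho * np.sqrt(mu / rho) / 0.03
        st = fdm.DisplacementState.zeros(grid, h_t)
        speeds = []
        for _ in range(3000):
            K = fdm.assemble_nodal_force(st.u, grid, mu, lam, rho, f)
            st = fdm.explicit_step(st, K, rho, damping, fixed)
            speeds.append(st.max_speed)
        assert st.max_speed < 1e-5
        assert np.abs(st.u).max() > 0  # it actually deformed

    def test_grid_refinement_consistency(self):
        """Halving the spacing shrinks the spatial-discretisation error of the
        full force path (u -> F -> N -> div N) with observed order >= 1."""
        L = 0.03

        def force_residual(n):
            h = L / (n - 1)
            grid = fdm.SimulationGrid((n, n, n), (h,) * 3)
            idx = np.indices(grid.shape, dtype=float) * h
            kx = 2 * np.pi / L
            u = np.zeros((3, *grid.shape))
            u[0] = 1e-3 * np.sin(kx * idx[0]) * np.cos(kx * idx[1])
            u[1] = 1e-3 * np.cos(kx * idx[1]) * np.sin(kx * idx[2])
            u[2] = 1e-3 * np.sin(kx * idx[2]) * np.cos(kx * idx[0])
            kin = fdm.deformation_gradient(u, grid)
            N = fdm.neo_hookean_stress(kin, 500.0, 1200.0)
            return fdm.divergence_of_stress(N, grid)

        n = 9
        coarse = force_residual(n)
        mid = force_residual(2 * (n - 1) + 1)
        fine = force_residual(4 * (n - 1) + 1)
        # compare on shared interior coarse nodes
        sl_c = (slice(None),) + (slice(2, -2),) * 3
        mid_on_c = mid[:, ::2, ::2, ::2][sl_c]
        fine_on_c = fine[:, ::4, ::4, ::4][sl_c]
        e_h = np.abs(coarse[sl_c] - fine_on_c).max()
        e_h2 = np.abs(mid_on_c - fine_on_c).max()
        assert e_h2 < 0.5 * e_h  # order >= 1 (central stencils: expect ~2)


class TestFusedKernel:
    def test_matches_reference_path_bitwise(self, rng):
        """The numba fast path reproduces the numpy reference step."""
        shape = (8, 9, 10)
        grid = fdm.SimulationGrid(shape, (0.009, 0.008, 0.01))
        u = 0.001 * rng.standard_normal((3, *shape))
        u_prev = u - 1e-5 * rng.standard_normal((3, *shape))
        mu = np.full(shape, 300.0)
        mu[:3] = 30.0
        lam = fdm.lame_lambda_from_mu(mu, 0.49)
        rho = np.full(shape, 1000.0)
        rho[:3] = 100.0
        f = 0.1 * rng.standard_normal((3, *shape))
        r = np.full(shape, 50.0)
        fixed = fdm.boundary_mask(shape)
        hyper = np.ones(shape, bool)
        hyper[:3] = False

        K = fdm.assemble_nodal_force(u, grid, mu, lam, rho, f, hyperelastic_mask=hyper)
        st = fdm.DisplacementState(u=u.copy(), u_prev=u_prev.copy(), h_t=2e-4)
        ref = fdm.explicit_step(st, K, rho, r, fixed)

        N = np.empty((3, 3, *shape))
        out = np.empty((3, *shape))
        jmin, _ = fused_step(
            u, u_prev, mu, lam, rho, r, f, fixed, hyper, grid.spacing, 2e-4, N, out
        )
        assert jmin > 0
        assert np.abs(out - ref.u).max() < 1e-15
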