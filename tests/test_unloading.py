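"""Prediction-correction gravity unloading: configuration pullback,
quasi-static detection, and physical consistency oracles."""

import numpy as np
import pytest

from bresym import fdm_mechanics as fdm
from bresym.fdm_mechanics import DisplacementState, SimulationGrid, boundary_mask
from bresym.phantom import forward_gravity_loading
from bresym.unloading import (
    MaterialConfiguration,
    UnloadingParams,
    UnloadingSimulation,
    material_from_labels,
    quasi_static_reached,
    update_configuration,
)
from bresym.volumes_io import LABEL_ADIPOSE, LABEL_BACKGROUND, LABEL_CHEST


def slab_labels(shape=(12, 12, 12), chest_top=2, tissue_top=8):
    labels = np.full(shape, LABEL_BACKGROUND, dtype=int)
    labels[:, :, : chest_top + 1] = LABEL_CHEST
    labels[:, :, chest_top + 1 : tissue_top + 1] = LABEL_ADIPOSE
    return labels


class TestUpdateConfiguration:
    def _material(self, grid):
        return material_from_labels(
            slab_labels(grid.shape), grid, 200.0, 0.49, np.array([0, 0, -9.81])
        )

    def test_zero_dvf_is_identity(self):
        grid = SimulationGrid((12, 12, 12), (5e-3,) * 3)
        m0 = self._material(grid)
        m1 = update_configuration(m0, np.zeros((3, *grid.shape)))
        assert np.allclose(m1.mu, m0.mu)
        assert np.allclose(m1.rho, m0.rho)
        assert np.array_equal(m1.labels, m0.labels)

    def test_labels_resampled_without_new_codes(self, rng):
        grid = SimulationGrid((12, 12, 12), (5e-3,) * 3)
        m0 = self._material(grid)
        dvf = 4.0 * rng.standard_normal((3, *grid.shape))
        m1 = update_configuration(m0, dvf)
        assert set(np.unique(m1.labels)) <= set(np.unique(m0.labels))

    def test_translation_moves_interface_by_offset(self):
        grid = SimulationGrid((12, 12, 12), (5e-3,) * 3)
        m0 = self._material(grid)
        dvf = np.zeros((3, *grid.shape))
        dvf[2] = 2 * 5.0  # sample two cells further up
        m1 = update_configuration(m0, dvf)
        # tissue/background interface at k=8 moves down to k=6
        assert np.all(m1.labels[:, :, 6] == LABEL_ADIPOSE)
        assert np.all(m1.labels[5, 5, 7:] == LABEL_BACKGROUND)


class TestQuasiStatic:
    def test_frozen_state_is_quasi_static(self):
        grid = SimulationGrid((5, 5, 5), (1e-3,) * 3)
        st = DisplacementState.zeros(grid, 1e-4)
        st.step = 10
        assert quasi_static_reached(st, 1e-6)

    def test_drifting_state_is_not(self):
        grid = SimulationGrid((5, 5, 5), (1e-3,) * 3)
        u = np.full((3, *grid.shape), 1e-3)
        st = DisplacementState(u=u, u_prev=np.zeros_like(u), h_t=1e-3, step=10)
        assert not quasi_static_reached(st, 0.5)  # speed ~ 1.7 m/s
        assert quasi_static_reached(st, 10.0)

    def test_oscillator_flag_flips_at_predicted_settling_time(self):
        """For an analytic damped oscillator the quasi-static flag flips
        permanently once the velocity envelope drops below tolerance."""
        omega, zeta, u0 = 2 * np.pi, 0.3, 1.0e-2
        wd = omega * np.sqrt(1 - zeta**2)
        h_t = 1e-3
        tol = 1e-4
        # velocity amplitude ~ u0 * omega * exp(-zeta omega t)
        t_star = np.log(u0 * omega / tol) / (zeta * omega)
        t = np.arange(0, 2 * t_star, h_t)
        u = u0 * np.exp(-zeta * omega * t) * np.cos(wd * t)
        flips = []
        for n in range(1, len(t)):
            st = DisplacementState(
                u=np.full((3, 2, 2, 2), u[n]),
                u_prev=np.full((3, 2, 2, 2), u[n - 1]),
                h_t=h_t,
                step=n,
            )
            flips.append(quasi_static_reached(st, np.sqrt(3) * tol))
        flips = np.asarray(flips)
        last_false = np.where(~flips)[0][-1]
        t_flip = t[last_false + 1]
        assert t_flip == pytest.approx(t_star, rel=0.2)


class TestForwardLoadingOracles:
    def test_confined_slab_matches_linear_elastic_closed_form(self):
        """A laterally wide slab under weak gravity compresses like the
        1-D confined column: u(surface) = rho g L^2 / (2 (lambda + 2 mu))."""
        shape = (25, 25, 16)
        h = 3e-3
        labels = np.full(shape, LABEL_BACKGROUND, dtype=int)
        labels[:, :, :3] = LABEL_CHEST
        labels[:, :, 3:13] = LABEL_ADIPOSE  # 10 cells = 30 mm of tissue
        grid = SimulationGrid(shape, (h,) * 3)
        mu = 4000.0  # stiff -> strain < 1%: small-strain regime
        nu = 0.3  # moderate compressibility: collocated central differences
        # overestimate compliance near nu = 0.5, see docs/methods.md
        g = 0.5
        dvf, conv, _ = forward_gravity_loading(
            labels, grid, mu, np.array([0, 0, -g]), poisson=nu,
            tol_speed=1e-6, max_steps=20000,
        )
        assert conv
        lam = float(fdm.lame_lambda_from_mu(mu, nu))
        L = 10 * h
        expected = -1000.0 * g * L**2 / (2 * (lam + 2 * mu)) * 1e3  # mm
        centre = dvf[2, 12, 12, 12]  # top tissue layer, centre column
        assert centre == pytest.approx(expected, rel=0.10)

    def test_monotone_settling_after_ramp(self):
        """With default damping the max nodal speed is non-increasing over
        100-step windows once the gravity ramp has completed."""
        shape = (10, 10, 10)
        labels = slab_labels(shape)
        grid = SimulationGrid(shape, (5e-3,) * 3)
        m = material_from_labels(labels, grid, 300.0, 0.49, np.array([0, 0, -9.81]))
        from bresym.unloading import near_critical_damping

        damping = np.broadcast_to(
            np.asarray(near_critical_damping(labels, grid, 300.0, m.rho, 2)), shape
        ).copy()
        fixed = boundary_mask(shape) | (labels == LABEL_CHEST)
        h_t = fdm.critical_time_step(m.mu, m.lam, m.rho, grid)
        st = DisplacementState.zeros(grid, h_t)
        ramp = 300
        window_max = []
        current = 0.0
        for n in range(1, 2501):
            scale = min(1.0, st.step / ramp)
            K = fdm.assemble_nodal_force(
                st.u, grid, m.mu, m.lam, m.rho, scale * m.body_force,
                hyperelastic_mask=labels != LABEL_BACKGROUND,
            )
            st = fdm.explicit_step(st, K, m.rho, damping, fixed)
            current = max(current, st.max_speed)
            if n % 100 == 0:
                if n > ramp + 200:
                    window_max.append(current)
                current = 0.0
        diffs = np.diff(window_max)
        assert np.all(diffs <= 1e-12)


class TestUnloadingLoop:
    def _make_sim(self, mu=300.0, gravity=(0, 0, -9.81), shape=(12, 12, 12)):
        labels = slab_labels(shape)
        grid = SimulationGrid(shape, (5e-3,) * 3)
        g = np.asarray(gravity, dtype=float)
        m0 = material_from_labels(labels, grid, mu, 0.49, g)
        params = UnloadingParams()
        params.solver.max_steps = 4000
        fixed = labels == LABEL_CHEST
        return UnloadingSimulation(m0, params, g, fixed_mask=fixed)

    def test_zero_gravity_yields_identity(self):
        sim = self._make_sim(gravity=(0.0, 0.0, 0.0))
        res = sim.run_until_quasistatic(600)
        assert np.abs(res.dvf_mm).max() < 1e-9

    def test_unloading_converges_and_contracts_against_gravity(self):
        sim = self._make_sim()
        res = sim.run_until_quasistatic()
        assert res.converged
        # gravity pulls -z: the dvf (unloaded -> loaded sampling map) points down
        tissue = sim.material.labels == LABEL_ADIPOSE
        assert res.dvf_mm[2][tissue].mean() < 0
        assert res.n_resamples > 2

    def test_volume_change_stays_bounded_in_tissue(self):
        """|J - 1| < 0.25 in tissue for the near-incompressible material."""
        sim = self._make_sim()
        sim.run_until_quasistatic()
        J = fdm.deformation_gradient(sim.state.u, sim.grid).J
        tissue = sim.material.labels >= 2
        assert np.abs(J[tissue] - 1).max() < 0.25

    def test_checkpoint_restore_reproduces_run_exactly(self):
        """Resuming from a snapshot gives bit-identical evolution."""
        sim = self._make_sim()
        for _ in range(3):
            sim.step_block()
        snap = sim.snapshot()
        for _ in range(2):
            sim.step_block()
        dvf_direct = sim.dvf_mm.copy()
        sim.restore(snap)
        for _ in range(2):
            sim.step_block()
        assert np.array_equal(sim.dvf_mm, dvf_direct)

    def test_fixed_point_is_stable_under_continued_iteration(self):
        """Once converged, further resampling changes the dvf by less than
        the convergence tolerance (idempotence at the fixed point)."""
        sim = self._make_sim()
        sim.run_until_quasistatic()
        dvf_before = sim.dvf_mm.copy()
        for _ in range(3):
            sim.step_block()
        change = np.abs(sim.dvf_mm - dvf_before).max()
        assert change < 2 * sim.params.tol_config_mm
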