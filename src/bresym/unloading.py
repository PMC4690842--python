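"""Iterative prediction-correction gravity unloading.

One forward loading simulation is run from the currently estimated unloaded
configuration; at regular intervals the *loaded* material configuration

    M_m(X) = {lambda_m(X), mu_m(X), rho_m(X), f_m(X)}

is pulled back through the current displacement field,

    M_{m+1}(X) = M_0(X + U(X)),

which contracts the estimate towards the true unloaded geometry. Because the
simulation displacement is the forward map (unloaded estimate -> loaded), the
pullback is a plain resampling step and no explicit field inversion is ever
required. The loop terminates when the dynamic simulation is quasi-static and
the configuration update has become small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import fdm_mechanics as fdm
from ._kernels import fused_step
from .chest_constraint import ConstraintState, apply_constraint
from .fdm_mechanics import (
    DisplacementState,
    SimulationGrid,
    SolverParams,
    boundary_mask,
    critical_time_step,
    explicit_step,
    lame_lambda_from_mu,
)
from .volumes_io import (
    LABEL_BACKGROUND,
    LABEL_CHEST,
    ImageVolume,
    LabelVolume,
    invert_displacement_field,
    pullback_resample,
    resample_to_grid,
)

__all__ = [
    "MaterialConfiguration",
    "UnloadingResult",
    "UnloadingParams",
    "UnloadingSimulation",
    "material_from_labels",
    "update_configuration",
    "quasi_static_reached",
    "unload",
    "grid_volume",
    "dvf_to_grid",
]

GRAVITY = 9.81  # m/s^2

# background ("air") material: soft and light enough not to resist the breast,
# compressible (low Poisson ratio) and heavy enough that the explicit scheme
# stays regular where the skin advances through it; its wave speed stays well
# below the tissue dilatational speed, so the CFL step is governed by tissue
BACKGROUND_SOFTENING = 10.0
BACKGROUND_POISSON = 0.3
BACKGROUND_RHO_FRACTION = 0.1
RHO_TISSUE = 1000.0  # kg/m^3, soft tissue ~ water
# chest shares the tissue modulus: its interface nodes are constrained anyway
# and a stiffer chest would only shrink the critical time step
CHEST_STIFFENING = 1.0


@dataclass
class MaterialConfiguration:
    """Per-node Lame fields, density and body force on one simulation grid."""

    grid: SimulationGrid
    mu: np.ndarray  # Pa
    lam: np.ndarray  # Pa
    rho: np.ndarray  # kg/m^3
    body_force: np.ndarray  # (3, ...) N/kg
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.mu < 0) or np.any(self.lam < 0):
            raise ValueError("Lame fields must be non-negative")
        if np.any(self.rho <= 0):
            raise ValueError("density must be positive")


@dataclass
class UnloadingResult:
    """Outcome of one unloading run.

    dvf_mm is the pullback field on the simulation grid: sampling the loaded
    volume at X + dvf(X) yields the unloaded estimate at X (the forward map
    of the simulation, stored loaded-from-unloaded).
    """

    dvf_mm: np.ndarray
    converged: bool
    n_steps: int
    n_resamples: int
    residual_speed: float
    config_update_mm: float


@dataclass
class UnloadingParams:
    """Loop controls (defaults are the package-wide study conditions)."""

    solver: SolverParams = field(default_factory=SolverParams)
    resample_interval: int = 50  # steps between configuration updates
    resample_max_cells: float = 0.25  # or when u moved this many cells
    tol_speed: float = 1e-4  # m/s quasi-static residual
    tol_config_mm: float = 0.1  # mean config-update displacement
    ramp_fraction: float = 0.1  # gravity ramped over this share of max_steps
    poisson: float = 0.49
    # per-node speed cap (m/s): limits kinetic excursions of very soft
    # material during the transient (dynamic relaxation); does not affect the
    # quasi-static solution the loop converges to
    max_node_speed: float = 0.05


def material_from_labels(
    labels: np.ndarray,
    grid: SimulationGrid,
    mu_tissue: float,
    poisson: float = 0.49,
    gravity_vec: np.ndarray | None = None,
) -> MaterialConfiguration:
    """Homogeneous tissue material from a 4-class label grid.

    Fat and gland share one global shear modulus; chest is an order of
    magnitude stiffer (its interface nodes are constrained anyway); the
    background is ~100x softer and lighter so the skin can move freely inside
    the grid. Gravity acts on tissue and chest only (air is weightless).
    """
    labels = np.asarray(labels)
    mu = np.full(grid.shape, mu_tissue, dtype=float)
    rho = np.full(grid.shape, RHO_TISSUE, dtype=float)
    bg = labels == LABEL_BACKGROUND
    chest = labels == LABEL_CHEST
    mu[bg] = mu_tissue / BACKGROUND_SOFTENING
    mu[chest] = mu_tissue * CHEST_STIFFENING
    rho[bg] = RHO_TISSUE * BACKGROUND_RHO_FRACTION
    lam = lame_lambda_from_mu(mu, poisson)
    lam[bg] = lame_lambda_from_mu(mu[bg], BACKGROUND_POISSON)
    f = np.zeros((3, *grid.shape))
    if gravity_vec is not None:
        f[:, ~bg] = np.asarray(gravity_vec, dtype=float)[:, None]
    return MaterialConfiguration(
        grid=grid, mu=mu, lam=lam, rho=rho, body_force=f, labels=labels.copy()
    )


def update_configuration(
    m0: MaterialConfiguration, dvf_mm: np.ndarray
) -> MaterialConfiguration:
    """Eq-(9)-style pullback: every field of the loaded configuration is
    resampled at X + dvf(X); labels use nearest-neighbour interpolation."""
    grid = m0.grid
    if dvf_mm.shape != (3, *grid.shape):
        raise ValueError("dvf grid does not match the material grid")
    spacing_mm = np.asarray(grid.spacing_mm)
    idx = np.indices(grid.shape, dtype=float)
    sample_idx = idx + np.asarray(dvf_mm) / spacing_mm[:, None, None, None]

    def pull(a: np.ndarray, order: int) -> np.ndarray:
        return ndimage.map_coordinates(
            a.astype(float, copy=False), sample_idx, order=order, mode="nearest", prefilter=False
        )

    labels = None
    if m0.labels is not None:
        labels = np.rint(pull(m0.labels, 0)).astype(m0.labels.dtype)
    return MaterialConfiguration(
        grid=grid,
        mu=pull(m0.mu, 1),
        lam=pull(m0.lam, 1),
        rho=pull(m0.rho, 1),
        body_force=np.stack([pull(m0.body_force[a], 1) for a in range(3)]),
        labels=labels,
    )


def characteristic_thickness(
    labels: np.ndarray | None, grid: SimulationGrid, gravity_axis: int = 1
) -> float:
    """Mean tissue thickness along the gravity axis (m): tissue volume over
    its projected footprint. Sets the wavelength of the slowest structural
    mode of the chest-clamped breast, hence the near-critical damping rate."""
    if labels is None:
        return 0.25 * max(grid.spacing[a] * grid.shape[a] for a in range(3))
    tissue = np.asarray(labels) >= 2
    if not tissue.any():
        return 0.25 * max(grid.spacing[a] * grid.shape[a] for a in range(3))
    footprint = tissue.any(axis=gravity_axis)
    cell_area = np.prod([grid.spacing[a] for a in range(3) if a != gravity_axis])
    volume = tissue.sum() * np.prod(grid.spacing)
    thickness = volume / (footprint.sum() * cell_area)
    return float(max(thickness, min(grid.spacing)))


def near_critical_damping(
    labels: np.ndarray | None,
    grid: SimulationGrid,
    mu_tissue: float,
    rho: np.ndarray | float,
    gravity_axis: int = 1,
) -> np.ndarray | float:
    """Per-node damping r = 2 rho omega with omega = c_s / thickness, the
    shear-wave estimate of the slowest mode's frequency."""
    c_s = np.sqrt(mu_tissue / RHO_TISSUE)
    omega = c_s / characteristic_thickness(labels, grid, gravity_axis)
    return 2.0 * np.asarray(rho) * omega


def quasi_static_reached(state: DisplacementState, tolerance: float) -> bool:
    """True iff the maximum nodal speed |U^n - U^{n-1}| / h_t < tolerance."""
    if state.step < 2:
        return False
    return state.max_speed < tolerance


def grid_volume(grid: SimulationGrid, data: np.ndarray) -> ImageVolume:
    """Wrap a simulation-grid field as an ImageVolume (mm geometry)."""
    return ImageVolume(data=data, spacing=grid.spacing_mm, origin=grid.origin_mm)


def dvf_to_grid(
    dvf_mm: np.ndarray, grid: SimulationGrid, target: ImageVolume
) -> np.ndarray:
    """Linearly interpolate a simulation-grid DVF (mm) onto a target grid."""
    comps = [
        resample_to_grid(grid_volume(grid, dvf_mm[a]), target, "linear", 0.0).data
        for a in range(3)
    ]
    return np.stack(comps)


class UnloadingSimulation:
    """One side's continuous forward simulation with interleaved resampling.

    The object owns the *loaded* configuration M_0 (material, labels and the
    accumulated image-force record) and the running displacement state; the
    registration driver composes two of these symmetrically and feeds image
    forces into them.
    """

    def __init__(
        self,
        m0: MaterialConfiguration,
        params: UnloadingParams,
        gravity_vec: np.ndarray,
        constraint: ConstraintState | None = None,
        fixed_mask: np.ndarray | None = None,
    ):
        self.grid = m0.grid
        self.params = params
        self.m0 = m0
        self.material = MaterialConfiguration(
            grid=m0.grid,
            mu=m0.mu.copy(),
            lam=m0.lam.copy(),
            rho=m0.rho.copy(),
            body_force=m0.body_force.copy(),
            labels=None if m0.labels is None else m0.labels.copy(),
        )
        self.gravity_vec = np.asarray(gravity_vec, dtype=float)
        self.constraint = constraint
        self.dirichlet = boundary_mask(self.grid.shape)
        if fixed_mask is not None:
            self.dirichlet = self.dirichlet | fixed_mask
        # image-force record, loaded configuration (N/kg)
        self.f_img_loaded = np.zeros((3, *self.grid.shape))
        self._f_img_current = np.zeros_like(self.f_img_loaded)
        self._f_increment = np.zeros_like(self.f_img_loaded)
        self._increment_start = 0
        self._increment_ramp = max(params.resample_interval, 1)
        self._ht_cap = np.inf
        self.sponge_width = 3
        self.sponge_factor = 20.0
        self._setup_time_step()
        self._setup_damping()
        if self.params.solver.damping is not None:
            self._refresh_damping_array()
        self._scratch_N = np.empty((3, 3, *self.grid.shape))
        self._u_out = np.empty((3, *self.grid.shape))
        self.state = DisplacementState.zeros(self.grid, self.h_t)
        self.u_at_resample = self.state.u.copy()
        self.n_resamples = 0
        self.ramp_steps = max(1, int(params.ramp_fraction * params.solver.max_steps))
        self.last_config_update_mm = np.inf

    # -- setup -------------------------------------------------------------
    def _setup_time_step(self) -> None:
        self.h_t = critical_time_step(
            self.material.mu,
            self.material.lam,
            self.material.rho,
            self.grid,
            self.params.solver.safety,
        )

    def _setup_damping(self) -> None:
        if self.params.solver.damping is not None:
            self.damping = self.params.solver.damping
            return
        labels = self.m0.labels
        if labels is not None and (labels >= 2).any():
            mu_t = float(np.max(self.m0.mu[labels >= 2]))
        else:
            mu_t = float(np.max(self.m0.mu))
        axis = int(np.argmax(np.abs(self.gravity_vec))) if self.gravity_vec.any() else 1
        self.damping = near_critical_damping(
            labels, self.grid, mu_t, self.material.rho, axis
        )
        self._refresh_damping_array()

    def _refresh_damping_array(self) -> None:
        arr = np.array(
            np.broadcast_to(np.asarray(self.damping, dtype=float), self.grid.shape)
        )
        # sponge layer: the few node layers against the Dirichlet wall carry
        # weakly damped short-wavelength modes; overdamping them is harmless
        # (they sit in the padding) and lets the bulk reach quasi-static
        sponge = boundary_mask(self.grid.shape, width=self.sponge_width)
        arr[sponge] *= self.sponge_factor
        self._damping_arr = arr

    # -- state views ---------------------------------------------------------
    @property
    def dvf_mm(self) -> np.ndarray:
        """Pullback DVF (loaded-from-unloaded), mm, simulation grid."""
        return self.state.u * 1e3

    def gravity_scale(self) -> float:
        return min(1.0, self.state.step / self.ramp_steps)

    def _image_force_now(self) -> np.ndarray:
        if not self._f_increment.any():
            return self._f_img_current
        s = min(1.0, (self.state.step - self._increment_start) / self._increment_ramp)
        return self._f_img_current + s * self._f_increment

    def body_force_now(self) -> np.ndarray:
        f = self.gravity_scale() * self.material.body_force
        f_img = self._image_force_now()
        if f_img.any():
            f = f + f_img
        return f

    def hyperelastic_mask(self) -> np.ndarray:
        """Tissue/chest nodes of the current configuration (neo-Hookean);
        the background outside is the linear-elastic filler medium."""
        if self.material.labels is None:
            return np.ones(self.grid.shape, dtype=bool)
        return self.material.labels != LABEL_BACKGROUND

    # -- stepping ------------------------------------------------------------
    def step(self) -> None:
        """One fused explicit step (identical math to the reference path in
        :mod:`fdm_mechanics`, see the equivalence test)."""
        jmin, worst = fused_step(
            self.state.u,
            self.state.u_prev,
            self.material.mu,
            self.material.lam,
            self.material.rho,
            self._damping_arr,
            self.body_force_now(),
            self.dirichlet,
            self.hyperelastic_mask(),
            self.grid.spacing,
            self.h_t,
            self._scratch_N,
            self._u_out,
        )
        if jmin <= 0.0:
            raise fdm.ElementInversionError(worst, jmin)
        u_next = self._u_out.copy()
        cap = self.params.max_node_speed * self.h_t
        if cap > 0:
            du = u_next - self.state.u
            norm = np.sqrt((du**2).sum(axis=0))
            over = norm > cap
            if over.any():
                du[:, over] *= cap / norm[over]
                u_next = self.state.u + du
        if self.state.step % 100 == 0 and not np.isfinite(u_next).all():
            raise fdm.DivergenceError(
                "non-finite displacement: reduce the time step or increase damping"
            )
        self.state = DisplacementState(
            u=u_next, u_prev=self.state.u, h_t=self.h_t, step=self.state.step + 1
        )
        if self.constraint is not None:
            self.state.u = apply_constraint(
                self.state.u, self.state.u_prev, self.h_t, self.constraint
            )

    def set_time_step(self, h_t_new: float) -> None:
        """Change h_t keeping the nodal velocity continuous."""
        if h_t_new == self.state.h_t:
            return
        vel = (self.state.u - self.state.u_prev) / self.state.h_t
        self.state = DisplacementState(
            u=self.state.u,
            u_prev=self.state.u - vel * h_t_new,
            h_t=h_t_new,
            step=self.state.step,
        )
        self.h_t = h_t_new

    def _adapt_time_step(self) -> None:
        """Shrink h_t when the tissue is strongly compressed: the tangent
        stiffness of a compressed neo-Hookean material grows ~1/J^2, so the
        rest-state CFL bound is no longer sufficient."""
        J = fdm.deformation_gradient(self.state.u, self.grid).J
        mask = self.hyperelastic_mask()
        j_min = float(J[mask].min()) if mask is not None and mask.any() else float(J.min())
        base = critical_time_step(
            self.material.mu,
            self.material.lam,
            self.material.rho,
            self.grid,
            self.params.solver.safety,
        )
        scale = float(np.clip(j_min, 0.15, 1.0))
        self.set_time_step(min(base * scale, self._ht_cap))

    def needs_resample(self) -> bool:
        if self.state.step == 0:
            return False
        if self.state.step % self.params.resample_interval == 0:
            return True
        drift = np.abs(self.state.u - self.u_at_resample).max()
        return drift > self.params.resample_max_cells * min(self.grid.spacing)

    def resample(self) -> float:
        """Pull the loaded configuration back through the current U (Eq 9).

        Returns the mean configuration-update displacement in mm (the change
        of the DVF since the previous resample).
        """
        self.material = update_configuration(self.m0, self.dvf_mm)
        if self.material.labels is not None:
            # gravity must stay consistent with the resampled labels: a
            # linearly interpolated force field would put weight on (light)
            # background nodes near the skin and make them fall indefinitely
            f = np.zeros_like(self.material.body_force)
            f[:, self.material.labels != LABEL_BACKGROUND] = self.gravity_vec[:, None]
            self.material.body_force = f
        self._pull_image_force()
        update = self.state.u - self.u_at_resample
        mean_update_mm = float(np.sqrt((update**2).sum(axis=0)).mean() * 1e3)
        self.u_at_resample = self.state.u.copy()
        self.n_resamples += 1
        self.last_config_update_mm = mean_update_mm
        return mean_update_mm

    def step_block(self) -> None:
        """Advance until the next scheduled resample, then resample.

        If the explicit scheme inverts an element mid-block, the block is
        rolled back to its start and retried with a halved time step.
        """
        for attempt in range(6):
            snapshot = (self.state.u.copy(), self.state.u_prev.copy(), self.state.step)
            try:
                for _ in range(self.params.resample_interval):
                    self.step()
                    if self.needs_resample():
                        break
                break
            except fdm.ElementInversionError:
                if attempt == 5:
                    raise
                u, u_prev, step = snapshot
                self.state = DisplacementState(u=u, u_prev=u_prev, h_t=self.h_t, step=step)
                self._ht_cap = 0.5 * self.h_t
                self.set_time_step(self._ht_cap)
        self._adapt_time_step()
        self.resample()

    def converged(self) -> bool:
        return (
            self.state.step > self.ramp_steps
            and quasi_static_reached(self.state, self.params.tol_speed)
            and self.last_config_update_mm < self.params.tol_config_mm
        )

    def _settle(self, budget: int) -> bool:
        """Step with a frozen configuration until quasi-static: the periodic
        pullback perturbs interface nodes (label flips), so the final approach
        to equilibrium must run without it.

        The settle is only valid near the fixed point. If the field drifts by
        more than one grid cell (the bulk is still moving, e.g. under a much
        too soft material) or an element inverts, the state is the settle
        start / last good state and False is returned so the caller resumes
        resampling.
        """
        u_start = self.state.u.copy()
        snapshot = (self.state.u.copy(), self.state.u_prev.copy(), self.state.step)
        drift_cap = min(self.grid.spacing)
        for n in range(budget):
            try:
                self.step()
            except fdm.ElementInversionError:
                u, u_prev, step = snapshot
                self.state = DisplacementState(u=u, u_prev=u_prev, h_t=self.h_t, step=step)
                return False
            if n % 50 == 49:
                if float(np.abs(self.state.u - u_start).max()) > drift_cap:
                    return False
                snapshot = (self.state.u.copy(), self.state.u_prev.copy(), self.state.step)
                if n % 200 == 199:
                    self._adapt_time_step()
            if quasi_static_reached(self.state, self.params.tol_speed):
                return True
        return quasi_static_reached(self.state, self.params.tol_speed)

    def run_until_quasistatic(self, max_steps: int | None = None) -> UnloadingResult:
        """Alternate resampling blocks and frozen settles until both the
        configuration update and the residual speed are below tolerance (or
        the step budget runs out; intermediate states of the pipeline are
        allowed to stop on budget)."""
        limit = max_steps if max_steps is not None else self.params.solver.max_steps
        start = self.state.step
        upd_hist: list[float] = []
        while self.state.step - start < limit:
            self.step_block()
            upd_hist.append(self.last_config_update_mm)
            plateau = (
                len(upd_hist) >= 6
                and self.state.step > self.ramp_steps
                and np.std(upd_hist[-4:]) < 0.05 * (np.mean(upd_hist[-4:]) + 1e-12)
            )
            if self.last_config_update_mm < self.params.tol_config_mm or plateau:
                remaining = limit - (self.state.step - start)
                self._settle(min(max(remaining, 0), 4000))
                self.resample()
                upd_hist.clear()
                if self.converged():
                    break
        return UnloadingResult(
            dvf_mm=self.dvf_mm.copy(),
            converged=self.converged(),
            n_steps=self.state.step,
            n_resamples=self.n_resamples,
            residual_speed=self.state.max_speed,
            config_update_mm=self.last_config_update_mm,
        )

    # -- checkpointing ---------------------------------------------------------
    def snapshot(self) -> dict:
        """Deep copy of the evolving state (for rollback or resume)."""
        m = self.material
        return {
            "u": self.state.u.copy(),
            "u_prev": self.state.u_prev.copy(),
            "step": self.state.step,
            "h_t": self.h_t,
            "ht_cap": self._ht_cap,
            "material": (
                m.mu.copy(),
                m.lam.copy(),
                m.rho.copy(),
                m.body_force.copy(),
                None if m.labels is None else m.labels.copy(),
            ),
            "f_img_loaded": self.f_img_loaded.copy(),
            "f_img_current": self._f_img_current.copy(),
            "f_increment": self._f_increment.copy(),
            "increment_start": self._increment_start,
            "increment_ramp": self._increment_ramp,
            "u_at_resample": self.u_at_resample.copy(),
            "n_resamples": self.n_resamples,
            "last_config_update_mm": self.last_config_update_mm,
        }

    def restore(self, snap: dict) -> None:
        mu, lam, rho, f, labels = snap["material"]
        self.material = MaterialConfiguration(
            grid=self.grid, mu=mu.copy(), lam=lam.copy(), rho=rho.copy(),
            body_force=f.copy(), labels=None if labels is None else labels.copy(),
        )
        self.h_t = snap["h_t"]
        self._ht_cap = snap["ht_cap"]
        self.state = DisplacementState(
            u=snap["u"].copy(), u_prev=snap["u_prev"].copy(),
            h_t=snap["h_t"], step=snap["step"],
        )
        self.f_img_loaded = snap["f_img_loaded"].copy()
        self._f_img_current = snap["f_img_current"].copy()
        self._f_increment = snap["f_increment"].copy()
        self._increment_start = snap["increment_start"]
        self._increment_ramp = snap["increment_ramp"]
        self.u_at_resample = snap["u_at_resample"].copy()
        self.n_resamples = snap["n_resamples"]
        self.last_config_update_mm = snap["last_config_update_mm"]

    # -- material updates ------------------------------------------------------
    def scale_material(self, factor: float) -> None:
        """Multiply tissue mu and lambda by ``factor`` (loaded and current
        fields); the time step and damping are re-derived."""
        for cfg in (self.m0, self.material):
            bg = cfg.labels == LABEL_BACKGROUND if cfg.labels is not None else None
            if bg is None:
                cfg.mu *= factor
                cfg.lam *= factor
            else:
                cfg.mu[~bg] *= factor
                cfg.lam[~bg] *= factor
        old_ht = self.h_t
        self._setup_time_step()
        self._setup_damping()
        if self.h_t != old_ht:
            # keep nodal velocity continuous across the step change
            vel = (self.state.u - self.state.u_prev) / old_ht
            self.state = DisplacementState(
                u=self.state.u,
                u_prev=self.state.u - vel * self.h_t,
                h_t=self.h_t,
                step=self.state.step,
            )

    # -- image forces -----------------------------------------------------------
    def deformation_gradient(self) -> fdm.KinematicsField:
        return fdm.deformation_gradient(self.state.u, self.grid)

    def begin_force_increment(self, f_ssd_sim: np.ndarray, ramp_steps: int) -> None:
        """Fold the previous (fully ramped) increment into the loaded-frame
        record and start ramping a new one.

        The new force, evaluated in the central configuration, is transported
        by the side's deformation gradient F before accumulation; the record
        is kept in the loaded configuration, from which it is pulled back with
        every configuration update.
        """
        self._fold_increment()
        F = self.deformation_gradient().F
        f_new = np.einsum("ij...,j...->i...", F, np.asarray(f_ssd_sim))
        self._f_increment = f_new
        self._increment_start = self.state.step
        self._increment_ramp = max(1, ramp_steps)

    def _fold_increment(self) -> None:
        if not self._f_increment.any():
            return
        # push the current-frame increment forward into the loaded frame
        inv = invert_displacement_field(
            self.state.u * 1e3, self.grid.spacing_mm, iterations=10, tol_mm=0.05
        )
        spacing_mm = np.asarray(self.grid.spacing_mm)
        idx = np.indices(self.grid.shape, dtype=float)
        sample_idx = idx + inv / spacing_mm[:, None, None, None]
        pushed = np.stack(
            [
                ndimage.map_coordinates(
                    self._f_increment[a], sample_idx, order=1, mode="nearest", prefilter=False
                )
                for a in range(3)
            ]
        )
        self.f_img_loaded += pushed
        self._f_increment = np.zeros_like(self._f_increment)
        self._pull_image_force()

    def _pull_image_force(self) -> None:
        if not self.f_img_loaded.any():
            return
        spacing_mm = np.asarray(self.grid.spacing_mm)
        idx = np.indices(self.grid.shape, dtype=float)
        sample_idx = idx + self.dvf_mm / spacing_mm[:, None, None, None]
        self._f_img_current = np.stack(
            [
                ndimage.map_coordinates(
                    self.f_img_loaded[a], sample_idx, order=1, mode="nearest", prefilter=False
                )
                for a in range(3)
            ]
        )

    def scale_image_forces(self, factor: float) -> None:
        """Globally rescale the accumulated image forces (monotone-acceptance
        backoff in the driver)."""
        self.f_img_loaded *= factor
        self._f_img_current *= factor
        self._f_increment *= factor


# ---------------------------------------------------------------------------
# stand-alone unloading of one side
# ---------------------------------------------------------------------------


def unload(
    image: ImageVolume,
    labels: LabelVolume,
    mu_tissue: float,
    gravity_direction: np.ndarray,
    params: UnloadingParams | None = None,
    sim_spacing_mm: float = 9.07,
    constraint: ConstraintState | None = None,
    fix_chest: bool = True,
) -> tuple[UnloadingResult, ImageVolume, LabelVolume, UnloadingSimulation]:
    """Recover the virtually unloaded configuration of one loaded image.

    ``gravity_direction`` is the unit vector of gravity in the *loaded*
    orientation (anterior for prone, posterior for supine); the loading
    simulation applies it to the current estimate and the interleaved
    pullbacks contract the geometry to the unloaded state.
    """
    params = params or UnloadingParams()
    grid = _make_sim_grid(image, sim_spacing_mm)
    labels_sim = resample_to_grid(labels, grid_volume(grid, np.zeros(grid.shape)), "nearest")
    labels_sim_data = np.rint(labels_sim.data).astype(int)
    g = np.asarray(gravity_direction, dtype=float)
    g = GRAVITY * g / np.linalg.norm(g)
    m0 = material_from_labels(labels_sim_data, grid, mu_tissue, params.poisson, g)
    fixed = labels_sim_data == LABEL_CHEST if fix_chest else None
    sim = UnloadingSimulation(m0, params, g, constraint=constraint, fixed_mask=fixed)
    result = sim.run_until_quasistatic()
    dvf_img = dvf_to_grid(result.dvf_mm, grid, image)
    unloaded_image = pullback_resample(image, dvf_img, "linear")
    unloaded_labels_data = pullback_resample(
        ImageVolume(labels.data, labels.spacing, labels.origin, labels.orientation),
        dvf_img,
        "nearest",
    ).data
    unloaded_labels = LabelVolume(
        np.rint(unloaded_labels_data).astype(labels.data.dtype),
        labels.spacing,
        labels.origin,
        labels.orientation,
    )
    return result, unloaded_image, unloaded_labels, sim


def _make_sim_grid(image: ImageVolume, sim_spacing_mm: float) -> SimulationGrid:
    """Node grid at coarse spacing covering the image domain."""
    extent_mm = [image.spacing[a] * (image.shape[a] - 1) for a in range(3)]
    shape = tuple(max(3, int(np.floor(e / sim_spacing_mm)) + 1) for e in extent_mm)
    return SimulationGrid(
        shape=shape,
        spacing=(sim_spacing_mm * 1e-3,) * 3,
        origin_mm=tuple(image.origin),
    )
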