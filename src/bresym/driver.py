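"""Three-phase symmetric registration pipeline.

Phase 1 unloads the prone and the supine image under gravity with generic
material parameters; phase 2 repeatedly stiffens/softens the global tissue
modulus, keeping only steps that improve the central-configuration SSD;
phase 3 accumulates image-derived forces directly into both unloading
simulations over a multiscale force-grid schedule until the similarity stops
improving. Both sides are advanced together so the images meet in the shared
virtually unloaded frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import image_forces as imf
from .chest_constraint import ConstraintState, build_correction_field
from .evaluation import TREReport, tre, warp_landmarks
from .fdm_mechanics import SimulationGrid
from .material_optimisation import MaterialSchedule, OptimisationTrace, optimise_material
from .unloading import (
    GRAVITY,
    UnloadingParams,
    UnloadingSimulation,
    dvf_to_grid,
    grid_volume,
    material_from_labels,
)
from .volumes_io import (
    LABEL_CHEST,
    ImageVolume,
    LabelVolume,
    LandmarkSet,
    RigidTransform,
    apply_rigid,
    pullback_resample,
    resample_to_grid,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("bresym")


@dataclass
class PipelineConfig:
    """All tunables of the registration pipeline.

    Defaults are the phantom study conditions (simulation grid 9.07 mm, one
    force level at 9.07/4 mm); clinical-style runs would use
    ``sim_spacing_mm=8`` and ``force_levels_mm=(4, 2, 1)``.
    """

    sim_spacing_mm: float = 9.07
    force_levels_mm: tuple[float, ...] = (2.2675,)
    pad_cells: int = 2
    gravity_axis: int = 1  # AP
    prone_gravity_sign: float = +1.0  # anterior; supine uses the opposite
    gravity_magnitude: float = GRAVITY
    # material: start from the stiff extremal (the generic 357.1 Pa breast
    # modulus) and soften; softer states are then always reached by warm
    # start, which the explicit scheme tolerates far better than a cold start
    # with very soft tissue
    mu_init_pa: float = 357.1
    poisson: float = 0.49
    material_factor: float = 1.2
    material_direction: str = "soften"
    material_max_steps: int = 8
    # chest handling: 'fixed' (prescribed zero displacement), 'tied' or
    # 'sliding' surface constraint
    chest_mode: str = "fixed"
    constraint_p: float = 0.005
    constraint_v_max: float = 0.05
    constraint_l: float | None = None
    # solver / unloading loop
    safety: float = 0.5
    resample_interval: int = 50
    tol_speed: float = 1e-4
    tol_config_mm: float = 0.1
    phase1_max_steps: int = 6000
    settle_max_steps: int = 2500  # per material-update evaluation
    # image forces
    force_gamma: float | None = None  # None -> auto-calibrated from gravity
    force_gamma_fraction: float = 0.1  # initial force magnitude as share of g
    blocks_per_force_cycle: int = 1  # equilibration blocks per force update
    phase3_max_cycles: int = 150
    phase3_min_cycles: int = 5
    phase3_rel_tol: float = 2e-4
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["force_levels_mm"] = list(self.force_levels_mm)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        bad = sorted(set(d) - known)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        if "force_levels_mm" in d:
            d["force_levels_mm"] = tuple(d["force_levels_mm"])
        return cls(**d)


@dataclass
class PipelineResult:
    """Central images, per-side pullback DVFs and diagnostics."""

    central_prone: ImageVolume
    central_supine: ImageVolume
    dvf_prone_mm: np.ndarray  # pullback, simulation grid
    dvf_supine_mm: np.ndarray
    sim_grid: SimulationGrid
    ssd_trace: pd.DataFrame
    material_trace: OptimisationTrace | None
    tre_reports: list[TREReport]
    final_mu_pa: float
    converged: bool

    def tre_summary(self) -> pd.DataFrame:
        return pd.DataFrame([r.summary() for r in self.tre_reports])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _pad_volume(vol: ImageVolume, pad_mm: float, value: float) -> ImageVolume:
    pad_vox = tuple(int(np.ceil(pad_mm / s)) for s in vol.spacing)
    padded = np.pad(
        vol.data.astype(float),
        [(p, p) for p in pad_vox],
        mode="constant",
        constant_values=value,
    )
    origin = tuple(vol.origin[a] - pad_vox[a] * vol.spacing[a] for a in range(3))
    return ImageVolume(padded, vol.spacing, origin, vol.orientation)


def _pad_labels(lab: LabelVolume, pad_mm: float) -> LabelVolume:
    padded = _pad_volume(ImageVolume(lab.data, lab.spacing, lab.origin), pad_mm, 0)
    return LabelVolume(
        np.rint(padded.data).astype(lab.data.dtype), padded.spacing, padded.origin
    )


def _sim_grid_for(image: ImageVolume, spacing_mm: float) -> SimulationGrid:
    extent = [image.spacing[a] * (image.shape[a] - 1) for a in range(3)]
    shape = tuple(max(3, int(np.floor(e / spacing_mm)) + 1) for e in extent)
    return SimulationGrid(shape, (spacing_mm * 1e-3,) * 3, tuple(image.origin))


def _force_grid_for(sim_grid: SimulationGrid, level_mm: float) -> tuple[ImageVolume, int]:
    """Cell-centred fine grid tiling each simulation cell with k^3 voxels."""
    H = sim_grid.spacing_mm[0]
    k = int(round(H / level_mm))
    if k < 1 or abs(H / k - level_mm) > 0.05 * level_mm:
        raise ValueError(
            f"force level {level_mm} mm must refine the simulation spacing {H} mm "
            "by an integer factor"
        )
    h = H / k
    shape = tuple(n * k for n in sim_grid.shape)
    origin = tuple(sim_grid.origin_mm[a] - H / 2 + h / 2 for a in range(3))
    return ImageVolume(np.zeros(shape), (h,) * 3, origin), k


class _Side:
    """One side of the symmetric registration."""

    def __init__(
        self,
        name: str,
        image: ImageVolume,
        labels: LabelVolume,
        gravity_vec: np.ndarray,
        sim_grid: SimulationGrid,
        cfg: PipelineConfig,
        params: UnloadingParams,
    ):
        self.name = name
        self.image = image
        self.labels = labels
        lab_sim = resample_to_grid(
            ImageVolume(labels.data, labels.spacing, labels.origin),
            grid_volume(sim_grid, np.zeros(sim_grid.shape)),
            "nearest",
        )
        self.labels_sim = np.rint(lab_sim.data).astype(int)
        m0 = material_from_labels(
            self.labels_sim, sim_grid, cfg.mu_init_pa, cfg.poisson, gravity_vec
        )
        constraint: ConstraintState | None = None
        fixed = None
        if cfg.chest_mode == "fixed":
            fixed = self.labels_sim == LABEL_CHEST
        else:
            constraint = build_correction_field(
                self.labels_sim,
                sim_grid,
                p=cfg.constraint_p,
                v_max=cfg.constraint_v_max,
                logistic_l=cfg.constraint_l,
                mode="tied" if cfg.chest_mode == "tied" else "sliding",
            )
            # the chest *interface* slides; the chest interior behind it is
            # not breast tissue and stays prescribed-fixed
            fixed = constraint.chest_interior
        self.sim = UnloadingSimulation(
            m0, params, gravity_vec, constraint=constraint, fixed_mask=fixed
        )

    def central_image(self, target: ImageVolume) -> ImageVolume:
        dvf = dvf_to_grid(self.sim.dvf_mm, self.sim.grid, target)
        src = resample_to_grid(self.image, target, "linear", 0.0, dvf_mm=dvf)
        return src


def _evaluate_tre(
    sides: dict[str, _Side],
    landmarks: dict[str, LandmarkSet] | None,
    stage: str,
) -> TREReport | None:
    if not landmarks:
        return None
    central = {
        k: warp_landmarks(landmarks[k], sides[k].sim.dvf_mm, sides[k].sim.grid)
        for k in ("prone", "supine")
    }
    report = tre(central["prone"], central["supine"], stage=stage)
    log.info(
        "TRE %-12s mean %.2f  std %.2f  max %.2f mm",
        stage,
        report.mean,
        report.std,
        report.max,
    )
    return report


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    prone_image: ImageVolume,
    prone_labels: LabelVolume,
    supine_image: ImageVolume,
    supine_labels: LabelVolume,
    config: PipelineConfig | None = None,
    landmarks_prone: LandmarkSet | None = None,
    landmarks_supine: LandmarkSet | None = None,
    rigid_supine: RigidTransform | None = None,
    suppress_mask: np.ndarray | None = None,
) -> PipelineResult:
    """Register a prone/supine pair in the central unloaded configuration.

    Inputs must be rigidly pre-aligned on the chest (or ``rigid_supine``
    supplied); ``suppress_mask`` marks voxels (input grid) where image forces
    and similarity contributions are switched off (marker-clip protocol).
    """
    cfg = config or PipelineConfig()
    if rigid_supine is not None:
        supine_image = apply_rigid(supine_image, rigid_supine)
        lab = apply_rigid(
            ImageVolume(supine_labels.data, supine_labels.spacing, supine_labels.origin),
            rigid_supine,
            "nearest",
        )
        supine_labels = LabelVolume(
            np.rint(lab.data).astype(supine_labels.data.dtype), lab.spacing, lab.origin
        )

    # normalise intensities inside the body mask so the force weight transfers
    prone_image = imf.normalise_intensities(prone_image, prone_labels.breast_or_chest_mask)
    supine_image = imf.normalise_intensities(supine_image, supine_labels.breast_or_chest_mask)

    pad_mm = cfg.pad_cells * cfg.sim_spacing_mm
    p_img = _pad_volume(prone_image, pad_mm, 0.0)
    s_img = _pad_volume(supine_image, pad_mm, 0.0)
    p_lab = _pad_labels(prone_labels, pad_mm)
    s_lab = _pad_labels(supine_labels, pad_mm)
    mask_padded = None
    if suppress_mask is not None:
        mask_padded = (
            _pad_volume(
                ImageVolume(
                    suppress_mask.astype(float), prone_image.spacing, prone_image.origin
                ),
                pad_mm,
                0.0,
            ).data
            > 0.5
        )

    sim_grid = _sim_grid_for(p_img, cfg.sim_spacing_mm)
    params = UnloadingParams(
        resample_interval=cfg.resample_interval,
        tol_speed=cfg.tol_speed,
        tol_config_mm=cfg.tol_config_mm,
        poisson=cfg.poisson,
    )
    params.solver.safety = cfg.safety
    params.solver.max_steps = cfg.phase1_max_steps

    g_vec = np.zeros(3)
    g_vec[cfg.gravity_axis] = cfg.prone_gravity_sign * cfg.gravity_magnitude
    sides = {
        "prone": _Side("prone", p_img, p_lab, g_vec.copy(), sim_grid, cfg, params),
        "supine": _Side("supine", s_img, s_lab, -g_vec, sim_grid, cfg, params),
    }
    landmarks = None
    if landmarks_prone is not None and landmarks_supine is not None:
        landmarks = {"prone": landmarks_prone, "supine": landmarks_supine}

    ssd_rows: list[dict] = []
    tre_reports: list[TREReport] = []
    if (r := _evaluate_tre(sides, landmarks, "none")) is not None:
        tre_reports.append(r)

    force_grid0, _ = _force_grid_for(sim_grid, cfg.force_levels_mm[0])

    def central_ssd(force_grid: ImageVolume) -> tuple[float, ImageVolume, ImageVolume, np.ndarray | None]:
        p_c = sides["prone"].central_image(force_grid)
        s_c = sides["supine"].central_image(force_grid)
        msk = None
        if mask_padded is not None:
            m = resample_to_grid(
                ImageVolume(mask_padded.astype(float), p_img.spacing, p_img.origin),
                force_grid,
                "nearest",
            ).data
            msk = ~(m > 0.5)
        return imf.ssd(p_c, s_c, msk), p_c, s_c, msk

    # degenerate fast path: already aligned, nothing to do
    s0, _, _, _ = central_ssd(force_grid0)
    if s0 == 0.0 and cfg.gravity_magnitude == 0.0:
        ssd_rows.append({"phase": "init", "cycle": 0, "ssd": 0.0, "mu": cfg.mu_init_pa})
        return _finish(
            sides, sim_grid, p_img, s_img, ssd_rows, None, tre_reports, cfg.mu_init_pa, True
        )

    # ---------------- phase 1: generic-material unloading -----------------
    log.info("phase 1: gravity unloading (mu = %.1f Pa)", cfg.mu_init_pa)
    res_p = sides["prone"].sim.run_until_quasistatic(cfg.phase1_max_steps)
    res_s = sides["supine"].sim.run_until_quasistatic(cfg.phase1_max_steps)
    converged = res_p.converged and res_s.converged
    value, *_ = central_ssd(force_grid0)
    ssd_rows.append({"phase": "unloading", "cycle": 0, "ssd": value, "mu": cfg.mu_init_pa})
    if (r := _evaluate_tre(sides, landmarks, "unloading")) is not None:
        tre_reports.append(r)

    # ---------------- phase 2: material optimisation ----------------------
    current_mu = {"side": cfg.mu_init_pa}

    def evaluate(mu: float) -> float:
        factor = mu / current_mu["side"]
        if factor != 1.0:
            for s in sides.values():
                s.sim.scale_material(factor)
            current_mu["side"] = mu
            for s in sides.values():
                s.sim.run_until_quasistatic(cfg.settle_max_steps)
        v, *_ = central_ssd(force_grid0)
        ssd_rows.append({"phase": "material", "cycle": len(ssd_rows), "ssd": v, "mu": mu})
        log.info("material mu = %.1f Pa -> SSD %.4g", mu, v)
        return v

    schedule = MaterialSchedule(
        mu0=cfg.mu_init_pa,
        factor=cfg.material_factor,
        direction=cfg.material_direction,
        max_steps=cfg.material_max_steps,
    )
    trace = optimise_material(evaluate, schedule)
    best_mu = trace.best_mu
    if current_mu["side"] != best_mu:
        # the final unsuccessful update is discarded: restore the best modulus
        for s in sides.values():
            s.sim.scale_material(best_mu / current_mu["side"])
        current_mu["side"] = best_mu
        for s in sides.values():
            s.sim.run_until_quasistatic(cfg.settle_max_steps)
    log.info("material optimisation: accepted %d steps, mu = %.1f Pa", trace.n_accepted, best_mu)
    if (r := _evaluate_tre(sides, landmarks, "material")) is not None:
        tre_reports.append(r)

    # ---------------- phase 3: image-derived forces -----------------------
    gamma = cfg.force_gamma
    for level_mm in cfg.force_levels_mm:
        force_grid, k = _force_grid_for(sim_grid, level_mm)
        best_ssd, p_c, s_c, msk = central_ssd(force_grid)
        ssd_rows.append({"phase": f"forces@{level_mm}", "cycle": 0, "ssd": best_ssd, "mu": best_mu})
        best_state = {n: s.sim.snapshot() for n, s in sides.items()}
        rollbacks = 0
        stale = 0
        for cycle in range(1, cfg.phase3_max_cycles + 1):
            f_p, f_s = imf.ssd_forces(p_c, s_c, msk)
            if gamma is None:
                # one-off calibration: initial force magnitude as a set share
                # of gravity (the scale of image vs physical forces is a free
                # parameter of the formulation)
                mag = np.linalg.norm(np.concatenate([f_p, f_s], axis=0), axis=0)
                scale_ref = float(np.percentile(mag[mag > 0], 95)) if (mag > 0).any() else 1.0
                gamma = cfg.force_gamma_fraction * cfg.gravity_magnitude / max(scale_ref, 1e-12)
                log.info("calibrated force weight gamma = %.3g", gamma)
            for name, f in (("prone", f_p), ("supine", f_s)):
                f_sim = imf.restrict_force_to_simulation_grid(
                    gamma * f, force_grid.spacing, sim_grid.shape, sim_grid.spacing_mm
                )
                sides[name].sim.begin_force_increment(f_sim, cfg.resample_interval)
            for _ in range(cfg.blocks_per_force_cycle):
                for s in sides.values():
                    s.sim.step_block()
            value, p_c, s_c, msk = central_ssd(force_grid)
            ssd_rows.append(
                {"phase": f"forces@{level_mm}", "cycle": cycle, "ssd": value, "mu": best_mu}
            )
            if value > 1.02 * best_ssd:
                # a real excursion (beyond relaxation noise): rewind to the
                # best state and push with gentler increments
                rollbacks += 1
                log.info(
                    "cycle %d: SSD spiked (%.4g > %.4g), rollback %d and halve gamma",
                    cycle, value, best_ssd, rollbacks,
                )
                for n, s in sides.items():
                    s.sim.restore(best_state[n])
                gamma = 0.5 * gamma
                _, p_c, s_c, msk = central_ssd(force_grid)
                if rollbacks >= 4:
                    break
                continue
            if value < best_ssd:
                stale = 0 if value < (1 - cfg.phase3_rel_tol) * best_ssd else stale + 1
                best_ssd = value
                best_state = {n: s.sim.snapshot() for n, s in sides.items()}
            else:
                stale += 1
            if cycle >= cfg.phase3_min_cycles and stale >= 10:
                break
        # finish at the best accepted state, then settle
        for n, s in sides.items():
            s.sim.restore(best_state[n])
        for s in sides.values():
            s.sim.run_until_quasistatic(cfg.settle_max_steps)
    if (r := _evaluate_tre(sides, landmarks, "image-forces")) is not None:
        tre_reports.append(r)

    return _finish(
        sides, sim_grid, p_img, s_img, ssd_rows, trace, tre_reports, best_mu, converged
    )


def _finish(
    sides: dict[str, _Side],
    sim_grid: SimulationGrid,
    p_img: ImageVolume,
    s_img: ImageVolume,
    ssd_rows: list[dict],
    trace: OptimisationTrace | None,
    tre_reports: list[TREReport],
    final_mu: float,
    converged: bool,
) -> PipelineResult:
    dvf_p = sides["prone"].sim.dvf_mm.copy()
    dvf_s = sides["supine"].sim.dvf_mm.copy()
    central_p = pullback_resample(p_img, dvf_to_grid(dvf_p, sim_grid, p_img))
    central_s = pullback_resample(s_img, dvf_to_grid(dvf_s, sim_grid, s_img))
    return PipelineResult(
        central_prone=central_p,
        central_supine=central_s,
        dvf_prone_mm=dvf_p,
        dvf_supine_mm=dvf_s,
        sim_grid=sim_grid,
        ssd_trace=pd.DataFrame(ssd_rows),
        material_trace=trace,
        tre_reports=tre_reports,
        final_mu_pa=final_mu,
        converged=converged,
    )
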