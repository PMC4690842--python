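"""Symmetric SSD similarity, per-side image forces and force bookkeeping.

Both loaded images are warped into the shared central (virtually unloaded)
configuration; the sum-of-squared-differences

    S_SSD = 1/2 int (P(X) - S(X))^2 dX

is the alignment measure, and its variational derivative yields one force
field per side,

    f_P = -(P - S) grad P,      f_S = -(S - P) grad S,

so the two sides are driven towards each other symmetrically. Forces are
evaluated on a fine force grid, restricted (conservatively) to the coarse
simulation grid, and accumulated incrementally: the newest increment is
transported by the side's deformation gradient and ramped in by a polygonal
loading function s(t) with s(0) = 0, s(T) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes_io import GeometryError, ImageVolume

__all__ = [
    "ForceState",
    "MultiscaleSchedule",
    "polygonal_ramp",
    "ssd",
    "ssd_forces",
    "accumulate_forces",
    "restrict_force_to_simulation_grid",
    "normalise_intensities",
]


@dataclass
class MultiscaleSchedule:
    """Force-grid levels (mm, coarse -> fine) over one fixed simulation grid."""

    force_spacings_mm: tuple[float, ...]
    sim_spacing_mm: float
    cycles_per_level: int = 40

    def __post_init__(self) -> None:
        sp = self.force_spacings_mm
        if any(sp[i] <= sp[i + 1] for i in range(len(sp) - 1)):
            raise ValueError("force spacings must be strictly decreasing")
        if self.sim_spacing_mm < sp[0]:
            raise ValueError("simulation spacing must be >= the coarsest force spacing")


@dataclass
class ForceState:
    """Per-side accumulated image force, recorded in the loaded configuration.

    ``accumulated`` is the sum of fully loaded increments  sum_j F_j f_j;
    ``increment`` is the newest transported force F_N f_N, scaled by the
    polygonal ramp until it is folded into the sum.
    """

    accumulated: np.ndarray
    increment: np.ndarray | None = None
    n_updates: int = 0

    @classmethod
    def zeros(cls, shape: tuple[int, ...]) -> "ForceState":
        return cls(accumulated=np.zeros((3, *shape)))

    def total(self, s: float) -> np.ndarray:
        """Effective force at ramp value s in [0, 1]."""
        if self.increment is None:
            return self.accumulated
        return self.accumulated + s * self.increment


def polygonal_ramp(t: float, T: float) -> float:
    """Piecewise-linear loading function: 0 at t=0, 1 at t>=T."""
    if T <= 0:
        return 1.0
    return float(np.clip(t / T, 0.0, 1.0))


def _as_array(img: ImageVolume | np.ndarray) -> np.ndarray:
    return img.data if isinstance(img, ImageVolume) else np.asarray(img)


def ssd(
    p_central: ImageVolume,
    s_central: ImageVolume,
    mask: np.ndarray | None = None,
) -> float:
    """1/2 sum (P - S)^2 * voxel volume (mm^3) over the (optional) mask."""
    if not p_central.same_grid(s_central):
        raise GeometryError("P and S must share one grid")
    diff = p_central.data.astype(float) - s_central.data.astype(float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != diff.shape:
            raise GeometryError("mask grid mismatch")
        if not mask.any():
            raise ValueError("similarity undefined: empty mask")
        diff = diff[mask]
    vox = float(np.prod(p_central.spacing))
    return 0.5 * float((diff**2).sum()) * vox


def ssd_forces(
    p_central: ImageVolume,
    s_central: ImageVolume,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-side SSD force fields f_P = -(P-S) grad P, f_S = -(S-P) grad S.

    Gradients are central differences with respect to world mm; masked voxels
    contribute exactly zero force (marker-clip protocol).
    """
    if not p_central.same_grid(s_central):
        raise GeometryError("P and S must share one grid")
    P = p_central.data.astype(float)
    S = s_central.data.astype(float)
    residual = P - S
    if mask is not None:
        residual = np.where(np.asarray(mask, dtype=bool), residual, 0.0)
    grad_p = np.stack(np.gradient(P, *p_central.spacing, edge_order=1))
    grad_s = np.stack(np.gradient(S, *s_central.spacing, edge_order=1))
    f_p = -residual * grad_p
    f_s = residual * grad_s  # -(S - P) grad S
    return f_p, f_s


def accumulate_forces(
    force_state: ForceState,
    new_force: np.ndarray,
    deformation_gradient: np.ndarray,
    t: float,
    T: float,
) -> ForceState:
    """One incremental update of the accumulated image force.

    The previous increment (if any) is folded into the running sum at full
    scale, the new central-configuration force is transported by the side's
    deformation gradient F and becomes the ramping increment; the returned
    state evaluates to  s(t) F_N f_N + sum_j F_j f_j  via ``total``.
    """
    new_force = np.asarray(new_force, dtype=float)
    if new_force.shape != force_state.accumulated.shape:
        raise GeometryError("force grid mismatch")
    accumulated = force_state.accumulated
    if force_state.increment is not None:
        accumulated = accumulated + force_state.increment
    transported = np.einsum("ij...,j...->i...", deformation_gradient, new_force)
    # callers evaluate state.total(polygonal_ramp(t, T)) when applying
    return ForceState(
        accumulated=accumulated,
        increment=transported,
        n_updates=force_state.n_updates + 1,
    )


def restrict_force_to_simulation_grid(
    force_field: np.ndarray,
    force_spacing_mm: tuple[float, float, float] | float,
    sim_shape: tuple[int, int, int],
    sim_spacing_mm: tuple[float, float, float] | float,
) -> np.ndarray:
    """Volume-weighted block averaging of a fine force field onto the coarse
    simulation grid; conserves total force (sum * cell volume) exactly for
    integer refinement factors."""
    force_field = np.asarray(force_field, dtype=float)
    fsp = np.broadcast_to(np.asarray(force_spacing_mm, dtype=float), (3,))
    ssp = np.broadcast_to(np.asarray(sim_spacing_mm, dtype=float), (3,))
    ratio = ssp / fsp
    k = np.rint(ratio).astype(int)
    if np.any(k < 1) or not np.allclose(ratio, k, rtol=1e-3):
        raise ValueError(
            f"force grid must be finer than the simulation grid by an integer "
            f"factor, got spacing ratio {ratio}"
        )
    fine_shape = force_field.shape[1:]
    target_fine = tuple(int(sim_shape[a] * k[a]) for a in range(3))
    # zero-pad (or crop) the fine field so k^3 blocks tile the sim grid
    padded = np.zeros((3, *target_fine))
    sl = tuple(slice(0, min(fine_shape[a], target_fine[a])) for a in range(3))
    padded[(slice(None),) + sl] = force_field[(slice(None),) + sl]
    blocked = padded.reshape(
        3, sim_shape[0], k[0], sim_shape[1], k[1], sim_shape[2], k[2]
    )
    return blocked.mean(axis=(2, 4, 6))


def normalise_intensities(
    volume: ImageVolume, mask: np.ndarray | None = None
) -> ImageVolume:
    """Rescale intensities to [0, 1] (inside the mask if given) so the image
    force weight is transferable across cases."""
    vals = volume.data[np.asarray(mask, bool)] if mask is not None else volume.data
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo == 0:
        return volume.with_data(np.zeros_like(volume.data, dtype=float))
    return volume.with_data((volume.data.astype(float) - lo) / (hi - lo))
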