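"""Sliding chest-wall constraint via a precomputed distance-transform field.

The chest-breast interface voxels are extracted from the segmentation and a
Euclidean distance transform to that band is computed once. Its nearest-point
map yields a correction vector field c(X) that points back to the target
surface. During explicit stepping, interface ("slave") nodes that left the
band are displaced by s(v_s) * c(x): internal elastic forces regularise the
tangential motion while the correction keeps the nodes on the chest surface.
The correction magnitude is rolled off by a logistic function of the node
speed towards the surface, which keeps the repeated displacement updates from
pumping energy into the explicit scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fdm_mechanics import SimulationGrid
from .volumes_io import LABEL_CHEST, LabelVolume

__all__ = [
    "ConstraintState",
    "ConstraintConstructionError",
    "build_correction_field",
    "logistic_scale",
    "apply_constraint",
]

# constants used in all experiments; the system is largely insensitive to p
DEFAULT_P = 0.005
DEFAULT_V_MAX = 0.05  # m/s


class ConstraintConstructionError(ValueError):
    """Segmentation lacks a usable chest class."""


@dataclass
class ConstraintState:
    """Precomputed surface-constraint data on the simulation grid.

    correction_m:
        c(X), metres, (3, nx, ny, nz): vector from each node to its nearest
        point on the target surface band (zero on the band itself).
    distance_m:
        Euclidean distance to the band, metres.
    slave_mask:
        nodes labelled as chest-interface (slave) nodes.
    chest_interior:
        chest nodes that are *not* part of the band (used by the one-sided
        sliding mode).
    """

    grid: SimulationGrid
    correction_m: np.ndarray
    distance_m: np.ndarray
    slave_mask: np.ndarray
    chest_interior: np.ndarray
    p: float = DEFAULT_P
    logistic_l: float | None = None  # default 10 / v_max, set in __post_init__
    v_max: float = DEFAULT_V_MAX
    mode: str = "tied"  # or "sliding" (one-sided)
    band_tolerance_m: float = 0.0  # nodes closer than this count as on-surface

    def __post_init__(self) -> None:
        if self.p <= 0 or self.v_max <= 0:
            raise ValueError("p and v_max must be positive")
        if self.logistic_l is None:
            # l is not fixed by the formulation; 10/v_max gives s(0) ~ p and a
            # sharp roll-off near v_max
            self.logistic_l = 10.0 / self.v_max
        if self.mode not in ("tied", "sliding"):
            raise ValueError("mode must be 'tied' or 'sliding'")
        if self.band_tolerance_m == 0.0:
            # one node of the discretised surface counts as "on the surface"
            self.band_tolerance_m = 0.5 * min(self.grid.spacing)


def extract_interface_band(labels: np.ndarray) -> np.ndarray:
    """Chest voxels adjacent to non-chest tissue/background: the discretised
    target surface (one voxel thick)."""
    chest = labels == LABEL_CHEST
    if not chest.any():
        raise ConstraintConstructionError("segmentation has no chest voxels")
    non_chest = ~chest
    neighbour = ndimage.binary_dilation(
        non_chest, structure=ndimage.generate_binary_structure(3, 1)
    )
    band = chest & neighbour
    if not band.any():
        raise ConstraintConstructionError(
            "chest class fills the grid: no chest-breast interface found"
        )
    return band


def build_correction_field(
    labels_on_grid: np.ndarray | LabelVolume,
    grid: SimulationGrid,
    p: float = DEFAULT_P,
    v_max: float = DEFAULT_V_MAX,
    logistic_l: float | None = None,
    mode: str = "tied",
) -> ConstraintState:
    """Distance transform of the chest interface -> correction field c(X).

    ``c`` is obtained from the nearest-surface-voxel map of the Euclidean
    distance transform (equivalent to -distance * grad distance, but exact at
    voxel resolution), so ``|c|`` equals the distance to the band and c = 0 on
    the band.
    """
    data = labels_on_grid.data if isinstance(labels_on_grid, LabelVolume) else labels_on_grid
    data = np.asarray(data)
    if data.shape != grid.shape:
        raise ValueError("label grid does not match the simulation grid")
    band = extract_interface_band(data)
    dist, nearest = ndimage.distance_transform_edt(
        ~band, sampling=grid.spacing, return_indices=True
    )
    idx = np.indices(grid.shape, dtype=float)
    spacing = np.asarray(grid.spacing)[:, None, None, None]
    correction = (nearest.astype(float) - idx) * spacing
    chest = data == LABEL_CHEST
    return ConstraintState(
        grid=grid,
        correction_m=correction,
        distance_m=dist,
        slave_mask=band,
        chest_interior=chest & ~band,
        p=p,
        v_max=v_max,
        logistic_l=logistic_l,
        mode=mode,
    )


def logistic_scale(
    v_s: np.ndarray | float, p: float, l: float, v_max: float
) -> np.ndarray | float:
    """s(v_s) = p / (1 + exp(l (v_s - v_max))): p for slow nodes, p/2 at the
    speed limit, -> 0 for nodes already rushing towards the surface."""
    arg = np.clip(l * (np.asarray(v_s, dtype=float) - v_max), -700, 700)
    return p / (1.0 + np.exp(arg))


def _sample_vector(field_arr: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return np.stack(
        [
            ndimage.map_coordinates(field_arr[a], idx, order=1, mode="nearest", prefilter=False)
            for a in range(3)
        ]
    )


def apply_constraint(
    u: np.ndarray,
    u_prev: np.ndarray,
    h_t: float,
    constraint: ConstraintState,
) -> np.ndarray:
    """Correct slave-node displacements in place of the free update.

    For each slave node with deformed position x = X + u off the target band,
    u' = u + s(v_s) c(x), where v_s is the node speed along the correction
    direction (positive towards the surface). Corrections are capped at one
    grid cell per step as a safety valve. Returns the corrected ``u``.
    """
    grid = constraint.grid
    slave = constraint.slave_mask
    if not slave.any():
        return u
    spacing = np.asarray(grid.spacing)
    sl_idx = np.argwhere(slave).T.astype(float)  # (3, n_slave)
    disp = u[:, slave]  # metres
    # deformed position in fractional grid indices
    pos_idx = sl_idx + disp / spacing[:, None]
    c = _sample_vector(constraint.correction_m, pos_idx)
    dist = np.linalg.norm(c, axis=0)
    off_band = dist > constraint.band_tolerance_m
    if constraint.mode == "sliding":
        # one-sided: only correct nodes that moved out of the chest side
        inside_chest = ndimage.map_coordinates(
            constraint.chest_interior.astype(float),
            pos_idx,
            order=0,
            mode="nearest",
            prefilter=False,
        ).astype(bool)
        off_band &= ~inside_chest
    if not off_band.any():
        return u
    c_hat = np.zeros_like(c)
    c_hat[:, off_band] = c[:, off_band] / dist[off_band]
    vel = (u[:, slave] - u_prev[:, slave]) / h_t
    v_s = (vel * c_hat).sum(axis=0)  # positive when moving towards the surface
    s = logistic_scale(v_s, constraint.p, constraint.logistic_l, constraint.v_max)
    delta = s * c
    # cap at one grid cell per step
    step_norm = np.linalg.norm(delta, axis=0)
    cap = min(grid.spacing)
    too_big = step_norm > cap
    if too_big.any():
        delta[:, too_big] *= cap / step_norm[too_big]
    delta[:, ~off_band] = 0.0
    u_new = u.copy()
    u_new[:, slave] = u[:, slave] + delta
    return u_new
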