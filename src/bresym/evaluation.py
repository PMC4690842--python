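"""Landmark-based accuracy metrics in the central configuration.

Both sides' landmarks are mapped into the shared virtually unloaded frame and
compared there: the per-pair Euclidean distance is the target registration
error (TRE). Because the registration stores pullback fields (central grid
point X samples its loaded position X + D(X)), mapping a *loaded* landmark p
into the central frame solves X + D(X) = p by fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .fdm_mechanics import SimulationGrid
from .volumes_io import LandmarkSet

__all__ = ["TREReport", "warp_landmarks", "tre", "exclude_unreliable"]


@dataclass
class TREReport:
    """Per-landmark distances (mm) and their summary for one pipeline stage."""

    distances_mm: np.ndarray
    stage: str = ""

    def __post_init__(self) -> None:
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.distances_mm.mean())

    @property
    def std(self) -> float:
        return float(self.distances_mm.std(ddof=0))

    @property
    def max(self) -> float:
        return float(self.distances_mm.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"stage": self.stage, "tre_mm": self.distances_mm})

    def summary(self) -> dict[str, float]:
        return {"stage": self.stage, "mean": self.mean, "std": self.std, "max": self.max}


def _sample_dvf(dvf_mm: np.ndarray, grid: SimulationGrid, pts_mm: np.ndarray) -> np.ndarray:
    idx = (pts_mm - np.asarray(grid.origin_mm)) / np.asarray(grid.spacing_mm)
    return np.stack(
        [
            ndimage.map_coordinates(dvf_mm[a], idx.T, order=1, mode="nearest", prefilter=False)
            for a in range(3)
        ],
        axis=1,
    )


def warp_landmarks(
    landmarks: LandmarkSet,
    dvf_mm: np.ndarray,
    grid: SimulationGrid,
    iterations: int = 20,
    tol_mm: float = 0.01,
) -> LandmarkSet:
    """Map loaded-configuration landmarks into the central frame.

    Solves X = p - D(X) per point (<= ``iterations`` fixed-point sweeps,
    stopping when the largest update is below ``tol_mm``); points move
    opposite to the stored pullback vectors.
    """
    p = landmarks.points
    X = p.copy()
    for _ in range(iterations):
        X_new = p - _sample_dvf(dvf_mm, grid, X)
        err = float(np.abs(X_new - X).max())
        X = X_new
        if err < tol_mm:
            break
    return LandmarkSet(landmarks.labels.copy(), X)


def tre(
    prone_pts_central: LandmarkSet,
    supine_pts_central: LandmarkSet,
    stage: str = "",
) -> TREReport:
    """Per-pair Euclidean distances between corresponding landmarks."""
    if len(prone_pts_central) != len(supine_pts_central):
        raise ValueError("landmark counts differ")
    if not np.array_equal(prone_pts_central.labels, supine_pts_central.labels):
        raise ValueError("landmark labels do not match pairwise")
    d = np.linalg.norm(prone_pts_central.points - supine_pts_central.points, axis=1)
    return TREReport(distances_mm=d, stage=stage)


def exclude_unreliable(
    landmarks_obs1: LandmarkSet,
    landmarks_obs2: LandmarkSet,
    threshold_mm: float = 10.0,
) -> tuple[LandmarkSet, LandmarkSet, int]:
    """Inter-observer exclusion rule.

    Pairs whose inter-observer distance exceeds the threshold are removed;
    the second observer's points within the threshold stay in the evaluation
    set. Returns the filtered sets (matching labels) and the outlier count.
    """
    if not np.array_equal(landmarks_obs1.labels, landmarks_obs2.labels):
        raise ValueError("observers must provide matching landmark labels")
    d = np.linalg.norm(landmarks_obs1.points - landmarks_obs2.points, axis=1)
    keep = d <= threshold_mm
    n_outliers = int((~keep).sum())
    filtered1 = LandmarkSet(landmarks_obs1.labels[keep], landmarks_obs1.points[keep])
    filtered2 = LandmarkSet(landmarks_obs2.labels[keep], landmarks_obs2.points[keep])
    return filtered1, filtered2, n_outliers
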