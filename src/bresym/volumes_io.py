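"""Typed volume/transform/landmark containers and resampling primitives.

Conventions used throughout the package:

* voxel indices are 0-based and arrays are indexed ``data[i, j, k]`` with
  axis 0 = left-right (LR), axis 1 = posterior-anterior (AP) and axis 2 =
  inferior-superior (SI) for the phantom experiments;
* world coordinates are millimetres,
  ``world = origin + orientation @ (index * spacing)``;
* displacement vector fields (DVFs) are stored in the *pullback* (backward)
  convention: a vector sits at a target-grid voxel and points to the source
  position that is sampled, so warping an image is a plain resampling step
  and never requires an explicit field inversion.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "RigidTransform",
    "LandmarkSet",
    "LABEL_BACKGROUND",
    "LABEL_CHEST",
    "LABEL_ADIPOSE",
    "LABEL_FIBROGLANDULAR",
    "read_volume",
    "write_volume",
    "pullback_resample",
    "resample_to_grid",
    "invert_displacement_field",
    "intensity_inversion",
    "apply_rigid",
    "read_landmarks",
    "write_landmarks",
    "read_rigid",
    "write_rigid",
]

# four-class segmentation codes shared by the whole pipeline
LABEL_BACKGROUND = 0
LABEL_CHEST = 1
LABEL_ADIPOSE = 2
LABEL_FIBROGLANDULAR = 3
VALID_LABELS = (LABEL_BACKGROUND, LABEL_CHEST, LABEL_ADIPOSE, LABEL_FIBROGLANDULAR)


class VolumeFormatError(ValueError):
    """Unreadable file or unsupported on-disk format."""


class DimensionalityError(ValueError):
    """Payload is not a 3-D scalar volume."""


class GeometryError(ValueError):
    """Grid geometry mismatch between operands."""


@dataclass
class ImageVolume:
    """A 3-D scalar grid with physical geometry.

    Parameters
    ----------
    data:
        3-D array, indexed ``[i, j, k]``.
    spacing:
        Per-axis voxel size in mm, all entries > 0.
    origin:
        World position (mm) of voxel ``(0, 0, 0)``.
    orientation:
        3x3 axis-direction matrix (columns are the world directions of the
        voxel axes). Identity unless a file says otherwise.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got {self.data.ndim}-D data"
            )
        if any(s < 2 for s in self.data.shape):
            raise DimensionalityError(
                f"each axis needs at least 2 voxels, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3):
            raise GeometryError("orientation must be a 3x3 matrix")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.orientation, other.orientation)
        )

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + (idx * np.asarray(self.spacing)) @ self.orientation.T

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm points to (fractional) voxel indices."""
        pts = np.asarray(pts, dtype=float)
        rel = (pts - np.asarray(self.origin)) @ np.linalg.inv(self.orientation).T
        return rel / np.asarray(self.spacing)

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (valid for identity orientation)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same geometry, new payload."""
        return replace(self, data=np.asarray(data))


@dataclass
class LabelVolume(ImageVolume):
    """Integer 4-class segmentation on the same geometry as its image."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be an integer array")
        codes = np.unique(self.data)
        if not np.isin(codes, VALID_LABELS).all():
            raise ValueError(
                f"label codes {codes.tolist()} outside the declared set {VALID_LABELS}"
            )

    @property
    def tissue_mask(self) -> np.ndarray:
        """Breast tissue = adipose or fibro-glandular."""
        return self.data >= LABEL_ADIPOSE

    @property
    def chest_mask(self) -> np.ndarray:
        return self.data == LABEL_CHEST

    @property
    def breast_or_chest_mask(self) -> np.ndarray:
        return self.data != LABEL_BACKGROUND


@dataclass
class RigidTransform:
    """4x4 homogeneous rigid-body transform, translations in mm."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("rigid transform must be a 4x4 matrix")
        rot = self.matrix[:3, :3]
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(rot), 1.0, atol=1e-8
        ):
            raise ValueError("upper-left 3x3 block must be a rotation (det +1)")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1]):
            raise ValueError("last row must be [0, 0, 0, 1]")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]


@dataclass
class LandmarkSet:
    """Labelled points in world mm."""

    labels: np.ndarray
    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points length mismatch")
        if len(np.unique(self.labels)) != len(self.labels):
            raise ValueError("landmark labels must be unique")
        if not np.isfinite(self.points).all():
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
            }
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_path(path: str) -> None:
    name = str(path).lower()
    if not any(name.endswith(ext) for ext in _SUPPORTED_EXT):
        raise VolumeFormatError(
            f"unsupported volume format for {path!r}; use NIfTI (.nii/.nii.gz) "
            "or MetaImage (.mha/.mhd)"
        )


def read_volume(path: str) -> ImageVolume:
    """Read a 3-D NIfTI or MetaImage volume."""
    _check_path(path)
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path!r}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - ITK error text varies
        raise VolumeFormatError(f"unreadable volume {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path!r} holds a {img.GetDimension()}-D payload, expected 3-D"
        )
    # SimpleITK arrays come back (k, j, i); store (i, j, k)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(
        data=data,
        spacing=img.GetSpacing(),
        origin=img.GetOrigin(),
        orientation=np.asarray(img.GetDirection()).reshape(3, 3),
    )


def write_volume(volume: ImageVolume, path: str) -> None:
    """Write a volume; geometry and native scalar type are preserved."""
    _check_path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.orientation.ravel()))
    sitk.WriteImage(img, str(path))


def read_landmarks(path: str) -> LandmarkSet:
    df = pd.read_csv(path)
    return LandmarkSet(df["label"].to_numpy(), df[["x", "y", "z"]].to_numpy(float))


def write_landmarks(landmarks: LandmarkSet, path: str) -> None:
    landmarks.to_frame().to_csv(path, index=False)


def read_rigid(path: str) -> RigidTransform:
    return RigidTransform(np.loadtxt(path).reshape(4, 4))


def write_rigid(transform: RigidTransform, path: str) -> None:
    np.savetxt(path, transform.matrix, fmt="%.12g")


# ---------------------------------------------------------------------------
# resampling / warping
# ---------------------------------------------------------------------------

_ORDER = {"nearest": 0, "linear": 1}


def _map_coords(
    data: np.ndarray, idx: np.ndarray, interpolation: str, pad_value: float
) -> np.ndarray:
    order = _ORDER[interpolation]
    return ndimage.map_coordinates(
        data.astype(float, copy=False),
        idx,
        order=order,
        mode="grid-constant",
        cval=pad_value,
        prefilter=False,
    )


def pullback_resample(
    volume: ImageVolume,
    dvf: np.ndarray,
    interpolation: str = "linear",
    pad_value: float = 0.0,
) -> ImageVolume:
    """Warp ``volume`` by a pullback DVF defined on its own grid.

    ``output(X) = input(X + dvf(X))`` where ``dvf`` has shape
    ``(3, *volume.shape)`` in mm (world units, identity-orientation grids).
    Samples falling outside the domain take ``pad_value``.
    """
    dvf = np.asarray(dvf, dtype=float)
    if dvf.shape != (3, *volume.shape):
        raise GeometryError(
            f"dvf shape {dvf.shape} does not match volume grid (3, {volume.shape})"
        )
    spacing = np.asarray(volume.spacing)
    idx = np.indices(volume.shape, dtype=float)
    sample_idx = idx + dvf / spacing[:, None, None, None]
    out = _map_coords(volume.data, sample_idx, interpolation, pad_value)
    if interpolation == "nearest" and np.issubdtype(volume.data.dtype, np.integer):
        out = np.rint(out).astype(volume.data.dtype)
    return volume.with_data(out)


def resample_to_grid(
    volume: ImageVolume,
    target: ImageVolume,
    interpolation: str = "linear",
    pad_value: float = 0.0,
    dvf_mm: np.ndarray | None = None,
) -> ImageVolume:
    """Resample ``volume`` onto ``target``'s grid, optionally composing a
    pullback DVF defined on the target grid (mm)."""
    idx = np.indices(target.shape, dtype=float)
    world = (
        np.asarray(target.origin)[:, None, None, None]
        + idx * np.asarray(target.spacing)[:, None, None, None]
    )
    if dvf_mm is not None:
        dvf_mm = np.asarray(dvf_mm, dtype=float)
        if dvf_mm.shape != (3, *target.shape):
            raise GeometryError("dvf grid does not match the requested output grid")
        world = world + dvf_mm
    src_idx = (
        world - np.asarray(volume.origin)[:, None, None, None]
    ) / np.asarray(volume.spacing)[:, None, None, None]
    out = _map_coords(volume.data, src_idx, interpolation, pad_value)
    if interpolation == "nearest" and np.issubdtype(volume.data.dtype, np.integer):
        out = np.rint(out).astype(volume.data.dtype)
    return ImageVolume(
        data=out,
        spacing=target.spacing,
        origin=target.origin,
        orientation=target.orientation,
    )


def invert_displacement_field(
    forward_mm: np.ndarray,
    spacing: tuple[float, float, float],
    iterations: int = 20,
    tol_mm: float = 0.01,
) -> np.ndarray:
    """Invert a forward displacement field by fixed-point iteration.

    Given the forward displacement ``U`` on a grid (material point at ``X``
    moves to ``X + U(X)``), returns the pullback field ``d`` on the same grid
    such that ``x + d(x)`` recovers the material point imaged at ``x``:
    ``d(x) = -U(x + d(x))``.
    """
    forward_mm = np.asarray(forward_mm, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    shape = forward_mm.shape[1:]
    idx = np.indices(shape, dtype=float)
    d = -forward_mm.copy()
    for _ in range(iterations):
        sample_idx = idx + d / spacing[:, None, None, None]
        u_at = np.stack(
            [
                ndimage.map_coordinates(
                    forward_mm[a], sample_idx, order=1, mode="nearest", prefilter=False
                )
                for a in range(3)
            ]
        )
        d_new = -u_at
        err = np.max(np.abs(d_new - d))
        d = d_new
        if err < tol_mm:
            break
    return d


def intensity_inversion(
    mr_volume: ImageVolume,
    breast_mask: np.ndarray,
    out_low: float = 0.0,
    out_high: float = 1.0,
    background_value: float = 0.0,
) -> ImageVolume:
    """Pseudo-CT conversion: linearly invert intensities inside the mask.

    The mask-interior maximum maps to ``out_low`` and the minimum to
    ``out_high`` (bright fat in T2 MR becomes dark, as in CT).
    """
    mask = np.asarray(breast_mask, dtype=bool)
    if mask.shape != tuple(mr_volume.shape):
        raise GeometryError("mask grid does not match the volume")
    if not mask.any():
        raise ValueError("breast mask is empty")
    if not out_low < out_high:
        raise ValueError("require out_low < out_high")
    vals = mr_volume.data[mask].astype(float)
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo == 0:
        raise ValueError("degenerate intensity range inside the mask")
    out = np.full(mr_volume.shape, background_value, dtype=float)
    out[mask] = out_high + (mr_volume.data[mask] - lo) * (out_low - out_high) / (hi - lo)
    return mr_volume.with_data(out)


def apply_rigid(
    volume: ImageVolume,
    transform: RigidTransform,
    interpolation: str = "linear",
    pad_value: float = 0.0,
) -> ImageVolume:
    """Resample ``volume`` under a rigid transform onto its own grid.

    Pullback convention: ``output(x) = input(T @ x)``, i.e. the matrix maps
    output-grid world points to the positions sampled in the input.
    """
    idx = np.indices(volume.shape, dtype=float)
    world = (
        np.asarray(volume.origin)[:, None, None, None]
        + idx * np.asarray(volume.spacing)[:, None, None, None]
    )
    pts = world.reshape(3, -1).T
    src = transform.apply_points(pts).T.reshape(world.shape)
    src_idx = (
        src - np.asarray(volume.origin)[:, None, None, None]
    ) / np.asarray(volume.spacing)[:, None, None, None]
    out = _map_coords(volume.data, src_idx, interpolation, pad_value)
    if interpolation == "nearest" and np.issubdtype(volume.data.dtype, np.integer):
        out = np.rint(out).astype(volume.data.dtype)
    return volume.with_data(out)
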