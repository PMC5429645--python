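"""Volume containers, MetaImage/NIfTI I/O and straight-trajectory sampling.

Conventions
-----------
* ``Volume3D.values`` is indexed ``[i, j, k]`` (x, y, z order); the world
  position of voxel ``(i, j, k)`` is ``origin + index * spacing`` (voxel-center
  convention, 0-based indices, units mm).
* Label volumes are integer arrays; 0 means "unsegmented".
* Depth along a trajectory is measured in mm from the entry point.
* Sub-voxel lookups are nearest-neighbour: labels are categorical, and the
  tissue classifier thresholds a single voxel value at the needle tip, so no
  interpolation scheme is meaningful for either volume kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume3D",
    "Trajectory",
    "OutsideVolumeError",
    "TrajectoryTruncationError",
    "VolumeFormatError",
    "OversamplingWarning",
    "world_to_voxel",
    "voxel_to_world",
    "sample_labels_along",
    "read_volume",
    "write_volume",
]

#: Default number of force/label samples per path.
DEFAULT_N_SAMPLES = 1000
#: Default maximum needle insertion length in mm.
DEFAULT_MAX_LENGTH = 90.0


class OutsideVolumeError(ValueError):
    """A world point lies outside the volume bounds."""


class TrajectoryTruncationError(ValueError):
    """A trajectory exits the volume before reaching its full length."""

    def __init__(self, message: str, valid_depth_mm: float):
        super().__init__(message)
        self.valid_depth_mm = valid_depth_mm


class VolumeFormatError(ValueError):
    """A volume file does not satisfy the 3D scalar-volume contract."""


class OversamplingWarning(UserWarning):
    """Trajectory sample spacing is too coarse for sub-voxel sampling."""


@dataclass(frozen=True)
class Volume3D:
    """A 3D scalar grid with voxel spacing and world origin.

    Parameters
    ----------
    values : numpy.ndarray
        3D array indexed ``[i, j, k]``; HU for intensity volumes,
        non-negative integer codes for label volumes.
    spacing : tuple of float
        Per-axis voxel size in mm, strictly positive.
    origin : tuple of float
        World position (mm) of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise VolumeFormatError(
                f"expected 3D volume, got {values.ndim}D array"
            )
        object.__setattr__(self, "values", values)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or len(origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    def is_integer(self) -> bool:
        return np.issubdtype(self.values.dtype, np.integer)

    def continuous_index(self, points: np.ndarray) -> np.ndarray:
        """World points (mm, shape (..., 3)) -> continuous voxel index."""
        return (np.asarray(points, dtype=float) - self.origin_arr) / self.spacing_arr

    def nearest_index(self, points: np.ndarray) -> np.ndarray:
        """World points -> nearest voxel index (half rounds away from origin)."""
        ci = self.continuous_index(points)
        return np.floor(ci + 0.5).astype(np.intp)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True where the nearest voxel of each point exists in the grid."""
        idx = self.nearest_index(points)
        shape = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shape), axis=-1)

    def values_at(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel values at world points; no bounds check."""
        idx = self.nearest_index(points)
        return self.values[idx[..., 0], idx[..., 1], idx[..., 2]]


def world_to_voxel(point, vol: Volume3D) -> tuple[int, int, int]:
    """Nearest voxel index for a world point (mm).

    Inverse of :func:`voxel_to_world` up to rounding.

    Raises
    ------
    OutsideVolumeError
        If the point lies outside the volume bounds (no nearest voxel).
    """
    point = np.asarray(point, dtype=float)
    if point.shape != (3,):
        raise ValueError("point must be a 3-vector")
    if not bool(vol.contains(point)):
        raise OutsideVolumeError(f"point {tuple(point)} is outside volume")
    idx = vol.nearest_index(point)
    return (int(idx[0]), int(idx[1]), int(idx[2]))


def voxel_to_world(index, vol: Volume3D) -> np.ndarray:
    """World position (mm) of a voxel center."""
    return vol.origin_arr + np.asarray(index, dtype=float) * vol.spacing_arr


@dataclass(frozen=True)
class Trajectory:
    """A straight insertion path.

    Parameters
    ----------
    entry : array-like
        World entry point in mm.
    direction : array-like
        Unit direction vector (validated to |d| = 1 within 1e-9).
    length : float
        Insertion length in mm; must not exceed ``max_length``.
    n_samples : int
        Number of uniformly spaced depth samples (default 1,000).
    max_length : float
        Configured maximum insertion length (default 90 mm).
    """

    entry: np.ndarray
    direction: np.ndarray
    length: float
    n_samples: int = DEFAULT_N_SAMPLES
    max_length: float = field(default=DEFAULT_MAX_LENGTH, repr=False)

    def __post_init__(self):
        entry = np.asarray(self.entry, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        if entry.shape != (3,) or direction.shape != (3,):
            raise ValueError("entry and direction must be 3-vectors")
        norm = float(np.linalg.norm(direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector, |d| = {norm}")
        if self.length < 0:
            raise ValueError("length must be non-negative")
        if self.length > self.max_length:
            raise ValueError(
                f"length {self.length} mm exceeds maximum {self.max_length} mm"
            )
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        object.__setattr__(self, "entry", entry)
        object.__setattr__(self, "direction", direction)
        object.__setattr__(self, "length", float(self.length))

    @classmethod
    def from_points(cls, entry, target, **kwargs) -> "Trajectory":
        """Trajectory from entry to target world points."""
        entry = np.asarray(entry, dtype=float)
        target = np.asarray(target, dtype=float)
        delta = target - entry
        length = float(np.linalg.norm(delta))
        if length == 0:
            raise ValueError("entry and target coincide")
        return cls(entry=entry, direction=delta / length, length=length, **kwargs)

    @property
    def sample_spacing(self) -> float:
        """Uniform depth spacing between consecutive samples in mm."""
        return self.length / (self.n_samples - 1)

    def depths(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_samples)

    def points(self, depths: np.ndarray | None = None) -> np.ndarray:
        """World sample points, shape (n, 3)."""
        if depths is None:
            depths = self.depths()
        return self.entry[None, :] + np.asarray(depths)[:, None] * self.direction[None, :]

    def point_at(self, depth: float) -> np.ndarray:
        return self.entry + depth * self.direction


def _check_oversampling(traj: Trajectory, vol: Volume3D) -> None:
    # >=10x oversampling relative to the finest voxel axis; 2% grace so the
    # conventional 1,000-samples-over-90-mm grid on 0.9 mm voxels conforms.
    bound = min(vol.spacing) / 10.0
    if traj.sample_spacing > bound * 1.02:
        warnings.warn(
            f"sample spacing {traj.sample_spacing:.4f} mm exceeds "
            f"min(spacing)/10 = {bound:.4f} mm; sub-voxel sampling not guaranteed",
            OversamplingWarning,
            stacklevel=3,
        )


def sample_labels_along(
    traj: Trajectory, labels: Volume3D
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a label volume along a trajectory by nearest-voxel lookup.

    Returns
    -------
    (depths, labels) : pair of arrays of length ``traj.n_samples``
        Depth in mm from the entry point and the label code at each sample.

    Raises
    ------
    TrajectoryTruncationError
        If the trajectory exits the volume; the exception carries the last
        valid depth.
    """
    _check_oversampling(traj, labels)
    depths = traj.depths()
    points = traj.points(depths)
    inside = labels.contains(points)
    if not np.all(inside):
        first_out = int(np.argmin(inside))
        valid = float(depths[first_out - 1]) if first_out > 0 else 0.0
        raise TrajectoryTruncationError(
            f"trajectory exits the volume at depth {depths[first_out]:.3f} mm; "
            f"valid depth range [0, {valid:.3f}] mm",
            valid_depth_mm=valid,
        )
    return depths, labels.values_at(points)


# ---------------------------------------------------------------------------
# I/O (MetaImage .mhd/.raw and NIfTI .nii/.nii.gz via SimpleITK)
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume3D:
    """Read a 3D volume (MetaImage or NIfTI, by extension).

    Raises :class:`VolumeFormatError` for non-3D images or malformed headers.
    """
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps header errors in RuntimeError
        raise VolumeFormatError(f"cannot read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"expected 3D volume, got {img.GetDimension()}D image in {path}"
        )
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise VolumeFormatError(f"expected 3D scalar volume, {path} is multi-component")
    # SimpleITK arrays are [z, y, x]; transpose to this package's [x, y, z].
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume3D(
        values=np.ascontiguousarray(values),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume to MetaImage or NIfTI (format chosen by extension).

    Round-trips values, spacing and origin; bit-exact for integer labels.
    """
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))


def labels_to_csv(depths: np.ndarray, labels: np.ndarray, path) -> None:
    """Write a sampled label sequence as CSV (depth_mm, label)."""
    import pandas as pd

    pd.DataFrame({"depth_mm": depths, "label": labels}).to_csv(path, index=False)
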