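"""Volumetric image containers and I/O.

The package works in world millimetre coordinates throughout.  A volume is a
3-D scalar array indexed ``values[i, j, k]`` along the world (x, y, z) axes,
with the centre of voxel ``(i, j, k)`` at ``origin + (i, j, k) * spacing``.
MetaImage (.mha/.mhd) and NIfTI (.nii/.nii.gz) files are read and written
through SimpleITK; SimpleITK's numpy arrays are (z, y, x)-ordered, so they are
transposed on the way in and out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "PointSet",
    "LandmarkPairs",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "downsample_by_two",
    "read_landmarks",
    "write_landmarks",
    "read_point_set",
    "write_point_set",
]

_SUPPORTED_SUFFIXES = (".mha", ".mhd", ".nii", ".nii.gz")


def _as_float_triplet(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float).reshape(3)
    return arr


@dataclass
class ImageVolume:
    """A 3-D scalar grid with per-axis spacing (mm) and world origin (mm).

    Values are Hounsfield units for CT volumes, unitless for derived fields
    (vesselness, Jacobian maps).
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = _as_float_triplet(self.spacing)
        self.origin = _as_float_triplet(self.origin)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {self.values.ndim} axes")
        if any(n < 4 for n in self.values.shape):
            raise ValueError(f"each axis must have length >= 4, got {self.values.shape}")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacings must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def domain(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world coordinates of the voxel-centre lattice."""
        lo = self.origin.copy()
        hi = self.origin + self.spacing * (np.array(self.shape) - 1)
        return lo, hi

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to continuous 0-based voxel indices."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - self.origin) / self.spacing

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin + idx * self.spacing

    def same_grid(self, other: "ImageVolume", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class BinaryMask(ImageVolume):
    """A {0,1} mask sharing its paired volume's grid."""

    def __post_init__(self):
        vals = np.asarray(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        super().__post_init__()
        if not self.values.any():
            raise ValueError("mask must contain at least one nonzero voxel")

    @property
    def bool_values(self) -> np.ndarray:
        return self.values.astype(bool)


@dataclass
class PointSet:
    """N x 3 world-coordinate points (mm) with a free-text label."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an N x 3 array")
        if self.points.shape[0] < 1:
            raise ValueError("point set must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class LandmarkPairs:
    """Paired anatomical landmarks: p_k on the template, q_k on the target."""

    template_points: np.ndarray
    target_points: np.ndarray

    def __post_init__(self):
        self.template_points = np.atleast_2d(np.asarray(self.template_points, dtype=float))
        self.target_points = np.atleast_2d(np.asarray(self.target_points, dtype=float))
        if self.template_points.shape != self.target_points.shape:
            raise ValueError("template/target landmark counts must match")
        if self.template_points.shape[0] < 1 or self.template_points.shape[1] != 3:
            raise ValueError("landmarks must be N x 3 with N >= 1")

    def __len__(self) -> int:
        return self.template_points.shape[0]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported volume format {path.name!r}; use one of {_SUPPORTED_SUFFIXES}"
        )


def read_volume(path) -> ImageVolume:
    """Read a MetaImage or NIfTI volume; spacing/origin come from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - ITK error text varies
        raise ValueError(f"unreadable image file {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3-D image, got {img.GetDimension()}-D in {path}")
    values = sitk.GetArrayFromImage(img).T  # (z,y,x) -> (x,y,z)
    return ImageVolume(
        values=np.ascontiguousarray(values, dtype=float),
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
    )


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume; re-reading yields bit-identical values."""
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    vals = vol.values
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{path} is not a binary mask")
    return BinaryMask(vals, vol.spacing, vol.origin)


def write_mask(mask: BinaryMask, path) -> None:
    write_volume(mask, path)


def downsample_by_two(vol: ImageVolume) -> ImageVolume:
    """Halve each axis (floor) and double the spacing.

    Scalar volumes are Gaussian pre-smoothed (sigma = half the new spacing per
    axis, i.e. one source voxel) before decimation so constants and linear
    ramps survive; masks are reduced by 2x2x2 block majority vote and
    re-binarized.
    """
    shape = np.array(vol.shape)
    if np.any(shape < 8):
        raise ValueError(f"volume too small to downsample: shape {vol.shape}")
    new_shape = shape // 2
    crop = vol.values[: 2 * new_shape[0], : 2 * new_shape[1], : 2 * new_shape[2]]
    if isinstance(vol, BinaryMask):
        blocks = crop.reshape(new_shape[0], 2, new_shape[1], 2, new_shape[2], 2)
        frac = blocks.mean(axis=(1, 3, 5))
        out = (frac >= 0.5).astype(float)
        return BinaryMask(out, vol.spacing * 2, vol.origin.copy())
    # sigma of one source voxel == half the new spacing, in voxel units
    smoothed = ndimage.gaussian_filter(vol.values, sigma=1.0, mode="nearest")
    out = smoothed[::2, ::2, ::2][: new_shape[0], : new_shape[1], : new_shape[2]]
    return ImageVolume(np.ascontiguousarray(out), vol.spacing * 2, vol.origin.copy())


_LANDMARK_COLUMNS = ["id", "tx", "ty", "tz", "qx", "qy", "qz"]
_POINT_COLUMNS = ["id", "x", "y", "z"]


def read_landmarks(path) -> LandmarkPairs:
    """Read comma-delimited landmark pairs (header: id,tx,ty,tz,qx,qy,qz)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValueError(f"cannot parse landmark file {path}: {exc}") from exc
    missing = [c for c in _LANDMARK_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise ValueError(f"landmark file {path} missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"landmark file {path} contains no rows")
    coords = df[_LANDMARK_COLUMNS[1:]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError(f"landmark file {path} contains non-numeric coordinates")
    return LandmarkPairs(coords[:, :3], coords[:, 3:])


def write_landmarks(pairs: LandmarkPairs, path) -> None:
    df = pd.DataFrame(
        np.hstack([pairs.template_points, pairs.target_points]),
        columns=_LANDMARK_COLUMNS[1:],
    )
    df.insert(0, "id", np.arange(len(pairs)))
    df.to_csv(path, index=False)


def read_point_set(path, label: str = "") -> PointSet:
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValueError(f"cannot parse point file {path}: {exc}") from exc
    missing = [c for c in _POINT_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise ValueError(f"point file {path} missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"point file {path} contains no rows")
    pts = df[_POINT_COLUMNS[1:]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"point file {path} contains non-numeric coordinates")
    return PointSet(pts, label=label)


def write_point_set(ps: PointSet, path) -> None:
    df = pd.DataFrame(ps.points, columns=_POINT_COLUMNS[1:])
    df.insert(0, "id", np.arange(len(ps)))
    df.to_csv(path, index=False)
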