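"""Volume and mask containers, NIfTI IO, isotropic resampling, ROI cropping.

All internal processing uses 0-based voxel indices with world coordinates
``origin + index * spacing``.  After resampling to 1 mm isotropic, voxel
units and millimetres coincide, which is the convention the rest of the
package (smoothing scales, derivative filters) relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample_isotropic",
    "extract_roi",
    "dice_coefficient",
]


@dataclass
class ImageVolume:
    """A 3D scalar lattice (Hounsfield units or arbitrary intensity).

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; must be finite.
    spacing : tuple of float
        Voxel size (sx, sy, sz) in mm, all positive.
    origin : tuple of float
        World position of voxel (0, 0, 0) in mm.
    axis_order : str
        Tag recording the axis convention; data axes are (x, y, z).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent(self) -> np.ndarray:
        """Physical size of the lattice in mm along each axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing)


@dataclass
class BinaryMask:
    """A 3D {0,1} lattice sharing grid metadata with its paired volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got {arr.ndim}D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, found {vals[:10]}")
        self.data = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


def _affine(spacing, origin) -> np.ndarray:
    a = np.diag(list(spacing) + [1.0])
    a[:3, 3] = origin
    return a


def read_volume(path) -> ImageVolume:
    """Read a NIfTI file as an :class:`ImageVolume`.

    Raises a descriptive error for missing files, non-3D images and
    non-finite voxel data.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got shape {data.shape}")
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite voxels in {path}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return ImageVolume(data, tuple(float(z) for z in zooms), origin)


def read_mask(path) -> BinaryMask:
    """Read a NIfTI segmentation as a :class:`BinaryMask` (values {0,1})."""
    v = read_volume(path)
    return BinaryMask(v.data, v.spacing, v.origin)


def write_volume(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float64), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def _resample_grid(data, spacing, target_mm, order):
    extent = np.asarray(data.shape) * np.asarray(spacing)
    out_shape = np.ceil(extent / target_mm - 1e-9).astype(int)
    out_shape = np.maximum(out_shape, 1)
    axes = [np.arange(n) * target_mm / s for n, s in zip(out_shape, spacing)]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = ndimage.map_coordinates(data.astype(float), coords, order=order, mode="nearest")
    return out.reshape(tuple(out_shape))


def resample_isotropic(obj, target_mm: float = 1.0, mode: str | None = None):
    """Resample a volume or mask to an isotropic grid of ``target_mm`` spacing.

    Volumes use trilinear interpolation; masks use nearest-neighbour and are
    re-binarised so the {0,1} domain is preserved.  Output voxel ``j`` sits at
    world position ``origin + j * target_mm``, so constant and affine
    intensity fields are reproduced exactly away from the boundary.
    """
    if target_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_mm}")
    is_mask = isinstance(obj, BinaryMask)
    if mode is None:
        mode = "nearest" if is_mask else "trilinear"
    if is_mask and mode != "nearest":
        raise ValueError("masks must be resampled with mode='nearest'")
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    order = 0 if mode == "nearest" else 1
    if tuple(obj.spacing) == (target_mm,) * 3:
        return replace(obj, data=obj.data.copy())
    out = _resample_grid(obj.data.astype(float), obj.spacing, target_mm, order)
    spacing = (target_mm,) * 3
    if is_mask:
        return BinaryMask(out >= 0.5, spacing, obj.origin)
    return ImageVolume(out, spacing, obj.origin)


def extract_roi(volume: ImageVolume, mask: BinaryMask, pad: int = 4):
    """Crop volume and mask to the mask's bounding box dilated by ``pad`` voxels.

    The pad gives Gaussian-derivative filters support beyond the node
    boundary; the crop is clipped to the volume bounds.  Returns the cropped
    ``(ImageVolume, BinaryMask)`` pair with adjusted origins.
    """
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    if pad < 0:
        raise ValueError("pad must be non-negative")
    fg = np.argwhere(mask.data)
    if fg.size == 0:
        raise ValueError("empty mask: cannot extract ROI")
    lo = np.maximum(fg.min(axis=0) - pad, 0)
    hi = np.minimum(fg.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    origin = tuple(o + i * s for o, i, s in zip(volume.origin, lo, volume.spacing))
    v = ImageVolume(volume.data[sl].copy(), volume.spacing, origin)
    m = BinaryMask(mask.data[sl].copy(), mask.spacing, origin)
    return v, m


def dice_coefficient(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Both-empty masks return 1.0 (perfect agreement by convention).
    """
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)
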