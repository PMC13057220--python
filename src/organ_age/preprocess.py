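"""Organ-focused image preparation.

Mirrors the preprocessing applied to organ MRI/OCT before age regression:
per-image min-max intensity normalization, mask-guided cropping with a
tolerance margin, robust quality-control flagging of diverging segmentation
volumes, and resampling to the fixed network input grid.

Images are carried as :class:`OrganImage`: a 3D single-channel volume in
(z, y, x) order or a 2D multi-channel slice in (channel, y, x) order, plus a
binary mask on the same spatial grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .config import DataError, QCFailure


@dataclass
class OrganImage:
    """Intensity array with a binary organ mask on the same spatial grid."""

    voxels: np.ndarray  # (z, y, x) or (channel, y, x)
    mask: np.ndarray  # spatial grid, values {0, 1}
    organ: str
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        self.voxels = np.asarray(self.voxels)
        if self.voxels.shape != self.mask.shape and self.voxels.shape[1:] != self.mask.shape:
            raise DataError(
                f"mask shape {self.mask.shape} does not match image shape "
                f"{self.voxels.shape}")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise DataError("mask must be binary")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.mask.shape

    @property
    def has_channels(self) -> bool:
        """True for the 2D path, where axis 0 is a channel axis."""
        return self.voxels.shape != self.mask.shape


def normalize_intensity(img: OrganImage) -> OrganImage:
    """Min-max normalize intensities to [0, 1]; a constant image maps to zeros."""
    x = np.asarray(img.voxels, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise DataError(f"non-finite intensities in {img.organ} image")
    lo, hi = x.min(), x.max()
    if hi == lo:
        out = np.zeros_like(x)
    else:
        out = (x - lo) / (hi - lo)
    return replace(img, voxels=out, mask=img.mask)


def mask_bounding_box(mask: np.ndarray, margin: int = 0) -> tuple[slice, ...]:
    """Tight bounding box of the mask expanded by `margin` per side, clipped."""
    if not np.any(mask):
        raise QCFailure("empty mask: no organ voxels to crop to")
    slices = []
    for axis in range(mask.ndim):
        other = tuple(a for a in range(mask.ndim) if a != axis)
        profile = np.any(mask, axis=other)
        idx = np.nonzero(profile)[0]
        lo = max(int(idx[0]) - margin, 0)
        hi = min(int(idx[-1]) + margin + 1, mask.shape[axis])
        slices.append(slice(lo, hi))
    return tuple(slices)


def crop_to_organ(img: OrganImage, margin: int = 4) -> OrganImage:
    """Crop image and mask to the mask's padded bounding box.

    The margin is the tolerance added to the outer boundary of the
    segmentation; the box is clipped at the grid edge.  Never discards mask
    voxels.
    """
    box = mask_bounding_box(img.mask, margin)
    if img.has_channels:
        voxels = img.voxels[(slice(None),) + box]
    else:
        voxels = img.voxels[box]
    return replace(img, voxels=voxels, mask=img.mask[box])


def qc_flag_volumes(volumes, k: float = 5.0) -> np.ndarray:
    """Flag segmentation volumes diverging from the cohort by a robust z-score.

    Volume i is flagged iff |v_i - median| > k * 1.4826 * MAD.  With MAD = 0
    any volume differing from the median is flagged; an infinite k flags
    nothing.
    """
    v = np.asarray(volumes, dtype=np.float64)
    if v.size < 3:
        raise DataError("need at least 3 volumes for QC flagging")
    if np.isinf(k):
        return np.zeros(v.size, dtype=bool)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return v != med
    return np.abs(v - med) > k * 1.4826 * mad


def resample_to_grid(img: OrganImage, target_shape) -> OrganImage:
    """Resample to a fixed grid: linear for intensities, nearest for the mask."""
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != img.mask.ndim:
        raise DataError(
            f"target shape {target_shape} rank does not match spatial rank "
            f"{img.mask.ndim}")
    if any(t <= 0 for t in target_shape):
        raise DataError("target grid must have positive size along every axis")
    src = img.spatial_shape
    factors = tuple(t / s for t, s in zip(target_shape, src))
    in_unit = img.voxels.min() >= 0.0 and img.voxels.max() <= 1.0

    def _zoom(plane: np.ndarray) -> np.ndarray:
        out = ndimage.zoom(plane.astype(np.float64), factors, order=1,
                           mode="nearest", grid_mode=True)
        # guard against rounding in ndimage's output-shape computation
        if out.shape != target_shape:
            out = out[tuple(slice(0, t) for t in target_shape)]
        return out

    if img.has_channels:
        voxels = np.stack([_zoom(img.voxels[c]) for c in range(img.voxels.shape[0])])
    else:
        voxels = _zoom(img.voxels)
    if in_unit:
        voxels = np.clip(voxels, 0.0, 1.0)
    mask = ndimage.zoom(img.mask.astype(np.float64), factors, order=0,
                        mode="nearest", grid_mode=True)
    if mask.shape != target_shape:
        mask = mask[tuple(slice(0, t) for t in target_shape)]
    spacing = tuple(sp / f for sp, f in zip(img.spacing, factors))
    return OrganImage(voxels=voxels, mask=(mask > 0.5).astype(np.uint8),
                      organ=img.organ, spacing=spacing)


def preprocess_image(img: OrganImage, margin: int = 4,
                     target_shape=None) -> OrganImage:
    """Standard chain: normalize -> crop to organ -> resample to the grid."""
    out = crop_to_organ(normalize_intensity(img), margin=margin)
    if target_shape is not None:
        out = resample_to_grid(out, target_shape)
    return out


def save_nifti(img: OrganImage, image_path, mask_path=None) -> None:
    affine = np.diag(list(img.spacing[:3]) + [1.0] * (4 - min(3, len(img.spacing))))
    if affine.shape != (4, 4):
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(img.voxels, dtype=np.float32), affine),
             str(image_path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(np.asarray(img.mask, dtype=np.uint8), affine),
                 str(mask_path))


def load_nifti(image_path, mask_path, organ: str) -> OrganImage:
    image = nib.load(str(image_path))
    mask = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in image.header.get_zooms()[:3])
    return OrganImage(voxels=np.asarray(image.dataobj, dtype=np.float64),
                      mask=(np.asarray(mask.dataobj) > 0.5).astype(np.uint8),
                      organ=organ, spacing=spacing)
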