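"""Reading/writing slices and masks, and 2-D brain extraction.

The segmentation pipeline operates on single 2-D 8-bit gray-level slices.
Slices can be read from PNG/TIFF files or pulled out of NIfTI volumes
(slices taken along the last axis, no reorientation).  Images with more
than 8 bits per pixel are linearly rescaled to the 0-255 range.

Brain extraction follows a five-step morphological recipe: (1) global
Otsu binarisation, (2) morphological opening and removal of tiny regions,
(3) retention of centrally located components (those whose centroid lies
within the central portion of the image and whose area is a non-trivial
fraction of it — peripheral scalp and skull fall outside), (4) dilation
and hole filling, (5) application of the mask to the image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import dilation as _sk_dilation, disk, opening as _sk_opening, remove_small_objects

__all__ = ["BrainExtractionConfig", "read_slice", "write_mask", "write_image",
           "extract_brain", "apply_mask"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


@dataclass(frozen=True)
class BrainExtractionConfig:
    """Tunables of the five-step brain extraction (defaults for 256-512 px
    slices): opening/dilation disk radii, the minimum component area in
    pixels, the central fraction of the image extent a component centroid
    must fall into, and the minimum component area as a fraction of the
    image."""

    opening_radius: int = 3
    dilation_radius: int = 2
    min_area: int = 50
    central_fraction: float = 0.6
    min_area_fraction: float = 0.01


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def _to_uint8(data: np.ndarray) -> np.ndarray:
    """Linearly rescale anything beyond 8 bits into 0-255 and round."""
    if data.dtype == np.uint8:
        return data
    data = np.asarray(data, dtype=float)
    if np.issubdtype(np.asarray(data).dtype, np.floating) or data.max() > 255 or data.min() < 0:
        lo, hi = float(data.min()), float(data.max())
        if hi > lo:
            data = (data - lo) / (hi - lo) * 255.0
        else:
            data = np.zeros_like(data)
    return np.round(data).astype(np.uint8)


def read_slice(path, slice_index: int | None = None) -> np.ndarray:
    """Read a 2-D grayscale slice as an 8-bit array.

    PNG/TIFF files are read directly; for NIfTI volumes ``slice_index``
    selects a slice along the last axis.  Integer images wider than 8 bits
    are rescaled by their dtype range (so a 16-bit image with values
    {0, 65535} maps to {0, 255}); float images are min-max rescaled.
    """
    path = Path(path)
    if _is_nifti(path):
        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim == 2:
            data = vol
        else:
            if slice_index is None:
                raise ValueError("a slice_index is required for NIfTI volumes")
            if not (0 <= slice_index < vol.shape[-1]):
                raise IndexError(
                    f"slice index {slice_index} out of range for volume with "
                    f"{vol.shape[-1]} slices"
                )
            data = vol[..., slice_index]
    else:
        data = iio.imread(path)
        if data.ndim == 3:
            channels = data.reshape(-1, data.shape[-1])
            if not (channels[:, :3] == channels[:, :1]).all():
                raise ValueError(f"{path} is a colour image, not grayscale")
            data = data[..., 0]
    if data.ndim != 2:
        raise ValueError(f"{path} does not contain a 2-D slice")
    if np.issubdtype(data.dtype, np.integer) and data.dtype != np.uint8:
        info = np.iinfo(data.dtype)
        data = np.round(data.astype(float) * 255.0 / info.max).astype(np.uint8)
        return data
    return _to_uint8(np.asarray(data))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as PNG (0/255) or NIfTI (0/1)."""
    path = Path(path)
    mask = np.asarray(mask).astype(bool)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), str(path))
    else:
        iio.imwrite(path, (mask * 255).astype(np.uint8))


def write_image(path, image: np.ndarray) -> None:
    """Write a gray or float image (8-bit PNG, float TIFF, or NIfTI)."""
    path = Path(path)
    image = np.asarray(image)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(image.astype(np.float32), np.eye(4)), str(path))
    elif path.suffix.lower() in (".tif", ".tiff") and np.issubdtype(image.dtype, np.floating):
        iio.imwrite(path, image.astype(np.float32))
    else:
        iio.imwrite(path, _to_uint8(image))


def extract_brain(image: np.ndarray, cfg: BrainExtractionConfig | None = None) -> np.ndarray:
    """Single connected brain mask of a head slice (see module docstring)."""
    if cfg is None:
        cfg = BrainExtractionConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not image.any():
        raise ValueError("all-zero image: no brain to extract")

    binary = image > threshold_otsu(image)
    binary = _sk_opening(binary, disk(cfg.opening_radius))
    binary = remove_small_objects(binary, max_size=cfg.min_area - 1)

    h, w = image.shape
    margin_r = (1.0 - cfg.central_fraction) / 2.0 * h
    margin_c = (1.0 - cfg.central_fraction) / 2.0 * w
    min_area = cfg.min_area_fraction * h * w
    comp = cc_label(binary, connectivity=2)
    keep = np.zeros_like(binary)
    for region in regionprops(comp):
        cy, cx = region.centroid
        central = (margin_r <= cy <= h - margin_r) and (margin_c <= cx <= w - margin_c)
        if central and region.area >= min_area:
            keep |= comp == region.label

    mask = _sk_dilation(keep, disk(cfg.dilation_radius))
    mask = binary_fill_holes(mask)
    if not mask.any():
        raise ValueError("brain extraction produced an empty mask")
    comp = cc_label(mask, connectivity=2)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    return comp == int(np.argmax(sizes))


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out-of-mask pixels; in-mask pixels are unchanged."""
    image = np.asarray(image)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    return np.where(mask, image, 0)
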