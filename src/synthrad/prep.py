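"""Image I/O, unit-interval normalization and fixed-bin discretization.

Discretization maps masked intensities to integer gray levels 1..B
(0 outside the mask), the substrate for all texture matrices.  The number
of bins is fixed (default 20) and the bin width is derived per image from
the in-mask intensity range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = ["QuantizedImage", "read_image", "write_nifti", "write_png",
           "normalize_unit", "quantize"]

DEFAULT_BINS = 20


@dataclass
class QuantizedImage:
    """Masked image discretized to integer gray levels 1..B.

    ``levels`` holds 0 outside the mask and a level in [1, B] inside;
    ``bin_edges`` are the B+1 ascending intensity thresholds used.
    """

    levels: np.ndarray
    n_bins: int
    bin_edges: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        inside = self.levels[self.mask.astype(bool)]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_bins):
            raise ValueError("in-mask levels must lie in [1, n_bins]")
        if (self.levels[~self.mask.astype(bool)] != 0).any():
            raise ValueError("out-of-mask levels must be 0")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.astype(bool).sum())


def read_image(path: str | Path, slice_index: int | None = None) -> np.ndarray:
    """Read a 2D grayscale image from PNG or NIfTI.

    NIfTI scaling (slope/intercept) is applied by nibabel; a 3D volume with
    a singleton dimension is squeezed to 2D, and a genuine multi-slice
    volume requires an explicit ``slice_index`` (last axis).
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        data = np.squeeze(data)
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError(
                    f"{path} is a multi-slice volume; pass an explicit slice_index"
                )
            data = data[..., slice_index]
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a 2D slice, got shape {data.shape}")
        return data
    if name.endswith(".png"):
        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse RGB(A) written by other tools
            arr = arr[..., :3].mean(axis=-1)
        return arr.astype(float)
    raise ValueError(f"unsupported image format: {path}")


def write_nifti(path: str | Path, image: np.ndarray) -> None:
    """Write a 2D array as a float32 NIfTI with identity affine."""
    img = nib.Nifti1Image(np.asarray(image, dtype=np.float32), np.eye(4))
    nib.save(img, str(path))


def write_png(path: str | Path, image: np.ndarray) -> None:
    """Write a [0,1] 2D array as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 255).astype(np.uint8))


def normalize_unit(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]: (x - min) / (max - min)."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        raise ValueError("constant image: degenerate intensity range")
    return (image - lo) / (hi - lo)


def quantize(image: np.ndarray, mask: np.ndarray, n_bins: int = DEFAULT_BINS) -> QuantizedImage:
    """Discretize in-mask intensities to levels 1..n_bins.

    Bin width w = (max - min) / n_bins over the masked pixels only;
    level(x) = min(floor((x - min)/w) + 1, n_bins).  A constant in-mask
    image maps everything to level 1.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    image = np.asarray(image, dtype=float)
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
        edges = lo + np.arange(n_bins + 1, dtype=float)  # degenerate but ascending
    else:
        w = (hi - lo) / n_bins
        lv = np.floor((image - lo) / w).astype(np.int32) + 1
        np.minimum(lv, n_bins, out=lv)
        levels[mask] = lv[mask]
        edges = lo + w * np.arange(n_bins + 1)
    return QuantizedImage(levels=levels, n_bins=n_bins, bin_edges=edges,
                          mask=mask.astype(np.uint8))
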