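"""Leaf image loading, segmentation, contrast stretch, vein extraction.

Images are transmitted-light scans: one leaf per frame, lamina darker than
the bright background, veins brighter than the surrounding mesophyll
because they transmit more light.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


class SegmentationError(RuntimeError):
    pass


@dataclass
class GrayImage:
    """2-D grid of intensities normalised to [0, 1]."""

    values: np.ndarray
    bitdepth_src: int = 8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("GrayImage values must be 2-D")
        if min(self.values.shape) < 32:
            raise ValueError("image smaller than 32 pixels on a side")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite intensities")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryMask:
    """0/1 grid; role is 'leaf' or 'venation'."""

    values: np.ndarray
    role: str = "leaf"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(np.uint8)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.role not in ("leaf", "venation"):
            raise ValueError(f"unknown mask role {self.role!r}")

    def count(self) -> int:
        return int(self.values.sum())


# ITU-R BT.709 luminance weights, as used by skimage.color.rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])


def load_image(path) -> GrayImage:
    """Load a PNG/TIFF/JPEG as a normalised grayscale image.

    RGB is reduced by standard luminance weighting; integer intensities are
    divided by 2^bitdepth - 1.
    """
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise OSError(f"cannot read image file {path}: empty image")
    if arr.dtype == np.uint8:
        bitdepth, scale = 8, 255.0
    elif arr.dtype == np.uint16:
        bitdepth, scale = 16, 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        bitdepth, scale = 8, 1.0
    else:
        raise ValueError(f"unsupported image dtype {arr.dtype} in {path}")
    vals = arr.astype(np.float64) / scale
    if vals.ndim == 3:
        if vals.shape[2] == 4:  # drop alpha
            vals = vals[:, :, :3]
        if vals.shape[2] != 3:
            raise ValueError(
                f"unsupported channel count {vals.shape[2]} in {path}")
        vals = vals @ _LUMA
    elif vals.ndim != 2:
        raise ValueError(f"unsupported image dimensionality in {path}")
    return GrayImage(np.clip(vals, 0.0, 1.0), bitdepth_src=bitdepth)


def segment_leaf(img: GrayImage, dark_leaf: bool = True) -> BinaryMask:
    """Global (Otsu) threshold, keep the largest 4-connected component,
    fill interior holes.

    dark_leaf selects the polarity: True for a dark leaf on a light
    background (the transmitted-light convention).
    """
    from scipy.ndimage import binary_fill_holes
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    vals = img.values
    if vals.max() == vals.min():
        raise SegmentationError("uniform image: no foreground found")
    thresh = threshold_otsu(vals)
    fg = vals < thresh if dark_leaf else vals > thresh
    if not fg.any():
        raise SegmentationError("empty foreground after global threshold")
    lab = label(fg, connectivity=1)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    keep = lab == largest
    keep = binary_fill_holes(keep)
    touched = int(keep[0, :].any()) + int(keep[-1, :].any()) + \
        int(keep[:, 0].any()) + int(keep[:, -1].any())
    if touched >= 3:
        log.warning("leaf mask touches %d image borders; leaf may be cropped",
                    touched)
    return BinaryMask(keep, role="leaf")


def enhance_contrast(img: GrayImage, mask: BinaryMask,
                     p_lo: float = 1.0, p_hi: float = 99.0) -> GrayImage:
    """Linear stretch of within-mask intensities to span [0, 1].

    The [p_lo, p_hi] percentile range maps to [0, 1] with clipping; the
    background is set to 1.0 (transmitted light: background is bright).
    """
    if mask.role != "leaf":
        raise ValueError("enhance_contrast expects a leaf mask")
    fg = mask.values.astype(bool)
    if not fg.any():
        raise ValueError("empty leaf mask")
    inside = img.values[fg]
    lo, hi = np.percentile(inside, [p_lo, p_hi])
    if hi <= lo:
        warnings.warn("constant within-mask intensity; contrast unchanged")
        return img
    out = np.ones_like(img.values)
    out[fg] = np.clip((img.values[fg] - lo) / (hi - lo), 0.0, 1.0)
    return GrayImage(out, bitdepth_src=img.bitdepth_src)


def extract_venation(img: GrayImage, mask: BinaryMask,
                     scales=(1, 2, 4), bright_veins: bool = True,
                     low_quantile: float = 0.85, high_quantile: float = 0.97,
                     min_size: int = 20) -> BinaryMask:
    """Multiscale Hessian ridge enhancement + hysteresis threshold.

    The Sato tubeness filter responds to curvilinear bright (or dark)
    structures at the given scales; hysteresis keeps ridge pixels above the
    low response quantile that connect to a pixel above the high quantile.
    Components smaller than min_size pixels are removed.  The result is
    contained in the leaf mask.
    """
    from skimage.filters import apply_hysteresis_threshold, sato
    from skimage.morphology import remove_small_objects

    fg = mask.values.astype(bool)
    if not fg.any():
        raise ValueError("empty leaf mask")
    signal = img.values.copy()
    # pad background with the lamina median so mask edges do not ring
    signal[~fg] = np.median(img.values[fg])
    ridge = sato(signal, sigmas=scales, black_ridges=not bright_veins)
    ridge[~fg] = 0.0
    inside = ridge[fg]
    lo = np.quantile(inside, low_quantile)
    hi = np.quantile(inside, high_quantile)
    vein = apply_hysteresis_threshold(ridge, lo, hi) & fg
    vein = remove_small_objects(vein, max_size=min_size - 1, connectivity=2)
    if not vein.any():
        raise RuntimeError(
            "empty venation mask; lower the quantile thresholds or scales")
    return BinaryMask(vein, role="venation")
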