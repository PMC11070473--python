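"""Stem/background segmentation and contour extraction.

The stem is separated from the field background in HSV space: a hue gate
selects green vegetation, and Otsu's threshold on the saturation channel
inside that gate adapts the split to illumination (dusty low-saturation
soil vs. saturated stem tissue).  The one-pixel inner contour is the
morphological internal gradient, mask minus its erosion.

All filters use reflection padding so borders are not eroded artificially,
and every output is a strict {0, 1} raster of the input shape.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv

from .exceptions import EmptyMaskError, ParameterError

__all__ = [
    "hsv_otsu_segment",
    "otsu_threshold",
    "denoise",
    "largest_component",
    "internal_gradient_contour",
    "elliptical_element",
]

#: 8-connectivity structure used throughout the pipeline
STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def elliptical_element(ksize: int) -> np.ndarray:
    """Axis-aligned elliptical structuring element of size ksize x ksize.

    For ksize=3 this is the 4-connected cross; for ksize=5 a discrete disk.
    """
    if ksize < 1 or ksize % 2 == 0:
        raise ParameterError("structuring element size must be odd and >= 1")
    r = ksize // 2
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    if r == 0:
        return np.ones((1, 1), dtype=bool)
    return (x / r) ** 2 + (y / r) ** 2 <= 1.0 + 1e-9


def _as_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    return mask.astype(bool)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin histogram.

    Returns the level ``t`` maximizing the between-class variance of the
    split ``{<= t}`` vs ``{> t}``; ties are broken by the smallest level.
    A single-valued histogram is degenerate: a warning is issued and the
    occupied level returned.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or hist.size != 256:
        raise ParameterError("histogram must have 256 bins")
    total = hist.sum()
    if total <= 0:
        raise ParameterError("histogram is empty")
    occupied = np.nonzero(hist)[0]
    if occupied.size == 1:
        warnings.warn("single-valued histogram; Otsu threshold is degenerate")
        return int(occupied[0])

    levels = np.arange(256)
    w0 = np.cumsum(hist)                    # mass of class {<= t}
    m0 = np.cumsum(hist * levels)           # first moment of class {<= t}
    w1 = total - w0
    mu_total = m0[-1]
    # between-class variance, defined 0 where a class is empty
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mu_total - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, 0.0)
    return int(np.argmax(sigma_b))          # argmax takes the smallest tie


def otsu_efficiency(histogram: np.ndarray, level: int) -> float:
    """Otsu's separability measure eta = sigma_between / sigma_total at a level.

    Close to 1 for well-separated bimodal histograms; a unimodal histogram
    tops out near 0.64 (the Gaussian split-at-the-mean limit), which is what
    the bimodality guard in :func:`hsv_otsu_segment` exploits.
    """
    hist = np.asarray(histogram, dtype=float)
    total = hist.sum()
    levels = np.arange(256)
    mu = (hist * levels).sum() / total
    var_total = (hist * (levels - mu) ** 2).sum() / total
    if var_total <= 0:
        return 0.0
    w0 = hist[:level + 1].sum() / total
    w1 = 1.0 - w0
    if w0 <= 0 or w1 <= 0:
        return 0.0
    mu0 = (hist[:level + 1] * levels[:level + 1]).sum() / (w0 * total)
    mu1 = (hist[level + 1:] * levels[level + 1:]).sum() / (w1 * total)
    return float(w0 * w1 * (mu0 - mu1) ** 2 / var_total)


def hsv_otsu_segment(rgb: np.ndarray,
                     hue_range: tuple[float, float] = (35.0, 85.0),
                     min_separability: float = 0.75) -> np.ndarray:
    """Segment green stem pixels from the background.

    The image is converted to HSV; pixels whose hue (degrees, 0-360) falls
    in ``hue_range`` form the vegetation gate.  Otsu's threshold on the
    8-bit saturation histogram inside the gate then discards low-saturation
    (soil-colored) pixels.  When the gated saturation histogram is not
    meaningfully bimodal (separability below ``min_separability``) the
    Otsu split would only bisect sensor noise, so the whole gate is kept.

    Returns a uint8 {0, 1} mask of the input shape.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ParameterError("expected an (H, W, 3) color image")
    if rgb.dtype != np.uint8:
        raise ParameterError("expected an 8-bit color image")

    hsv = rgb2hsv(rgb)
    hue_deg = hsv[..., 0] * 360.0
    sat = np.rint(hsv[..., 1] * 255.0).astype(np.uint8)

    lo, hi = hue_range
    gate = (hue_deg >= lo) & (hue_deg <= hi) if lo <= hi else \
           (hue_deg >= lo) | (hue_deg <= hi)   # wrap-around gate
    if not gate.any():
        warnings.warn("hue gate matched no pixels; returning empty mask")
        return np.zeros(rgb.shape[:2], dtype=np.uint8)

    hist = np.bincount(sat[gate].ravel(), minlength=256).astype(float)
    occupied = np.nonzero(hist)[0]
    if occupied.size == 1:
        mask = gate
    else:
        level = otsu_threshold(hist)
        if otsu_efficiency(hist, level) < min_separability:
            mask = gate
        else:
            # stems are the saturated class within the vegetation gate
            mask = gate & (sat > level)
    return mask.astype(np.uint8)


def _median_filter_binary(mask: np.ndarray, ksize: int) -> np.ndarray:
    """Median of a binary raster with reflection padding, re-binarized at 0.5."""
    med = ndimage.median_filter(mask.astype(np.uint8), size=ksize, mode="reflect")
    return med > 0.5


def denoise(mask: np.ndarray, median_ksize: int = 5, open_ksize: int = 3) -> np.ndarray:
    """Median filtering followed by morphological opening.

    Removes speckle noise (median, strict-majority of a ``median_ksize``
    window) and thin protrusions (opening with an elliptical element of
    size ``open_ksize``), both with reflection padding.
    """
    mask = _as_binary(mask)
    if median_ksize > min(mask.shape) or open_ksize > min(mask.shape):
        raise ParameterError("kernel larger than image")
    if median_ksize % 2 == 0 or open_ksize % 2 == 0:
        raise ParameterError("kernel sizes must be odd")

    med = _median_filter_binary(mask, median_ksize)

    elem = elliptical_element(open_ksize)
    r = open_ksize // 2
    padded = np.pad(med, r, mode="reflect")
    opened = ndimage.binary_opening(padded, structure=elem)[r:-r, r:-r]
    return opened.astype(np.uint8)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties are broken by the component containing the smallest row-major
    pixel index (top-left first).
    """
    mask = _as_binary(mask)
    if not mask.any():
        raise EmptyMaskError("cannot extract a component from an empty mask")
    labels, n = ndimage.label(mask, structure=STRUCTURE_8)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = sizes.max()
    # scipy labels components in row-major discovery order, so among equal
    # sizes the smallest label is the one met first from the top-left
    winner = int(np.nonzero(sizes == best)[0][0])
    return (labels == winner).astype(np.uint8)


def internal_gradient_contour(mask: np.ndarray, ksize: int = 3) -> np.ndarray:
    """Inner boundary of a mask: mask minus its erosion.

    Uses an elliptical ``ksize`` element with reflection padding.  The
    result is a closed one-to-two-pixel boundary contained in the mask,
    with no interior pixels.
    """
    mask = _as_binary(mask)
    if not mask.any():
        return np.zeros_like(mask, dtype=np.uint8)
    elem = elliptical_element(ksize)
    r = ksize // 2
    padded = np.pad(mask, r, mode="reflect")
    eroded = ndimage.binary_erosion(padded, structure=elem)[r:-r, r:-r]
    return (mask & ~eroded).astype(np.uint8)
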