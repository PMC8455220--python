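"""Grayscale morphology and reconstruction by dilation/erosion.

Reconstruction iterates a geodesic step to a fixed point:

    dilation reconstruction:  g <- min(dilate(g), f)   (marker g <= mask f)
    erosion  reconstruction:  g <- max(erode(g),  f)   (marker g >= mask f)

Opening/closing by reconstruction compose these with a plain erosion or
dilation to build markers; the alternating composition used here
(opening-by-reconstruction followed by closing-by-reconstruction, and
its dual) removes bright and dark noise grains simultaneously while
preserving object contours, which is what makes the reconstructed image
a good clustering substrate for heavily corrupted inputs.

Border handling is truncated everywhere: dilation/erosion take the
max/min over the in-image part of the structuring-element footprint,
so no artificial extrema appear at the edges.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import reconstruction as _sk_reconstruction

__all__ = [
    "square_se",
    "dilate",
    "erode",
    "reconstruct_dilation",
    "reconstruct_erosion",
    "opening_reconstruction",
    "closing_reconstruction",
    "reconstruct_image",
]


def square_se(size: int = 3) -> np.ndarray:
    """Full square structuring element of odd side ``size``."""
    if size < 1 or size % 2 == 0:
        raise ValueError("structuring element size must be a positive odd integer")
    return np.ones((size, size), dtype=bool)


def _check_image(img) -> np.ndarray:
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a


def _check_se(se) -> np.ndarray:
    if se is None:
        return square_se(3)
    b = np.asarray(se, dtype=bool)
    if b.ndim != 2 or b.shape[0] % 2 == 0 or b.shape[1] % 2 == 0:
        raise ValueError("structuring element must be 2-D with odd side lengths")
    if not b[b.shape[0] // 2, b.shape[1] // 2]:
        raise ValueError("structuring element center must be set")
    return b


def dilate(img, se=None) -> np.ndarray:
    """Grayscale dilation: window maximum over the SE footprint."""
    a = _check_image(img)
    b = _check_se(se)
    return ndimage.maximum_filter(a, footprint=b, mode="constant", cval=-np.inf)


def erode(img, se=None) -> np.ndarray:
    """Grayscale erosion: window minimum over the SE footprint."""
    a = _check_image(img)
    b = _check_se(se)
    return ndimage.minimum_filter(a, footprint=b, mode="constant", cval=np.inf)


def reconstruct_dilation(mask, marker, se=None) -> np.ndarray:
    """Reconstruction by dilation of ``marker`` under ``mask`` (marker <= mask)."""
    f = _check_image(mask)
    g = _check_image(marker)
    b = _check_se(se)
    if f.shape != g.shape:
        raise ValueError("mask and marker must share a shape")
    excess = float(np.max(g - f))
    if excess > 0.0:
        raise ValueError(
            f"marker must be <= mask everywhere; max violation {excess:.3g}"
        )
    return _sk_reconstruction(g, f, method="dilation", footprint=b)


def reconstruct_erosion(mask, marker, se=None) -> np.ndarray:
    """Reconstruction by erosion of ``marker`` over ``mask`` (marker >= mask)."""
    f = _check_image(mask)
    g = _check_image(marker)
    b = _check_se(se)
    if f.shape != g.shape:
        raise ValueError("mask and marker must share a shape")
    deficit = float(np.max(f - g))
    if deficit > 0.0:
        raise ValueError(
            f"marker must be >= mask everywhere; max violation {deficit:.3g}"
        )
    return _sk_reconstruction(g, f, method="erosion", footprint=b)


def opening_reconstruction(f, se=None) -> np.ndarray:
    """Opening-by-reconstruction followed by closing-by-reconstruction of it."""
    b = _check_se(se)
    opened = reconstruct_dilation(f, erode(f, b), b)
    return reconstruct_erosion(opened, dilate(opened, b), b)


def closing_reconstruction(f, se=None) -> np.ndarray:
    """Closing-by-reconstruction followed by opening-by-reconstruction of it."""
    b = _check_se(se)
    closed = reconstruct_erosion(f, dilate(f, b), b)
    return reconstruct_dilation(closed, erode(closed, b), b)


def reconstruct_image(f, se=None) -> np.ndarray:
    """Denoised clustering substrate: the closing reconstruction of ``f``.

    Computed once per image, before any clustering iteration starts.
    """
    return closing_reconstruction(f, se)
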