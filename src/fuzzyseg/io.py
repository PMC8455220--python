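"""Reading and writing images and label maps.

Grayscale images travel as 8- or 16-bit PNG (or any format imageio can
read) or as raw ``.npy`` arrays; internally everything is a float array
on [0, 1].  Label maps are stored as 8-bit integer PNG.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .synthetic import normalize_image

__all__ = ["read_image", "write_image", "read_labels", "write_labels"]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image and normalize it onto [0, 1]."""
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse RGB(A) to luminance
            arr = np.asarray(arr, dtype=np.float64)[..., :3].mean(axis=-1)
            return normalize_image(arr)
    return normalize_image(arr)


def write_image(path: str | Path, img, bits: int = 8) -> None:
    """Write a [0, 1] image as 8- or 16-bit grayscale PNG or raw ``.npy``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    a = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    if path.suffix == ".npy":
        np.save(path, a)
        return
    if bits == 8:
        iio.imwrite(path, np.round(a * 255).astype(np.uint8))
    elif bits == 16:
        iio.imwrite(path, np.round(a * 65535).astype(np.uint16))
    else:
        raise ValueError("bits must be 8 or 16")


def read_labels(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path).astype(np.intp)
    return np.asarray(iio.imread(path)).astype(np.intp)


def write_labels(path: str | Path, labels) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lab = np.asarray(labels)
    if lab.min() < 0 or lab.max() > 255:
        raise ValueError("label values must fit in 8 bits")
    if path.suffix == ".npy":
        np.save(path, lab.astype(np.intp))
        return
    iio.imwrite(path, lab.astype(np.uint8))
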