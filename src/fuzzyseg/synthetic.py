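"""Synthetic test phantoms and noise models.

Two phantoms are provided, each with a pixel-aligned ground-truth label
map:

``ST`` — three-class image (grayscale levels 0, 85, 170 on the 8-bit
scale): three equal-width vertical bands, plus a disk straddling the
first band boundary and a square straddling the second.  The overlays
guarantee that the image contains both large homogeneous regions and
curved as well as straight class boundaries.

``SF`` — four-class image (levels 0, 85, 170, 255): a 2x2 quadrant
layout with a centered disk crossing all four quadrants.

The layouts are defined in relative coordinates, so phantoms can be
rendered at any size; the canonical size is 256 x 256.  Images are
returned on the normalized [0, 1] intensity scale.

Noise conventions (all on the [0, 1] scale, output clipped to [0, 1]):

* ``gaussian``: additive zero-mean Gaussian with *variance* = level
  (the ``imnoise`` convention, so "5% Gaussian" means variance 0.05).
* ``salt_pepper``: exactly round(level * N) pixels replaced, half by 1
  (salt) and half by 0 (pepper), positions uniform without replacement;
  an odd corruption count gives the extra pixel to salt.
* ``rician``: each pixel v becomes sqrt((v + n1)^2 + n2^2) with n1, n2
  independent N(0, sigma), sigma = level * reference intensity
  (default: the brightest intensity present) — the magnitude-MRI noise
  model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PHANTOM_INTENSITIES",
    "PhantomSpec",
    "NoiseSpec",
    "make_phantom",
    "add_noise",
    "normalize_image",
]

#: 8-bit class intensities of each phantom, in label order.
PHANTOM_INTENSITIES = {
    "ST": (0, 85, 170),
    "SF": (0, 85, 170, 255),
}


@dataclass(frozen=True)
class PhantomSpec:
    """A named phantom at a given square size (canonical: 256)."""

    name: str
    size: int = 256

    def __post_init__(self):
        if self.name not in PHANTOM_INTENSITIES:
            raise ValueError(
                f"unknown phantom {self.name!r}; valid options: "
                f"{sorted(PHANTOM_INTENSITIES)}"
            )
        if self.size < 8:
            raise ValueError("phantom size must be >= 8")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise kind, level (fraction, e.g. 0.05 for '5%'), and RNG seed."""

    kind: str
    level: float
    seed: object = None

    def __post_init__(self):
        if self.kind not in ("gaussian", "salt_pepper", "rician"):
            raise ValueError(
                f"unknown noise kind {self.kind!r}; valid options: "
                "['gaussian', 'rician', 'salt_pepper']"
            )
        if not self.level > 0:
            raise ValueError("noise level must be > 0")
        if self.kind == "salt_pepper" and self.level > 1:
            raise ValueError("salt & pepper level must lie in (0, 1]")


def make_phantom(spec: PhantomSpec | str, size: int = 256):
    """Render a phantom and its ground-truth label map.

    Returns ``(image, labels)`` with the image on [0, 1] and labels as an
    integer array of class indices.  Deterministic: no randomness.
    """
    if isinstance(spec, str):
        spec = PhantomSpec(spec, size)
    n = spec.size
    rr, cc = np.mgrid[0:n, 0:n]
    r = (rr + 0.5) / n  # pixel-center coordinates in [0, 1]
    c = (cc + 0.5) / n

    if spec.name == "ST":
        labels = np.minimum((cc * 3) // n, 2).astype(np.intp)
        # disk (class 2) crossing the 1/3 band boundary
        disk = (r - 1 / 3) ** 2 + (c - 1 / 3) ** 2 <= 0.156**2
        labels[disk] = 2
        # square (class 0) crossing the 2/3 band boundary
        square = (np.abs(r - 0.70) <= 0.117) & (np.abs(c - 0.665) <= 0.117)
        labels[square] = 0
    else:  # SF
        labels = (2 * (r >= 0.5) + (c >= 0.5)).astype(np.intp)
        disk = (r - 0.5) ** 2 + (c - 0.5) ** 2 <= 0.22**2
        labels[disk] = 3

    levels = np.asarray(PHANTOM_INTENSITIES[spec.name], dtype=np.float64) / 255.0
    return levels[labels], labels


def normalize_image(img) -> np.ndarray:
    """Map an arbitrary grayscale image onto the [0, 1] working scale."""
    a = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        info = np.iinfo(np.asarray(img).dtype)
        return a / float(info.max)
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def add_noise(img, spec: NoiseSpec) -> np.ndarray:
    """Corrupt a [0, 1] image according to ``spec``; clipped back to [0, 1].

    Deterministic for a given (image, spec) pair.
    """
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("image must be normalized to [0, 1] before adding noise")
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "gaussian":
        out = a + rng.normal(0.0, np.sqrt(spec.level), size=a.shape)
    elif spec.kind == "salt_pepper":
        n = a.size
        n_corrupt = int(round(spec.level * n))
        idx = rng.choice(n, size=n_corrupt, replace=False)
        n_salt = (n_corrupt + 1) // 2  # odd count: extra pixel is salt
        out = a.copy().ravel()
        out[idx[:n_salt]] = 1.0
        out[idx[n_salt:]] = 0.0
        out = out.reshape(a.shape)
    else:  # rician
        ref = float(a.max()) if a.max() > 0 else 1.0
        sigma = spec.level * ref
        n1 = rng.normal(0.0, sigma, size=a.shape)
        n2 = rng.normal(0.0, sigma, size=a.shape)
        out = np.sqrt((a + n1) ** 2 + n2**2)

    return np.clip(out, 0.0, 1.0)
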