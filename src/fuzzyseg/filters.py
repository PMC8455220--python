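"""Window filters with truncated-border semantics.

All filters in this module treat a pixel's window as the intersection of
the centered square window with the image: near borders the window simply
contains fewer pixels and statistics are normalized by the actual count.
No padding is ever introduced, so border pixels never see invented values
— important here because the filtered quantities are fuzzy membership
maps whose range must stay meaningful.

The guided filter follows the local linear model

    q_i = a_k I_i + b_k   for i in window w_k,

with per-window coefficients obtained from a ridge-regularized regression
of the input p on the guidance I:

    a_k = (mean(I p) - mu_k pbar_k) / (sigma_k^2 + eps),
    b_k = pbar_k - a_k mu_k,

and the final output q_i = abar_i I_i + bbar_i, where the bars denote
window means.  The guidance actually used is rho * I; scaling the
guidance by rho is mathematically equivalent to replacing eps by
eps / rho^2, which is the handle the clustering variants use to adapt
the filter's smoothing strength to the noise level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GuidedFilterParams",
    "GuidedFilter",
    "box_mean",
    "median_filter",
    "guided_filter",
]


def _as_image(img) -> np.ndarray:
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a


def _window_sum(a: np.ndarray, radius: int) -> np.ndarray:
    """Sum of ``a`` over the (2r+1)^2 window clipped to the image."""
    h, w = a.shape
    c = np.zeros((h + 1, w + 1), dtype=np.float64)
    np.cumsum(a, axis=0, out=c[1:, 1:])
    np.cumsum(c[1:, 1:], axis=1, out=c[1:, 1:])
    i = np.arange(h)
    j = np.arange(w)
    i0 = np.clip(i - radius, 0, h)
    i1 = np.clip(i + radius + 1, 0, h)
    j0 = np.clip(j - radius, 0, w)
    j1 = np.clip(j + radius + 1, 0, w)
    return (
        c[np.ix_(i1, j1)] - c[np.ix_(i0, j1)] - c[np.ix_(i1, j0)] + c[np.ix_(i0, j0)]
    )


def _window_count(shape: tuple[int, int], radius: int) -> np.ndarray:
    h, w = shape
    i = np.arange(h)
    j = np.arange(w)
    ci = np.clip(i + radius + 1, 0, h) - np.clip(i - radius, 0, h)
    cj = np.clip(j + radius + 1, 0, w) - np.clip(j - radius, 0, w)
    return ci[:, None] * cj[None, :].astype(np.float64)


def box_mean(img, radius: int = 1) -> np.ndarray:
    """Mean over the square window of half-width ``radius``, truncated at borders."""
    a = _as_image(img)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return _window_sum(a, radius) / _window_count(a.shape, radius)


def median_filter(img, radius: int = 1) -> np.ndarray:
    """Median over the truncated square window.

    Border windows contain only in-image pixels; an even-sized border
    window uses the usual midpoint convention for the median.
    """
    a = _as_image(img)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    h, w = a.shape
    side = 2 * radius + 1
    stack = np.full((side * side, h, w), np.nan)
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            layer = stack[(di + radius) * side + (dj + radius)]
            src_i = slice(max(0, -di), h - max(0, di))
            dst_i = slice(max(0, di), h - max(0, -di))
            src_j = slice(max(0, -dj), w - max(0, dj))
            dst_j = slice(max(0, dj), w - max(0, -dj))
            layer[dst_i, dst_j] = a[src_i, src_j]
    return np.nanmedian(stack, axis=0)


@dataclass(frozen=True)
class GuidedFilterParams:
    """Guided-filter configuration.

    radius : window half-width (3x3 window => radius 1).
    epsilon : ridge regularizer eps >= 0 on the window slope a_k.
    rho : influence factor multiplying the guidance image (rho = 1 means
        unscaled); equivalent to using eps / rho^2 with unscaled guidance.
    """

    radius: int = 1
    epsilon: float = 1e-4
    rho: float = 1.0

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not self.rho > 0:
            raise ValueError("rho must be > 0")


class GuidedFilter:
    """Guided filter with the guidance-image statistics precomputed.

    Intended for the clustering loops, which filter every membership map
    against the same guidance image on every iteration.
    """

    def __init__(self, guidance, params: GuidedFilterParams):
        self.params = params
        G = _as_image(guidance) * params.rho
        r = params.radius
        self._G = G
        self._mean_G = box_mean(G, r)
        # population variance over the truncated window; clamp tiny
        # negative round-off so eps=0 on constant windows is exactly 0/0
        self._var_G = np.maximum(_window_sum(G * G, r) / _window_count(G.shape, r)
                                 - self._mean_G ** 2, 0.0)

    def __call__(self, p) -> np.ndarray:
        a = _as_image(p)
        if a.shape != self._G.shape:
            raise ValueError(
                f"input shape {a.shape} != guidance shape {self._G.shape}"
            )
        r = self.params.radius
        mean_p = box_mean(a, r)
        cov_Gp = box_mean(self._G * a, r) - self._mean_G * mean_p
        denom = self._var_G + self.params.epsilon
        with np.errstate(divide="ignore", invalid="ignore"):
            ak = np.where(denom > 0.0, cov_Gp / np.where(denom > 0.0, denom, 1.0), 0.0)
        bk = mean_p - ak * self._mean_G
        return box_mean(ak, r) * self._G + box_mean(bk, r)


def guided_filter(p, guidance, params: GuidedFilterParams = GuidedFilterParams()) -> np.ndarray:
    """Edge-preserving smoothing of ``p`` steered by ``guidance``.

    The guidance image actually used is ``params.rho * guidance``.  The
    output range is not clipped; callers that need a bounded range (e.g.
    membership maps) clip and renormalize themselves.
    """
    return GuidedFilter(guidance, params)(p)
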