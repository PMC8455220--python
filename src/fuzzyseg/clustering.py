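"""The fuzzy c-means family: FCM, FCM_S1/S2, FCM+GF, IFCM_GF, MRIFCM_GF.

All variants share one Picard iteration that alternates a membership
update and a prototype update for the objective

    J(U, V) = sum_c sum_n u_cn^m ||x_n - v_c||^2,   sum_c u_cn = 1,

with closed-form updates

    u_cn = 1 / sum_j (||x_n - v_c|| / ||x_n - v_j||)^(2/(m-1)),
    v_c  = sum_n u_cn^m x_n / sum_n u_cn^m.

Variants differ in three orthogonal choices:

* spatial penalty (FCM_S1/S2): the objective gains a neighbor term
  alpha * ||xbar_n - v_c||^2, where xbar is the box-mean (S1) or
  window-median (S2) image, precomputed once;
* membership regularization (FCM+GF, IFCM_GF, MRIFCM_GF): after every
  membership update, each cluster's membership map is smoothed by the
  guided filter with the raw noisy image as guidance — scaled by the
  influence factor rho for the I-variants — then clipped and
  renormalized to keep columns stochastic;
* clustering substrate (MRIFCM_GF): memberships and prototypes are
  computed against the morphological closing reconstruction of the
  noisy image rather than the noisy image itself, while the guided
  filter keeps the *raw* image as guidance.

Convergence is declared when the objective changes by less than ``xi``
between successive iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .filters import GuidedFilter, GuidedFilterParams, box_mean, median_filter
from .morphology import reconstruct_image, square_se

__all__ = [
    "ClusteringConfig",
    "SegmentationResult",
    "update_memberships",
    "update_centers",
    "fcm",
    "fcm_s",
    "fcm_s1",
    "fcm_s2",
    "fcm_gf",
    "ifcm_gf",
    "mrifcm_gf",
    "segment",
    "METHODS",
]

logger = logging.getLogger(__name__)

_MEMBERSHIP_TOL = 1e-9


@dataclass(frozen=True)
class ClusteringConfig:
    """Configuration shared by the whole algorithm family.

    n_clusters : number of clusters C (>= 2).
    m : fuzzifier (> 1); 2 is the conventional default.
    xi : convergence threshold on |J_t - J_{t-1}|, intensities on [0, 1].
    max_iter : Picard iteration cap; hitting it flags converged=False.
    seed : RNG seed for the random center initialization.
    alpha : neighbor-term weight for FCM_S1/S2.
    gf : guided-filter parameters for the GF variants.
    se_size : structuring-element side for MRIFCM_GF's reconstruction.
    init_centers : optional explicit initial prototypes (overrides seed).
    """

    n_clusters: int
    m: float = 2.0
    xi: float = 1e-8
    max_iter: int = 200
    seed: object = None
    alpha: float = 3.8
    gf: GuidedFilterParams = field(default_factory=GuidedFilterParams)
    se_size: int = 3
    init_centers: Sequence[float] | None = None

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not self.m > 1:
            raise ValueError("fuzzifier m must be > 1")
        if not self.xi > 0:
            raise ValueError("xi must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class SegmentationResult:
    """Hard labels plus the fuzzy state that produced them."""

    labels: np.ndarray          # (H, W) argmax over memberships
    memberships: np.ndarray     # (C, N) column-stochastic
    centers: np.ndarray         # (C,) prototype intensities
    n_iter: int
    converged: bool
    objective_trace: np.ndarray


def update_memberships(x, centers, m: float = 2.0) -> np.ndarray:
    """Membership update for fixed prototypes.

    ``x`` is the flat pixel vector, ``centers`` the C prototypes.  When a
    pixel coincides with one or more prototypes, membership is split
    equally among the coinciding clusters (crisp singleton rule).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    v = np.asarray(centers, dtype=np.float64).ravel()
    d2 = (x[None, :] - v[:, None]) ** 2
    return _memberships_from_distances(d2, m)


def _memberships_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    zero = d2 <= 0.0
    any_zero = zero.any(axis=0)
    u = np.empty_like(d2)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        np.divide(inv, inv.sum(axis=0, keepdims=True), out=u)
    if any_zero.any():
        cols = np.nonzero(any_zero)[0]
        u[:, cols] = zero[:, cols] / zero[:, cols].sum(axis=0, keepdims=True)
    return u


def update_centers(x, u, m: float = 2.0, rng=None) -> np.ndarray:
    """Prototype update for fixed memberships (membership-weighted means).

    A cluster whose total membership mass vanishes is re-seeded from a
    random pixel (and the event logged) rather than propagating NaN.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    um = np.asarray(u, dtype=np.float64) ** m
    mass = um.sum(axis=1)
    empty = mass <= 0.0
    if empty.any():
        rng = np.random.default_rng(rng)
        logger.warning("re-seeding %d empty cluster(s)", int(empty.sum()))
        mass[empty] = 1.0
        centers = um @ x / mass
        centers[empty] = rng.choice(x, size=int(empty.sum()))
        return centers
    return um @ x / mass


def _init_centers(x: np.ndarray, C: int, rng) -> np.ndarray:
    """Draw C distinct pixel intensities uniformly from the image."""
    uniq = np.unique(x)
    if uniq.size < C:
        raise ValueError(
            f"image has only {uniq.size} distinct intensities; cannot seed "
            f"{C} distinct prototypes"
        )
    for _ in range(100):
        v = rng.choice(x, size=C, replace=False)
        if np.unique(v).size == C:
            return np.sort(v)
    return np.sort(rng.choice(uniq, size=C, replace=False))


def _filter_memberships(u: np.ndarray, gf: GuidedFilter, shape) -> np.ndarray:
    """Guided-filter every membership map, then restore column-stochasticity.

    The filter output can leave [0, 1]; negatives are clipped to 0 and each
    pixel's column renormalized.  A pixel whose filtered column sums to 0
    falls back to its pre-filter memberships.
    """
    filtered = np.empty_like(u)
    for c in range(u.shape[0]):
        filtered[c] = gf(u[c].reshape(shape)).ravel()
    np.clip(filtered, 0.0, None, out=filtered)
    colsum = filtered.sum(axis=0)
    dead = colsum <= 0.0
    if dead.any():
        filtered[:, dead] = u[:, dead]
        colsum[dead] = 1.0
    return filtered / colsum


def _picard(
    x: np.ndarray,
    shape,
    cfg: ClusteringConfig,
    *,
    xbar: np.ndarray | None = None,
    alpha: float = 0.0,
    gf: GuidedFilter | None = None,
) -> SegmentationResult:
    """Shared alternating-update engine for the whole family."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.init_centers is not None:
        v = np.asarray(cfg.init_centers, dtype=np.float64).ravel()
        if v.size != cfg.n_clusters:
            raise ValueError("init_centers must supply n_clusters values")
    else:
        v = _init_centers(x, cfg.n_clusters, rng)

    trace = []
    j_prev = np.inf
    converged = False
    n_iter = 0
    u = None
    for n_iter in range(1, cfg.max_iter + 1):
        d2 = (x[None, :] - v[:, None]) ** 2
        if xbar is not None:
            d2 = d2 + alpha * (xbar[None, :] - v[:, None]) ** 2
        u = _memberships_from_distances(d2, cfg.m)
        if gf is not None:
            u = _filter_memberships(u, gf, shape)
        um = u**cfg.m
        mass = um.sum(axis=1)
        if (mass <= 0.0).any():
            v = update_centers(x, u, cfg.m, rng=rng)
        elif xbar is not None:
            v = (um @ (x + alpha * xbar)) / ((1.0 + alpha) * mass)
        else:
            v = (um @ x) / mass
        d2 = (x[None, :] - v[:, None]) ** 2
        if xbar is not None:
            d2 = d2 + alpha * (xbar[None, :] - v[:, None]) ** 2
        j = float((um * d2).sum())
        trace.append(j)
        if abs(j_prev - j) < cfg.xi:
            converged = True
            break
        j_prev = j

    labels = np.argmax(u, axis=0).reshape(shape)
    return SegmentationResult(
        labels=labels,
        memberships=u,
        centers=np.asarray(v, dtype=np.float64),
        n_iter=n_iter,
        converged=converged,
        objective_trace=np.asarray(trace),
    )


def _as_field(img) -> tuple[np.ndarray, tuple[int, int]]:
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a.ravel(), a.shape


def fcm(img, cfg: ClusteringConfig) -> SegmentationResult:
    """Plain fuzzy c-means on pixel intensities."""
    x, shape = _as_field(img)
    return _picard(x, shape, cfg)


def fcm_s(img, cfg: ClusteringConfig, variant: str) -> SegmentationResult:
    """FCM with a precomputed spatial neighbor term.

    ``variant`` is ``"S1"`` (box-mean neighbor image) or ``"S2"``
    (window-median neighbor image); both use a 3x3 window.  The neighbor
    term is weighted by ``cfg.alpha``.
    """
    x, shape = _as_field(img)
    if variant == "S1":
        xbar = box_mean(img, radius=1).ravel()
    elif variant == "S2":
        xbar = median_filter(img, radius=1).ravel()
    else:
        raise ValueError(f"unknown variant {variant!r}; expected 'S1' or 'S2'")
    return _picard(x, shape, cfg, xbar=xbar, alpha=cfg.alpha)


def fcm_s1(img, cfg: ClusteringConfig) -> SegmentationResult:
    return fcm_s(img, cfg, "S1")


def fcm_s2(img, cfg: ClusteringConfig) -> SegmentationResult:
    return fcm_s(img, cfg, "S2")


def fcm_gf(img, cfg: ClusteringConfig) -> SegmentationResult:
    """FCM with guided-filter membership smoothing, unscaled guidance (rho=1)."""
    x, shape = _as_field(img)
    gf = GuidedFilter(img, replace(cfg.gf, rho=1.0))
    return _picard(x, shape, cfg, gf=gf)


def ifcm_gf(img, cfg: ClusteringConfig) -> SegmentationResult:
    """FCM+GF with the guidance image scaled by the influence factor rho.

    Scaling the guidance by rho is equivalent to running the guided
    filter with regularizer epsilon / rho^2, so rho tunes how aggressively
    membership maps are smoothed relative to image edges.
    """
    x, shape = _as_field(img)
    gf = GuidedFilter(img, cfg.gf)
    return _picard(x, shape, cfg, gf=gf)


def mrifcm_gf(img, cfg: ClusteringConfig) -> SegmentationResult:
    """IFCM_GF run on the morphological closing reconstruction.

    The reconstruction beta is computed once up front and becomes the
    clustering substrate; the guided filter keeps the raw noisy image
    (scaled by rho) as guidance, so edge structure comes from the
    original data while prototypes are estimated on denoised intensities.
    """
    a = np.asarray(img, dtype=np.float64)
    beta = reconstruct_image(a, square_se(cfg.se_size))
    x, shape = _as_field(beta)
    gf = GuidedFilter(a, cfg.gf)
    return _picard(x, shape, cfg, gf=gf)


METHODS = {
    "fcm": fcm,
    "fcm_s1": fcm_s1,
    "fcm_s2": fcm_s2,
    "fcm_gf": fcm_gf,
    "ifcm_gf": ifcm_gf,
    "mrifcm_gf": mrifcm_gf,
}


def segment(img, cfg: ClusteringConfig, method: str = "mrifcm_gf") -> SegmentationResult:
    """Dispatch a segmentation by method name (see ``METHODS``)."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; valid options: {sorted(METHODS)}"
        ) from None
    return fn(img, cfg)
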