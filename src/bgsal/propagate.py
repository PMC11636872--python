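"""Error propagation, pixel-level lifting, object bias and Bayesian fusion.

Superpixel reconstruction errors are smoothed within K-means feature
clusters (context-aware propagation), lifted to pixel resolution as a
similarity-weighted mean over scales, re-weighted by a 2-D Gaussian
centered at the error-weighted centroid, and finally the dense and sparse
maps are fused by letting each serve as the prior for a likelihood built
from the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from bgsal.abstraction import FeatureMatrix, SuperpixelMap, pixel_features
from bgsal.errors import ShapeMismatchError
from bgsal.reconstruct import ErrorVector, normalize_errors

__all__ = [
    "PropagationConfig",
    "propagate_errors",
    "pixel_errors_multiscale",
    "error_weighted_centroid",
    "object_biased_reweight",
    "bayesian_integrate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropagationConfig:
    n_clusters: int = 8
    nu: float = 0.5  # mix weight: nu * cluster context + (1 - nu) * own error
    sigma_f: float = 10.0  # similarity bandwidth in feature units
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError("nu must lie in [0, 1]")
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")


def propagate_errors(
    features: FeatureMatrix,
    errors: ErrorVector,
    config: PropagationConfig | None = None,
    renormalize: bool = True,
) -> ErrorVector:
    """Smooth errors within K-means clusters of the feature space.

    Members of each cluster are processed in descending order of their
    initial error; each receives ``nu`` times the Gaussian-weighted mean
    of its cluster peers' *current* errors plus ``(1 - nu)`` times its
    own initial error.  Updated values feed into later members, so high
    errors leak toward similar low-error regions and vice versa.
    """
    config = config or PropagationConfig()
    if not errors.normalized:
        errors = normalize_errors(errors)
    X = features.F
    k = X.shape[0]
    eps0 = errors.values.astype(float).copy()
    n_clusters = min(config.n_clusters, k)
    km = KMeans(n_clusters=n_clusters, random_state=config.seed, n_init=10)
    assign = km.fit_predict(X)
    out = eps0.copy()
    inv_two_sigma_sq = 1.0 / (2.0 * config.sigma_f**2)
    for c in range(n_clusters):
        members = np.nonzero(assign == c)[0]
        if members.size <= 1:
            continue
        order = members[np.argsort(eps0[members])[::-1]]
        for i in order:
            peers = members[members != i]
            d2 = np.einsum(
                "ij,ij->i", X[peers] - X[i], X[peers] - X[i]
            )
            w = np.exp(-d2 * inv_two_sigma_sq)
            wsum = w.sum()
            if wsum <= 0:
                context = eps0[i]
            else:
                context = float(w @ out[peers]) / wsum
            out[i] = config.nu * context + (1.0 - config.nu) * eps0[i]
    ev = ErrorVector(values=out, kind=errors.kind)
    return normalize_errors(ev) if renormalize else ev


def pixel_errors_multiscale(
    per_scale_errors: list[ErrorVector],
    per_scale_maps: list[SuperpixelMap],
    per_scale_features: list[FeatureMatrix],
    image: np.ndarray,
    sigma_f: float = 10.0,
) -> np.ndarray:
    """Lift superpixel errors to pixels as a similarity-weighted mean.

    Each pixel takes, at every scale, the propagated error of the
    superpixel containing it, weighted by the Gaussian similarity between
    the pixel's own 8-dim feature and that superpixel's mean feature.
    """
    if not per_scale_errors:
        raise ValueError("need at least one scale")
    if not (len(per_scale_errors) == len(per_scale_maps) == len(per_scale_features)):
        raise ShapeMismatchError("per-scale lists must align")
    pfeat = pixel_features(image)
    h, w = pfeat.shape[:2]
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    inv_two_sigma_sq = 1.0 / (2.0 * sigma_f**2)
    for ev, spmap, feats in zip(per_scale_errors, per_scale_maps, per_scale_features):
        if spmap.shape != (h, w):
            raise ShapeMismatchError("superpixel map does not match image shape")
        sp_feat = feats.F[spmap.labels]  # (H, W, 8)
        d2 = np.einsum("ijk,ijk->ij", pfeat - sp_feat, pfeat - sp_feat)
        weight = np.exp(-d2 * inv_two_sigma_sq)
        num += weight * ev.values[spmap.labels]
        den += weight
    return num / np.maximum(den, 1e-12)


def error_weighted_centroid(error_map: np.ndarray) -> tuple[float, float]:
    """(x, y) centroid of a non-negative map, weighted by its values.

    Constant (including all-zero) maps fall back to the image center.
    """
    m = np.asarray(error_map, dtype=float)
    h, w = m.shape
    total = m.sum()
    if total <= 0 or np.ptp(m) == 0:
        return (w - 1) / 2.0, (h - 1) / 2.0
    ys, xs = np.mgrid[0:h, 0:w]
    return float((m * xs).sum() / total), float((m * ys).sum() / total)


def object_biased_reweight(
    error_map: np.ndarray,
    sigma_x: float | None = None,
    sigma_y: float | None = None,
) -> np.ndarray:
    """Multiply by a 2-D Gaussian centered at the error-weighted centroid.

    Defaults: ``sigma_x = W / 4``, ``sigma_y = H / 4``.  A constant map
    has no usable centroid, so the image center is used; an all-zero map
    stays all-zero.  The result is min-max re-normalized.
    """
    m = np.asarray(error_map, dtype=float)
    h, w = m.shape
    sigma_x = w / 4.0 if sigma_x is None else sigma_x
    sigma_y = h / 4.0 if sigma_y is None else sigma_y
    xc, yc = error_weighted_centroid(m)
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    gauss = np.exp(
        -((xs - xc) ** 2 / (2.0 * sigma_x**2) + (ys - yc) ** 2 / (2.0 * sigma_y**2))
    )
    out = m * gauss
    span = np.ptp(out)
    if span <= 0:
        return np.zeros_like(out)
    return (out - out.min()) / span


#: Mixing weight of the uniform distribution into histogram likelihoods.
#: Keeps every bin strictly positive while leaving a constant (single-bin)
#: likelihood identical across regions, so an uninformative likelihood
#: reproduces the prior exactly.
_SMOOTHING = 1e-3


def _likelihood_lookup(
    q: np.ndarray, region: np.ndarray, bins: int
) -> np.ndarray:
    """Smoothed histogram likelihood of q-values inside a region."""
    hist, _ = np.histogram(q[region], bins=bins, range=(0.0, 1.0))
    probs = (1.0 - _SMOOTHING) * hist / hist.sum() + _SMOOTHING / bins
    idx = np.clip((q * bins).astype(int), 0, bins - 1)
    return probs[idx]


def _posterior_with_prior(P: np.ndarray, Q: np.ndarray, bins: int) -> np.ndarray:
    fg = P >= P.mean()
    bg = ~fg
    if not fg.any() or not bg.any():
        logger.info("degenerate prior split; posterior falls back to the prior")
        return P.copy()
    lf = _likelihood_lookup(Q, fg, bins)
    lb = _likelihood_lookup(Q, bg, bins)
    num = P * lf
    den = num + (1.0 - P) * lb
    return num / np.maximum(den, 1e-12)


def bayesian_integrate(
    s_dense: np.ndarray,
    s_sparse: np.ndarray,
    bins: int = 64,
) -> np.ndarray:
    """Fuse two saliency maps by symmetric Bayesian posteriors.

    Each map is split at its mean into foreground/background regions; the
    other map's values are histogrammed within each region to form
    likelihoods, and the posterior treats the first map as the pixel-wise
    prior.  The two posteriors are averaged and min-max normalized.
    """
    P = np.asarray(s_dense, dtype=float)
    Q = np.asarray(s_sparse, dtype=float)
    if P.shape != Q.shape:
        raise ShapeMismatchError("saliency maps must share a shape")
    fused = 0.5 * (
        _posterior_with_prior(P, Q, bins) + _posterior_with_prior(Q, P, bins)
    )
    span = np.ptp(fused)
    if span <= 0:
        return np.zeros_like(fused)
    return (fused - fused.min()) / span
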