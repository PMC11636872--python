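"""Saliency evaluation metrics.

Implements the standard suite for comparing a saliency map or binary mask
``S`` against a binary ground truth ``G``: MAE, threshold-swept
precision/recall with F1 and F-beta, ROC/AUC, structure measure
(S-measure), enhanced-alignment measure (E-measure), IoU, and dataset
aggregation (per-threshold PR averaging plus threshold-exceedance
fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from bgsal.errors import ShapeMismatchError

__all__ = [
    "MetricConfig",
    "PRCurve",
    "mae",
    "pr_curve",
    "f_scores",
    "roc_auc",
    "s_measure",
    "e_measure",
    "iou",
    "evaluate_pair",
    "aggregate_dataset",
]


@dataclass(frozen=True)
class MetricConfig:
    beta_sq: float = 0.3
    s_alpha: float = 0.5
    eps: float = 1e-8
    thresholds: np.ndarray = field(
        default_factory=lambda: np.arange(256), repr=False
    )


class PRCurve(NamedTuple):
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray


def _checked_pair(S: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    S = np.asarray(S, dtype=float)
    G = np.asarray(G)
    if S.shape != G.shape:
        raise ShapeMismatchError(f"S shape {S.shape} != G shape {G.shape}")
    gv = np.unique(G)
    if not np.isin(gv, (0, 1)).all():
        raise ValueError("ground truth must be binary 0/1")
    if S.min() < -1e-9 or S.max() > 1.0 + 1e-9:
        raise ValueError("saliency values must lie in [0, 1]")
    return np.clip(S, 0.0, 1.0), G.astype(bool)


def mae(S: np.ndarray, G: np.ndarray) -> float:
    """Mean absolute per-pixel difference."""
    S, G = _checked_pair(S, G)
    return float(np.abs(S - G.astype(float)).mean())


def pr_curve(
    S: np.ndarray, G: np.ndarray, config: MetricConfig | None = None
) -> PRCurve:
    """Precision/recall at every integer threshold of ``S * 255``.

    For each T the prediction is ``S * 255 >= T``; precision and recall
    are epsilon-guarded so an empty prediction or ground truth does not
    divide by zero.
    """
    config = config or MetricConfig()
    S, G = _checked_pair(S, G)
    s255 = (S * 255.0).ravel()
    g = G.ravel()
    pos = np.sort(s255[g])
    all_sorted = np.sort(s255)
    n_pos = pos.size
    n_all = all_sorted.size
    ts = np.asarray(config.thresholds, dtype=float)
    tp = n_pos - np.searchsorted(pos, ts, side="left")
    pred = n_all - np.searchsorted(all_sorted, ts, side="left")
    fp = pred - tp
    fn = n_pos - tp
    precision = tp / (tp + fp + config.eps)
    recall = tp / (tp + fn + config.eps)
    return PRCurve(thresholds=ts, precision=precision, recall=recall)


def f_scores(
    precision: np.ndarray | float,
    recall: np.ndarray | float,
    config: MetricConfig | None = None,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """F1 (harmonic mean) and F-beta (precision-weighted, beta^2 = 0.3)."""
    config = config or MetricConfig()
    p = np.asarray(precision, dtype=float)
    r = np.asarray(recall, dtype=float)
    f1 = 2.0 * p * r / (p + r + config.eps)
    fb = (1.0 + config.beta_sq) * p * r / (config.beta_sq * p + r + config.eps)
    if np.isscalar(precision) or p.ndim == 0:
        return float(f1), float(fb)
    return f1, fb


def roc_auc(
    S: np.ndarray, G: np.ndarray, config: MetricConfig | None = None
) -> float:
    """Trapezoidal area under the ROC curve swept over thresholds 0..255."""
    config = config or MetricConfig()
    S, G = _checked_pair(S, G)
    n_pos = int(G.sum())
    n_neg = G.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: ground truth has a single class")
    s255 = (S * 255.0).ravel()
    g = G.ravel()
    pos = np.sort(s255[g])
    neg = np.sort(s255[~g])
    ts = np.asarray(config.thresholds, dtype=float)
    tpr = (n_pos - np.searchsorted(pos, ts, side="left")) / n_pos
    fpr = (n_neg - np.searchsorted(neg, ts, side="left")) / n_neg
    fpr = np.concatenate([[0.0], fpr[::-1], [1.0]])
    tpr = np.concatenate([[0.0], tpr[::-1], [1.0]])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


# ---------------------------------------------------------------------------
# Structure measure


def _object_score(x: np.ndarray) -> float:
    """Object-aware similarity of map values within one region."""
    if x.size == 0:
        return 0.0
    mean = x.mean()
    std = x.std()
    return 2.0 * mean / (mean * mean + 1.0 + std + 1e-12)


def _s_object(S: np.ndarray, G: np.ndarray) -> float:
    u = G.mean()
    o_fg = _object_score(S[G])
    o_bg = _object_score(1.0 - S[~G])
    return u * o_fg + (1.0 - u) * o_bg


def _ssim_like(pred: np.ndarray, gt: np.ndarray) -> float:
    n = pred.size
    if n <= 1:
        return 1.0 if np.allclose(pred, gt) else 0.0
    x, y = pred.mean(), gt.mean()
    sx = ((pred - x) ** 2).sum() / (n - 1)
    sy = ((gt - y) ** 2).sum() / (n - 1)
    sxy = ((pred - x) * (gt - y)).sum() / (n - 1)
    alpha = 4.0 * x * y * sxy
    beta = (x * x + y * y) * (sx + sy)
    if alpha != 0:
        return alpha / (beta + 1e-12)
    if beta == 0:
        return 1.0
    return 0.0


def _s_region(S: np.ndarray, G: np.ndarray) -> float:
    h, w = G.shape
    total = G.sum()
    ys, xs = np.nonzero(G)
    # rounded foreground centroid splits both maps into 4 blocks
    cy = int(np.round(ys.mean())) + 1
    cx = int(np.round(xs.mean())) + 1
    cy = min(max(cy, 1), h - 1) if h > 1 else 1
    cx = min(max(cx, 1), w - 1) if w > 1 else 1
    score = 0.0
    for rs, cs in ((slice(0, cy), slice(0, cx)), (slice(0, cy), slice(cx, w)),
                   (slice(cy, h), slice(0, cx)), (slice(cy, h), slice(cx, w))):
        g_blk = G[rs, cs]
        weight = g_blk.sum() / max(total, 1)
        score += weight * _ssim_like(S[rs, cs].astype(float), g_blk.astype(float))
    return score


def s_measure(
    S: np.ndarray, G: np.ndarray, config: MetricConfig | None = None
) -> float:
    """Structure measure: alpha * object similarity + (1-alpha) * region similarity.

    Degenerate ground truths follow the reference convention: an all-zero
    G scores ``1 - mean(S)``, an all-one G scores ``mean(S)``.
    """
    config = config or MetricConfig()
    S, G = _checked_pair(S, G)
    y = G.mean()
    if y == 0:
        return float(1.0 - S.mean())
    if y == 1:
        return float(S.mean())
    value = config.s_alpha * _s_object(S, G.astype(bool)) + (
        1.0 - config.s_alpha
    ) * _s_region(S, G.astype(bool))
    return float(max(value, 0.0))


# ---------------------------------------------------------------------------
# Enhanced-alignment measure


def e_measure(S: np.ndarray, G: np.ndarray) -> float:
    """Enhanced-alignment measure on ``S`` binarized at twice its mean.

    The alignment between the mean-centered binary prediction and ground
    truth is enhanced quadratically and averaged over pixels; degenerate
    ground truths reduce to agreement with the (inverted) prediction.
    """
    S, G = _checked_pair(S, G)
    mean_s = S.mean()
    if mean_s == 0:
        sb = np.zeros_like(S, dtype=float)
    else:
        t = min(2.0 * mean_s, 1.0)
        sb = (S >= t).astype(float)
    g = G.astype(float)
    if G.all():
        enhanced = sb
    elif not G.any():
        enhanced = 1.0 - sb
    else:
        ds = sb - sb.mean()
        dg = g - g.mean()
        align = 2.0 * dg * ds / (dg * dg + ds * ds + 1e-12)
        enhanced = (align + 1.0) ** 2 / 4.0
    return float(enhanced.mean())


def iou(mask: np.ndarray, G: np.ndarray, eps: float = 1e-8) -> float:
    """Intersection over union of two binary masks."""
    m = np.asarray(mask).astype(bool)
    g = np.asarray(G).astype(bool)
    if m.shape != g.shape:
        raise ShapeMismatchError(f"shape mismatch: {m.shape} vs {g.shape}")
    inter = np.logical_and(m, g).sum()
    union = np.logical_or(m, g).sum()
    return float(inter / (union + eps))


# ---------------------------------------------------------------------------
# Dataset-level aggregation


def evaluate_pair(
    S: np.ndarray,
    G: np.ndarray,
    mask: np.ndarray | None = None,
    config: MetricConfig | None = None,
) -> dict:
    """All per-image metrics for one (saliency, ground-truth) pair.

    If ``mask`` is given its IoU against ``G`` is included; F-scores are
    reported at the curve point maximizing F1 / F-beta respectively.
    """
    config = config or MetricConfig()
    curve = pr_curve(S, G, config)
    f1_curve, fb_curve = f_scores(curve.precision, curve.recall, config)
    out = {
        "mae": mae(S, G),
        "pr": curve,
        "f1": float(np.max(f1_curve)),
        "f_beta": float(np.max(fb_curve)),
        "s_measure": s_measure(S, G, config),
        "e_measure": e_measure(S, G),
    }
    g = np.asarray(G).astype(bool)
    if g.any() and not g.all():
        out["auc"] = roc_auc(S, G, config)
    if mask is not None:
        out["iou"] = iou(mask, G)
    return out


def aggregate_dataset(
    results: list[dict],
    iou_cutoffs: tuple[float, ...] = (0.9,),
    mae_cutoffs: tuple[float, ...] = (0.1,),
) -> dict:
    """Average per-image metrics over a dataset.

    PR curves are averaged per threshold; scalar metrics are arithmetic
    means over the images that defined them.  Also reports the fraction
    of images with IoU above / MAE below each cutoff.
    """
    if not results:
        raise ValueError("need at least one per-image result")
    report: dict = {"n_images": len(results)}
    for key in ("mae", "f1", "f_beta", "s_measure", "e_measure", "auc", "iou"):
        vals = [r[key] for r in results if key in r]
        if vals:
            report[key] = float(np.mean(vals))
    curves = [r["pr"] for r in results if "pr" in r]
    if curves:
        report["pr"] = PRCurve(
            thresholds=curves[0].thresholds,
            precision=np.mean([c.precision for c in curves], axis=0),
            recall=np.mean([c.recall for c in curves], axis=0),
        )
    ious = np.array([r["iou"] for r in results if "iou" in r])
    maes = np.array([r["mae"] for r in results if "mae" in r])
    for c in iou_cutoffs:
        if ious.size:
            report[f"frac_iou_gt_{c}"] = float((ious > c).mean())
    for c in mae_cutoffs:
        if maes.size:
            report[f"frac_mae_lt_{c}"] = float((maes < c).mean())
    return report
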