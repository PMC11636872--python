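"""Saliency-map thresholding, mask clean-up and the pluggable refiner hook."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from bgsal.errors import RefinerContractError

__all__ = ["BinaryMask", "threshold_mask", "clean_mask", "apply_refiner"]

logger = logging.getLogger(__name__)

#: Connected components smaller than this fraction of the largest one are
#: dropped by :func:`clean_mask` (strict comparison).
MIN_COMPONENT_FRACTION = 0.10


@dataclass(frozen=True)
class BinaryMask:
    """A 0/1 per-pixel segmentation with provenance."""

    values: np.ndarray
    source: str = "initial"  # "initial" | "refined"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def threshold_mask(
    saliency: np.ndarray,
    method: str = "otsu",
    fixed_t: float = 0.5,
) -> BinaryMask:
    """Binarize a [0, 1] saliency map.

    ``method="otsu"`` picks the threshold from a 256-bin histogram;
    ``method="fixed"`` uses ``fixed_t``.  The mask is ``saliency >= t``.
    A constant map cannot be split and yields an all-zero mask.
    """
    s = np.asarray(saliency, dtype=float)
    if s.min() < -1e-9 or s.max() > 1.0 + 1e-9:
        raise ValueError("saliency map must lie in [0, 1]")
    if method == "fixed":
        t = fixed_t
    elif method == "otsu":
        if np.ptp(s) == 0:
            logger.info("constant saliency map; returning empty mask")
            return BinaryMask(values=np.zeros(s.shape, dtype=np.uint8))
        t = threshold_otsu(s, nbins=256)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return BinaryMask(values=(s >= t).astype(np.uint8))


def clean_mask(mask: BinaryMask) -> BinaryMask:
    """Drop tiny components and fill interior holes.

    8-connected components with area strictly below 10% of the largest
    component's area are removed; background regions not connected to the
    image border are then filled.  Idempotent.
    """
    def prune(v: np.ndarray) -> np.ndarray:
        labelled = cc_label(v, connectivity=2)
        areas = np.bincount(labelled.ravel())[1:]
        keep = areas >= MIN_COMPONENT_FRACTION * areas.max()
        return np.isin(labelled, np.nonzero(keep)[0] + 1)

    v = mask.values.astype(bool)
    if not v.any():
        return mask
    filled = ndimage.binary_fill_holes(prune(v))
    # hole filling changes component areas, so prune once more against the
    # final sizes — this is what makes the operation idempotent
    return BinaryMask(values=prune(filled).astype(np.uint8), source=mask.source)


Refiner = Callable[[np.ndarray, np.ndarray], np.ndarray]


def identity_refiner(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return mask


def apply_refiner(
    image: np.ndarray,
    mask: BinaryMask,
    refiner: Refiner | None = None,
) -> BinaryMask:
    """Run an external segmentation refiner over the initial mask.

    The refiner is any callable taking ``(image, mask_values)`` and
    returning a same-shape 0/1 array; the default is the identity.  The
    contract is validated so plug-in bugs surface immediately.
    """
    refiner = refiner or identity_refiner
    out = np.asarray(refiner(image, mask.values))
    if out.shape != mask.values.shape:
        raise RefinerContractError(
            f"refiner returned shape {out.shape}, expected {mask.values.shape}"
        )
    if not np.isin(out, (0, 1)).all():
        raise RefinerContractError("refiner returned non-binary values")
    return BinaryMask(values=out.astype(np.uint8), source="refined")
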