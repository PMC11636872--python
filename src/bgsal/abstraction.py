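"""Superpixel segmentation and per-superpixel feature extraction.

An image is decomposed into SLIC superpixels at one or more scales.  Each
superpixel is described by an 8-dimensional feature vector
``f = [R, G, B, L, a, b, x, y]``: mean RGB (scaled to [0, 1]), mean CIE-Lab
(native units, D65), and the centroid of its pixels normalized to [0, 1].
Superpixels owning at least one pixel on the image border form the initial
background dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab
from skimage.segmentation import slic

from bgsal.errors import ShapeMismatchError, SizingError

__all__ = [
    "SuperpixelMap",
    "FeatureMatrix",
    "BoundarySet",
    "segment_superpixels",
    "extract_features",
    "boundary_indices",
    "pixel_features",
]


@dataclass(frozen=True)
class SuperpixelMap:
    """A partition of an image into ``k`` connected superpixels.

    Attributes
    ----------
    labels
        Integer matrix of shape (H, W) with values in ``0..k-1``.  Every
        label occurs at least once.
    k
        Number of superpixels.
    scale_id
        Index of the segmentation scale this map belongs to.
    """

    labels: np.ndarray
    k: int
    scale_id: int = 0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ShapeMismatchError("labels must be a 2-D integer matrix")
        present = np.unique(labels)
        if present[0] != 0 or present[-1] != self.k - 1 or len(present) != self.k:
            raise ValueError("labels must cover exactly 0..k-1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-superpixel descriptors ``[R, G, B, L, a, b, x, y]`` and their mean."""

    F: np.ndarray
    f_bar: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "F", F)
        if self.f_bar is None:
            object.__setattr__(self, "f_bar", F.mean(axis=0))

    @property
    def k(self) -> int:
        return self.F.shape[0]

    @property
    def lab(self) -> np.ndarray:
        """The CIE-Lab columns (used for appearance distances)."""
        return self.F[:, 3:6]


@dataclass(frozen=True)
class BoundarySet:
    """Superpixel labels touching the image border (the initial dictionary B)."""

    indices: frozenset[int]

    @property
    def k_prime(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.fromiter(sorted(self.indices), dtype=int)


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    """Promote grayscale to 3 channels and scale uint8 to [0, 1] floats."""
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ShapeMismatchError(f"expected an RGB image, got shape {image.shape}")
    image = image[..., :3]
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0
    image = image.astype(float)
    if image.max() > 1.0 + 1e-9:
        image = image / 255.0
    return np.clip(image, 0.0, 1.0)


def segment_superpixels(
    image: np.ndarray,
    n_segments: int,
    compactness: float = 10.0,
    seed: int = 0,
    scale_id: int = 0,
) -> SuperpixelMap:
    """Segment ``image`` into roughly ``n_segments`` SLIC superpixels.

    The segmentation is grid-seeded and therefore deterministic; ``seed``
    is accepted for interface uniformity.  Connectivity is enforced, and
    labels are relabelled to the dense range ``0..k-1``.

    Raises
    ------
    SizingError
        If ``n_segments < 4`` or the image is smaller than 4 pixels a side.
    """
    rgb = _as_float_rgb(image)
    h, w = rgb.shape[:2]
    if h < 4 or w < 4:
        raise SizingError(f"image {h}x{w} too small; need at least 4x4")
    if n_segments < 4:
        raise SizingError(f"n_segments={n_segments} too small; need >= 4")
    if h * w < n_segments:
        raise SizingError("image has fewer pixels than requested segments")
    del seed  # SLIC initialization is a deterministic grid
    labels = slic(
        rgb,
        n_segments=n_segments,
        compactness=compactness,
        start_label=0,
        enforce_connectivity=True,
        channel_axis=-1,
    )
    # densify labels (SLIC may merge cells)
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(h, w)
    k = int(labels.max()) + 1
    return SuperpixelMap(labels=labels, k=k, scale_id=scale_id)


def pixel_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel ``[R, G, B, L, a, b, x, y]`` features, shape (H, W, 8).

    Uses the same conventions as :func:`extract_features`: RGB in [0, 1],
    Lab in native units, pixel-center coordinates normalized by
    ``(W-1, H-1)``.
    """
    rgb = _as_float_rgb(image)
    h, w = rgb.shape[:2]
    lab = rgb2lab(rgb)
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    xn = xs / max(w - 1, 1)
    yn = ys / max(h - 1, 1)
    return np.concatenate([rgb, lab, xn[..., None], yn[..., None]], axis=-1)


def extract_features(image: np.ndarray, spmap: SuperpixelMap) -> FeatureMatrix:
    """Mean color and centroid per superpixel.

    Row ``i`` of the result is the mean of the per-pixel features over
    superpixel ``i``; ``f_bar`` is the unweighted mean over rows.
    """
    rgb = _as_float_rgb(image)
    if rgb.shape[:2] != spmap.shape:
        raise ShapeMismatchError(
            f"image shape {rgb.shape[:2]} != label shape {spmap.shape}"
        )
    feats = pixel_features(rgb).reshape(-1, 8)
    labels = spmap.labels.ravel()
    counts = np.bincount(labels, minlength=spmap.k).astype(float)
    F = np.empty((spmap.k, 8))
    for c in range(8):
        F[:, c] = np.bincount(labels, weights=feats[:, c], minlength=spmap.k) / counts
    return FeatureMatrix(F=F)


def boundary_indices(spmap: SuperpixelMap) -> BoundarySet:
    """Labels owning at least one pixel on the image border."""
    lab = spmap.labels
    border = np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    return BoundarySet(indices=frozenset(int(v) for v in np.unique(border)))
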