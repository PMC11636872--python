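"""Reading and writing images, masks and debug tables."""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from bgsal.bgdict import ConductivityField, RefinedDictionary
from bgsal.mask import BinaryMask

__all__ = [
    "read_image",
    "write_gray",
    "read_mask",
    "write_mask",
    "write_labels",
    "write_conductivity_csv",
    "write_errors_csv",
]


def read_image(path) -> np.ndarray:
    """Load an 8-bit PNG/JPEG as float RGB in [0, 1]; grayscale is promoted."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    arr = arr[..., :3]
    return arr.astype(float) / 255.0


def write_gray(path, values: np.ndarray) -> None:
    """Save a [0, 1] map as 8-bit grayscale PNG."""
    v = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (v * 255).round().astype(np.uint8))


def read_mask(path) -> BinaryMask:
    """Load a 0/255 PNG as a binary mask (any nonzero pixel is foreground)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(values=(arr > 127).astype(np.uint8))


def write_mask(path, mask: BinaryMask) -> None:
    iio.imwrite(path, (mask.values * 255).astype(np.uint8))


def write_labels(path, labels: np.ndarray) -> None:
    """Save a superpixel label map as 16-bit PNG for debugging."""
    iio.imwrite(path, np.asarray(labels).astype(np.uint16))


def write_conductivity_csv(
    path, field: ConductivityField, refined: RefinedDictionary
) -> None:
    kept = set(refined.kept)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["superpixel", "bc", "bc_norm", "on_boundary", "kept"])
        boundary = refined.initial.indices
        for i in range(field.bc.shape[0]):
            writer.writerow(
                [i, f"{field.bc[i]:.6f}", f"{field.bc_norm[i]:.6f}",
                 int(i in boundary), int(i in kept)]
            )


def write_errors_csv(path, dense: np.ndarray, sparse: np.ndarray) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["superpixel", "dense_error", "sparse_error"])
        for i, (d, s) in enumerate(zip(dense, sparse)):
            writer.writerow([i, f"{d:.6f}", f"{s:.6f}"])


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
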