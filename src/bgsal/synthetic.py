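"""Seeded synthetic scenes with exact ground truth.

Generates the regimes a salient-object detector must handle — a single
centered object, multiple objects, low object/background contrast,
cluttered backgrounds, and objects touching the image border — without
any external dataset.  All randomness flows through one integer seed, so
identical specs reproduce bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import lab2rgb, rgb2lab

from bgsal.mask import BinaryMask

__all__ = ["ObjectSpec", "SceneSpec", "make_scene", "make_suite"]

_BACKGROUNDS = ("uniform", "gradient", "textured-clutter")
_SHAPES = ("ellipse", "rectangle", "blob")


@dataclass(frozen=True)
class ObjectSpec:
    """One painted object: shape, center (row, col), half-size (ry, rx)."""

    shape: str = "ellipse"
    center: tuple[float, float] = (0.5, 0.5)  # fractional (row, col)
    size: tuple[float, float] = (0.2, 0.2)  # fractional half-extents
    color: tuple[float, float, float] | None = None  # RGB in [0,1]; None = auto
    touches_border: bool = False

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class SceneSpec:
    size: tuple[int, int] = (128, 128)  # (H, W)
    background: str = "uniform"
    objects: tuple[ObjectSpec, ...] = (ObjectSpec(),)
    contrast: float = 60.0  # target CIE-Lab distance object vs background
    noise_sd: float = 0.01  # Gaussian pixel noise in [0,1] RGB units
    seed: int = 0
    background_color: tuple[float, float, float] = (0.45, 0.5, 0.55)

    def __post_init__(self) -> None:
        if self.background not in _BACKGROUNDS:
            raise ValueError(f"unknown background {self.background!r}")
        if not self.objects:
            raise ValueError("need at least one object")


def _object_support(obj: ObjectSpec, h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    cy, cx = obj.center[0] * (h - 1), obj.center[1] * (w - 1)
    ry, rx = max(obj.size[0] * h, 3.0), max(obj.size[1] * w, 3.0)
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    if obj.shape == "rectangle":
        support = (np.abs(ys - cy) <= ry) & (np.abs(xs - cx) <= rx)
    elif obj.shape == "ellipse":
        support = ((ys - cy) / ry) ** 2 + ((xs - cx) / rx) ** 2 <= 1.0
    else:  # blob: ellipse warped by low-frequency sinusoids
        theta = np.arctan2(ys - cy, xs - cx)
        a, b, p1, p2 = rng.uniform(0.05, 0.25, 2).tolist() + rng.uniform(
            0, 2 * np.pi, 2
        ).tolist()
        wobble = 1.0 + a * np.sin(3 * theta + p1) + b * np.cos(5 * theta + p2)
        support = ((ys - cy) / ry) ** 2 + ((xs - cx) / rx) ** 2 <= wobble
    return support


def _contrasting_color(
    background_rgb: tuple[float, float, float],
    contrast: float,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """A color at approximately ``contrast`` Lab distance from the background."""
    lab = rgb2lab(np.asarray(background_rgb).reshape(1, 1, 3))[0, 0]
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    target = lab + contrast * direction
    target[0] = np.clip(target[0], 5.0, 95.0)
    rgb = lab2rgb(target.reshape(1, 1, 3))[0, 0]
    return tuple(float(v) for v in np.clip(rgb, 0.0, 1.0))


def _paint_background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    base = np.asarray(spec.background_color, dtype=float)
    img = np.broadcast_to(base, (h, w, 3)).copy()
    if spec.background == "gradient":
        ramp = np.linspace(-0.12, 0.12, w)[None, :, None]
        img = np.clip(img + ramp, 0.0, 1.0)
    elif spec.background == "textured-clutter":
        # multi-octave value noise: smooth color blotches at 3 scales
        noise = np.zeros((h, w, 3))
        for cell, amp in ((16, 0.12), (8, 0.06), (4, 0.03)):
            coarse = rng.normal(0.0, 1.0, (h // cell + 2, w // cell + 2, 3))
            ys = np.linspace(0, coarse.shape[0] - 2, h)
            xs = np.linspace(0, coarse.shape[1] - 2, w)
            y0, x0 = ys.astype(int), xs.astype(int)
            fy, fx = (ys - y0)[:, None, None], (xs - x0)[None, :, None]
            blk = (
                coarse[y0][:, x0] * (1 - fy) * (1 - fx)
                + coarse[y0][:, x0 + 1] * (1 - fy) * fx
                + coarse[y0 + 1][:, x0] * fy * (1 - fx)
                + coarse[y0 + 1][:, x0 + 1] * fy * fx
            )
            noise += amp * blk
        img = np.clip(img + noise, 0.0, 1.0)
    return img


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, BinaryMask]:
    """Render a scene and its exact ground-truth mask.

    Returns a float RGB image in [0, 1] and the union of object supports.
    Rejects scenes whose objects cover more than 80% of the image (a
    background prior would be meaningless there).
    """
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    img = _paint_background(spec, rng)
    gt = np.zeros((h, w), dtype=bool)
    for obj in spec.objects:
        support = _object_support(obj, h, w, rng)
        if support.sum() < 25:
            raise ValueError("degenerate object: area below 25 px")
        color = obj.color or _contrasting_color(
            spec.background_color, spec.contrast, rng
        )
        img[support] = color
        gt |= support
    if gt.mean() > 0.8:
        raise ValueError("objects cover more than 80% of the image")
    if spec.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, 1.0)
    return img, BinaryMask(values=gt.astype(np.uint8))


def make_suite(seed: int = 0, size: tuple[int, int] = (128, 128)) -> list[tuple[str, np.ndarray, BinaryMask]]:
    """The fixed 20-scene battery: 5 scenes per regime at 128 x 128.

    Regimes: ``centered`` (one central high-contrast object), ``multi``
    (2-3 objects), ``lowcontrast`` (Lab distance ~25), and
    ``nearboundary`` (a high-contrast object overlapping the border).
    """
    rng = np.random.default_rng(seed)
    scenes: list[tuple[str, np.ndarray, BinaryMask]] = []

    def sub_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    for i in range(5):
        spec = SceneSpec(
            size=size,
            background="uniform" if i < 3 else "textured-clutter",
            objects=(
                ObjectSpec(
                    shape=_SHAPES[i % 3],
                    center=(0.5 + 0.05 * (i - 2) / 2, 0.5 - 0.05 * (i - 2) / 2),
                    size=(0.18 + 0.02 * i, 0.22 - 0.01 * i),
                ),
            ),
            contrast=65.0,
            seed=sub_seed(),
        )
        scenes.append((f"centered_{i}", *make_scene(spec)))

    for i in range(5):
        n_obj = 2 + i % 2
        centers = [(0.3, 0.3), (0.68, 0.62), (0.35, 0.72)][:n_obj]
        objs = tuple(
            ObjectSpec(
                shape=_SHAPES[(i + j) % 3],
                center=c,
                size=(0.12, 0.13),
            )
            for j, c in enumerate(centers)
        )
        spec = SceneSpec(
            size=size,
            background="uniform" if i % 2 == 0 else "gradient",
            objects=objs,
            contrast=60.0,
            seed=sub_seed(),
        )
        scenes.append((f"multi_{i}", *make_scene(spec)))

    for i in range(5):
        spec = SceneSpec(
            size=size,
            background="uniform",
            objects=(
                ObjectSpec(
                    shape=_SHAPES[i % 3],
                    center=(0.5, 0.5),
                    size=(0.2, 0.2),
                ),
            ),
            contrast=25.0,
            noise_sd=0.005,
            seed=sub_seed(),
        )
        scenes.append((f"lowcontrast_{i}", *make_scene(spec)))

    for i in range(5):
        # (row, col) centers hugging the left/top/right/bottom borders
        center = [(0.5, 0.02), (0.02, 0.5), (0.5, 0.98), (0.98, 0.5), (0.6, 0.02)][i]
        spec = SceneSpec(
            size=size,
            background="uniform" if i < 3 else "gradient",
            objects=(
                ObjectSpec(
                    shape="rectangle" if i % 2 else "ellipse",
                    center=center,
                    size=(0.2, 0.2),
                    touches_border=True,
                ),
            ),
            contrast=65.0,
            seed=sub_seed(),
        )
        name = f"nearboundary_{i}"
        img, gt = make_scene(spec)
        border = np.concatenate(
            [gt.values[0], gt.values[-1], gt.values[:, 0], gt.values[:, -1]]
        )
        assert border.any(), f"{name}: ground truth must touch the border"
        scenes.append((name, img, gt))

    return scenes
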