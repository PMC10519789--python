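"""Seeded generator of a six-class synthetic leaf-disease image set.

Real corn-disease imagery in field conditions is restricted, so the test
bed is a parametric renderer: a green elliptical "leaf" over a cluttered
soil-toned background, with one lesion phenotype per class:

* ``fall_armyworm`` — ragged chewed edges and holes;
* ``gray_leaf_spot`` — circular grey spots;
* ``leaf_blight`` — elongated tan streaks along the leaf axis;
* ``leaf_healthy`` — no lesions;
* ``northern_leaf_spot`` — few large dark blotches;
* ``rust_leaf`` — dense small orange pustules.

The renderers make no claim of photo-realism; their contract is that the
classes are statistically separable from colour/edge features and that a
``background_clutter`` dial makes the task monotonically harder (clutter
shapes increasingly cross the leaf).  Generation is exactly reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

CLASSES = ("fall_armyworm", "gray_leaf_spot", "leaf_blight",
           "leaf_healthy", "northern_leaf_spot", "rust_leaf")


@dataclass(frozen=True)
class SynthSpec:
    """Configuration of one generated image set (uniform class priors)."""

    n_per_class: int = 24
    resolution: int = 64
    background_clutter: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be at least 2")
        if self.resolution < 32:
            raise ValueError("resolution must be at least 32")
        if not 0.0 <= self.background_clutter <= 1.0:
            raise ValueError("background_clutter must be in [0, 1]")


def _ellipse_mask(res: int, cy: float, cx: float, ry: float, rx: float,
                  angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:res, 0:res]
    y, x = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _disk_mask(res: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:res, 0:res]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _paint(img: np.ndarray, mask: np.ndarray, color, jitter: float,
           rng: np.random.Generator) -> None:
    col = np.asarray(color, dtype=np.float32)
    noise = rng.normal(0.0, jitter, (int(mask.sum()), 3)).astype(np.float32)
    img[mask] = col + noise


def _render(class_name: str, res: int, clutter: float,
            rng: np.random.Generator) -> np.ndarray:
    img = np.empty((res, res, 3), dtype=np.float32)
    # soil background
    base = np.array([120, 100, 75], np.float32) + rng.normal(0, 8, 3)
    img[:] = base
    img += rng.normal(0, 6, img.shape)

    n_clutter = int(round(clutter * 40))
    behind = []
    for _ in range(n_clutter):
        cy, cx = rng.uniform(0, res, 2)
        ry = rng.uniform(res * 0.02, res * 0.14)
        rx = rng.uniform(res * 0.02, res * 0.14)
        col = np.array([rng.uniform(60, 160), rng.uniform(60, 160),
                        rng.uniform(40, 120)], np.float32)
        mask = _ellipse_mask(res, cy, cx, ry, rx, rng.uniform(0, np.pi))
        # most clutter lies behind the leaf; with increasing clutter more of
        # it crosses the foreground, occluding the lesion signal
        if rng.random() < 0.9 * clutter:
            behind.append((mask, col))
        else:
            _paint(img, mask, col, 5, rng)

    # leaf: modest pose/size variation — the class signal must dominate
    cy, cx = res / 2 + rng.normal(0, res * 0.02, 2)
    ry = rng.uniform(res * 0.26, res * 0.30)
    rx = rng.uniform(res * 0.40, res * 0.44)
    angle = rng.uniform(-0.2, 0.2)
    leaf = _ellipse_mask(res, cy, cx, ry, rx, angle)
    bites: list[np.ndarray] = []
    if class_name == "fall_armyworm":        # chewed margin: bites of background
        for _ in range(rng.integers(6, 10)):
            t = rng.uniform(0, 2 * np.pi)
            by = cy + ry * np.sin(t) * np.cos(angle) + rng.normal(0, 1)
            bx = cx + rx * np.cos(t) * np.cos(angle) - ry * np.sin(t) * np.sin(angle)
            r = rng.uniform(res * 0.05, res * 0.1)
            bites.append((_disk_mask(res, by, bx, r),
                          _disk_mask(res, by, bx, r * 1.4)))
            leaf &= ~bites[-1][0]
        for _ in range(rng.integers(3, 6)):  # interior holes
            hy = cy + rng.normal(0, ry * 0.5)
            hx = cx + rng.normal(0, rx * 0.5)
            r = rng.uniform(res * 0.025, res * 0.055)
            bites.append((_disk_mask(res, hy, hx, r), _disk_mask(res, hy, hx, r * 1.5)))
            leaf &= ~bites[-1][0]
    green = np.array([55, 125, 45], np.float32) + rng.normal(0, 4, 3)
    _paint(img, leaf, green, 5, rng)
    for hole, rim in bites:                  # necrotic rim around each bite
        _paint(img, rim & leaf & ~hole, (105, 80, 45), 6, rng)

    def inside(y, x):
        return leaf[int(np.clip(y, 0, res - 1)), int(np.clip(x, 0, res - 1))]

    if class_name == "gray_leaf_spot":
        for _ in range(rng.integers(16, 26)):
            sy, sx = cy + rng.normal(0, ry * 0.7), cx + rng.normal(0, rx * 0.7)
            if inside(sy, sx):
                m = _disk_mask(res, sy, sx, rng.uniform(res * 0.035, res * 0.06)) & leaf
                _paint(img, m, (150, 148, 140), 4, rng)
    elif class_name == "leaf_blight":
        for _ in range(rng.integers(7, 12)):
            sy = cy + rng.normal(0, ry * 0.6)
            sx = cx + rng.normal(0, rx * 0.4)
            m = _ellipse_mask(res, sy, sx, rng.uniform(res * 0.025, res * 0.05),
                              rng.uniform(res * 0.16, res * 0.28), angle) & leaf
            _paint(img, m, (185, 155, 95), 5, rng)
    elif class_name == "northern_leaf_spot":
        for _ in range(rng.integers(5, 9)):
            sy, sx = cy + rng.normal(0, ry * 0.6), cx + rng.normal(0, rx * 0.6)
            m = _disk_mask(res, sy, sx, rng.uniform(res * 0.07, res * 0.12)) & leaf
            _paint(img, m, (70, 50, 35), 5, rng)
    elif class_name == "rust_leaf":
        ys = cy + rng.normal(0, ry * 0.7, 160)
        xs = cx + rng.normal(0, rx * 0.7, 160)
        for sy, sx in zip(ys, xs):
            if inside(sy, sx):
                m = _disk_mask(res, sy, sx, rng.uniform(1.0, 1.0 + res * 0.02)) & leaf
                img[m] = np.array([205, 115, 30], np.float32) + rng.normal(0, 6, 3)
    # midvein (all classes), drawn over lesions
    vein = _ellipse_mask(res, cy, cx, res * 0.012, rx * 0.95, angle) & leaf
    img[vein] = green * 0.75

    for mask, col in behind:                 # foreground clutter occlusion
        _paint(img, mask, col, 5, rng)

    img += rng.normal(0, 2, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _image_rng(seed: int, class_idx: int, image_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(class_idx, image_idx)))


def generate_arrays(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Render the whole set in memory.

    Returns (images, labels, class names): images are (N, H, W, 3) uint8 in
    class-major order, labels index into the class-name tuple.  The same
    spec always produces byte-identical arrays.
    """
    imgs, labels = [], []
    for ci, cls in enumerate(CLASSES):
        for ii in range(spec.n_per_class):
            rng = _image_rng(spec.seed, ci, ii)
            imgs.append(_render(cls, spec.resolution,
                                spec.background_clutter, rng))
            labels.append(ci)
    return np.stack(imgs), np.asarray(labels, dtype=np.int64), CLASSES


def generate(spec: SynthSpec, out_dir) -> Path:
    """Write the set to ``out_dir`` as an image folder plus ``manifest.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, labels, classes = generate_arrays(spec)
    rows = []
    k = 0
    for ci, cls in enumerate(classes):
        cls_dir = out / cls
        cls_dir.mkdir(exist_ok=True)
        for ii in range(spec.n_per_class):
            path = cls_dir / f"{cls}_{ii:04d}.png"
            Image.fromarray(images[k]).save(path)
            rows.append((str(path), cls))
            k += 1
    with open(out / "manifest.csv", "w") as fh:
        fh.write("path,class\n")
        fh.writelines(f"{p},{c}\n" for p, c in rows)
    return out


def color_edge_features(images: np.ndarray) -> np.ndarray:
    """Per-image colour/edge summary for linear-probe checks.

    Eight-bin histograms per channel (lesion palettes occupy distinct bins),
    per-channel means and standard deviations, and the mean
    horizontal/vertical gradient magnitudes."""
    x = np.asarray(images, dtype=np.float32) / 255.0
    n = len(x)
    hists = np.empty((n, 24), dtype=np.float32)
    for i in range(n):
        for c in range(3):
            h, _ = np.histogram(x[i, ..., c], bins=8, range=(0.0, 1.0))
            hists[i, 8 * c:8 * (c + 1)] = h / h.sum()
    means = x.mean(axis=(1, 2))
    stds = x.std(axis=(1, 2))
    gy = np.abs(np.diff(x, axis=1)).mean(axis=(1, 2, 3))[:, None]
    gx = np.abs(np.diff(x, axis=2)).mean(axis=(1, 2, 3))[:, None]
    return np.concatenate([hists, means, stds, gy, gx], axis=1)
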