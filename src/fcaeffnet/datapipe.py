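"""Dataset splitting, online augmentation and photometric robustness transforms.

Images live in the conventional image-folder layout (``root/<class>/*.jpg``
or ``.png``).  Splitting is per class at an 8:1:1 ratio with half-up
rounding of the validation/test shares; the training share takes the
remainder, so the three subsets always partition the class.  Explicit
per-class counts are also accepted for corpora whose published split does
not follow a single rounding rule.

Three online augmentations are provided, each returning a new array and
leaving the input untouched:

* :func:`cutout` — zero a square region (possibly overhanging the border);
* :func:`grid_mask` — multiply by a periodic binary grid mask;
* :func:`random_erasing` — overwrite a random rectangle with random values.

The photometric robustness protocol perturbs a *test* set with brightness or
contrast scaling at factors {0.5, 0.67, 1.5, 2} — eight perturbed test sets
in total.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

IMAGE_EXTENSIONS = (".jpg", ".jpeg", ".png")
ROBUSTNESS_FACTORS = (0.5, 0.67, 1.5, 2.0)
DEFAULT_RATIOS = (0.8, 0.1, 0.1)


# -- splitting -----------------------------------------------------------------

@dataclass(frozen=True)
class SplitCounts:
    """Per-class image counts of a train/valid/test partition."""

    classes: tuple[str, ...]
    train: tuple[int, ...]
    valid: tuple[int, ...]
    test: tuple[int, ...]

    @property
    def totals(self) -> tuple[int, ...]:
        return tuple(a + b + c for a, b, c in zip(self.train, self.valid, self.test))

    def row(self, cls: str) -> tuple[int, int, int]:
        i = self.classes.index(cls)
        return self.train[i], self.valid[i], self.test[i]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_counts_for_total(n: int, ratios=DEFAULT_RATIOS) -> tuple[int, int, int]:
    """(train, valid, test) counts for one class of ``n`` images.

    valid and test get ``round(ratio * n)`` with half-up rounding; train
    takes the remainder, so the counts always sum to ``n``.
    """
    if n < 3:
        raise ValueError(f"need at least 3 images per class, got {n}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    valid = _round_half_up(ratios[1] * n)
    test = _round_half_up(ratios[2] * n)
    train = n - valid - test
    if train < 0:
        raise ValueError("ratios leave no training data")
    return train, valid, test


def split_dataset(items_by_class: dict[str, list],
                  ratios=DEFAULT_RATIOS,
                  seed: int = 0,
                  explicit_counts: dict[str, tuple[int, int, int]] | None = None,
                  ) -> tuple[SplitCounts, dict]:
    """Assign every item to train/valid/test, per class, deterministically.

    Parameters
    ----------
    items_by_class:
        Mapping class name -> list of items (paths or ids).
    explicit_counts:
        Optional per-class (train, valid, test) overriding the rounding rule
        (used to reproduce a published split verbatim).

    Returns
    -------
    (SplitCounts, assignment) where assignment maps item -> 'train' |
    'valid' | 'test'.  The permutation per class is seeded; the same seed
    yields the same assignment.
    """
    classes = tuple(sorted(items_by_class))
    trains, valids, tests = [], [], []
    assignment: dict = {}
    root_seq = np.random.SeedSequence(seed)
    children = root_seq.spawn(len(classes))
    for cls, child in zip(classes, children):
        items = list(items_by_class[cls])
        n = len(items)
        if explicit_counts is not None and cls in explicit_counts:
            tr, va, te = explicit_counts[cls]
            if tr + va + te != n:
                raise ValueError(f"explicit counts for {cls!r} sum to "
                                 f"{tr + va + te}, but the class has {n} items")
        else:
            tr, va, te = split_counts_for_total(n, ratios)
        rng = np.random.default_rng(child)
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            subset = "valid" if pos < va else ("test" if pos < va + te else "train")
            assignment[items[idx]] = subset
        trains.append(tr)
        valids.append(va)
        tests.append(te)
    counts = SplitCounts(classes, tuple(trains), tuple(valids), tuple(tests))
    return counts, assignment


# -- image IO ------------------------------------------------------------------

def list_image_folder(root) -> dict[str, list[Path]]:
    """Scan ``root/<class>/*`` for images, classes and files sorted."""
    root = Path(root)
    out: dict[str, list[Path]] = {}
    for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        files = sorted(p for p in cls_dir.iterdir()
                       if p.suffix.lower() in IMAGE_EXTENSIONS)
        if files:
            out[cls_dir.name] = files
    if not out:
        raise ValueError(f"no class folders with images under {root}")
    return out


def load_image(path, resolution: int | None = None) -> np.ndarray:
    """Load an image as HWC uint8, optionally bilinear-resized to a square."""
    with Image.open(path) as im:
        im = im.convert("RGB")
        if resolution is not None and im.size != (resolution, resolution):
            im = im.resize((resolution, resolution), Image.BILINEAR)
        return np.asarray(im, dtype=np.uint8)


def write_manifest(path, assignment: dict, classes_of: dict) -> None:
    """CSV manifest: path, class, subset."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "class", "subset"])
        for item in sorted(assignment, key=str):
            w.writerow([str(item), classes_of[item], assignment[item]])


def read_manifest(path) -> list[tuple[str, str, str]]:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if rows and rows[0] == ["path", "class", "subset"]:
        rows = rows[1:]
    return [(r[0], r[1], r[2]) for r in rows]


def to_model_input(images: np.ndarray) -> np.ndarray:
    """HWC uint8 batch -> NCHW float32 standardised to [-1, 1]."""
    x = np.asarray(images, dtype=np.float32) / 255.0
    if x.ndim == 3:
        x = x[None]
    x = (x - 0.5) / 0.5
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


# -- augmentations -------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationConfig:
    """Online-augmentation and robustness-protocol settings."""

    cutout_size: int = 56
    gridmask_ratio: float = 0.4
    gridmask_period: int = 56
    erase_prob: float = 1.0
    erase_area_range: tuple[float, float] = (0.02, 0.33)
    erase_aspect_range: tuple[float, float] = (0.3, 3.3)
    photometric_factors: tuple[float, ...] = ROBUSTNESS_FACTORS
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gridmask_ratio <= 1.0:
            raise ValueError("gridmask_ratio must be in [0, 1]")
        if self.gridmask_period < 2:
            raise ValueError("gridmask_period must be >= 2")
        lo, hi = self.erase_area_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("erase_area_range must satisfy 0 < lo <= hi < 1")
        if not 0.0 <= self.erase_prob <= 1.0:
            raise ValueError("erase_prob must be a probability")


def cutout(image: np.ndarray, size: int,
           rng: np.random.Generator) -> np.ndarray:
    """Zero one axis-aligned square of side ``size`` centred at a uniform
    position; the square may overhang the border (clipped), in which case
    fewer than ``size**2`` pixels are zeroed."""
    img = np.array(image, copy=True)
    if size == 0:
        return img
    h, w = img.shape[:2]
    if size > min(h, w):
        raise ValueError(f"cutout size {size} exceeds image extent {min(h, w)}")
    cy = int(rng.integers(0, h))
    cx = int(rng.integers(0, w))
    y0, y1 = max(0, cy - size // 2), min(h, cy - size // 2 + size)
    x0, x1 = max(0, cx - size // 2), min(w, cx - size // 2 + size)
    img[y0:y1, x0:x1] = 0
    return img


def grid_mask(image: np.ndarray, ratio: float, period: int,
              rng: np.random.Generator) -> np.ndarray:
    """Multiply by a periodic binary mask of the image's own resolution.

    Within every ``period x period`` cell a square of side
    ``round(ratio * period)`` is dropped, so the masked area fraction is
    ``(round(ratio * period) / period) ** 2`` (ratio quantised to the
    period).  ``ratio=0`` keeps the whole image.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0, 1]")
    if period < 2:
        raise ValueError("period must be >= 2")
    img = np.array(image, copy=True)
    h, w = img.shape[:2]
    side = _round_half_up(ratio * period)
    if side == 0:
        return img
    oy = int(rng.integers(0, period))
    ox = int(rng.integers(0, period))
    yy = (np.arange(h)[:, None] + oy) % period < side
    xx = (np.arange(w)[None, :] + ox) % period < side
    mask = ~(yy & xx)
    return img * mask[..., None] if img.ndim == 3 else img * mask


def random_erasing(image: np.ndarray, prob: float,
                   area_range: tuple[float, float],
                   rng: np.random.Generator,
                   aspect_range: tuple[float, float] = (0.3, 3.3)) -> np.ndarray:
    """With probability ``prob`` overwrite one rectangle with random values.

    The rectangle's area fraction is drawn from ``area_range`` and its
    aspect ratio from ``aspect_range``; up to ten placement attempts are
    made before giving up (the canonical behaviour of the method).
    """
    img = np.array(image, copy=True)
    if rng.random() >= prob:
        return img
    h, w = img.shape[:2]
    for _ in range(10):
        frac = rng.uniform(*area_range)
        aspect = rng.uniform(*aspect_range)
        target = frac * h * w
        eh = int(round(np.sqrt(target * aspect)))
        ew = int(round(np.sqrt(target / aspect)))
        if eh < 1 or ew < 1 or eh > h or ew > w:
            continue
        y0 = int(rng.integers(0, h - eh + 1))
        x0 = int(rng.integers(0, w - ew + 1))
        shape = (eh, ew) + img.shape[2:]
        if np.issubdtype(img.dtype, np.integer):
            patch = rng.integers(0, 256, size=shape)
        else:
            patch = rng.random(size=shape)
        img[y0:y0 + eh, x0:x0 + ew] = patch
        break
    return img


def photometric_transform(image: np.ndarray, kind: str, factor: float) -> np.ndarray:
    """Brightness (``factor * x``) or contrast (``mean + factor * (x - mean)``)
    scaling with clipping to the valid pixel range; the contrast pivot is the
    image's own grey mean."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    if kind not in ("brightness", "contrast"):
        raise ValueError(f"unknown photometric kind {kind!r}")
    x = np.asarray(image, dtype=np.float32)
    top = 255.0 if np.issubdtype(np.asarray(image).dtype, np.integer) else 1.0
    if kind == "brightness":
        out = factor * x
    else:
        out = x.mean() + factor * (x - x.mean())
    out = np.clip(out, 0.0, top)
    return out.round().astype(np.uint8) if top == 255.0 else out


def apply_online_augmentation(image: np.ndarray, cfg: AugmentationConfig,
                              rng: np.random.Generator) -> np.ndarray:
    """Pick one of the three augmentations (probability 1/3 each — at most
    one per image per epoch) and apply it."""
    u = rng.random()
    if u < 1 / 3:
        return cutout(image, cfg.cutout_size, rng)
    if u < 2 / 3:
        return grid_mask(image, cfg.gridmask_ratio, cfg.gridmask_period, rng)
    return random_erasing(image, cfg.erase_prob, cfg.erase_area_range, rng,
                          cfg.erase_aspect_range)


def robustness_protocol(cfg: AugmentationConfig = AugmentationConfig()
                        ) -> list[tuple[str, float]]:
    """The eight (kind, factor) perturbations applied to the test set."""
    return [(kind, f) for kind in ("brightness", "contrast")
            for f in cfg.photometric_factors]


# -- dataset convenience -------------------------------------------------------

@dataclass
class ImageDataset:
    """Materialised (in-memory) image set: NCHW float32 inputs and labels."""

    images: np.ndarray            # HWC uint8, (N, H, W, 3)
    labels: np.ndarray            # (N,) int
    classes: tuple[str, ...]

    def __len__(self):
        return len(self.labels)

    def model_inputs(self) -> np.ndarray:
        return to_model_input(self.images)


def load_split(root, resolution: int, seed: int = 0,
               ratios=DEFAULT_RATIOS) -> dict[str, ImageDataset]:
    """Scan, split and load an image folder into three in-memory datasets."""
    files = list_image_folder(root)
    counts, assignment = split_dataset(files, ratios, seed)
    classes = counts.classes
    cls_index = {c: i for i, c in enumerate(classes)}
    out = {}
    for subset in ("train", "valid", "test"):
        imgs, labels = [], []
        for cls in classes:
            for path in files[cls]:
                if assignment[path] == subset:
                    imgs.append(load_image(path, resolution))
                    labels.append(cls_index[cls])
        out[subset] = ImageDataset(np.stack(imgs) if imgs else
                                   np.zeros((0, resolution, resolution, 3), np.uint8),
                                   np.asarray(labels, dtype=np.int64), classes)
    return out
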