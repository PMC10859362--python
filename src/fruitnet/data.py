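"""Class-per-folder image IO, stratified splitting, and synthetic fixtures.

The on-disk convention mirrors Fruit-360: one subdirectory per class, each
holding JPEG/PNG images (100×100 fruit photographs on a white background in
the real dataset).  Class indices are the lexicographic rank of the
subdirectory name, compared bytewise so the ordering is locale-independent.

The fixture generator procedurally draws one colored-shape family per class
(distinct shape + base hue) on a white background with jittered size,
rotation, position and additive pixel noise — a seeded, linearly separable
stand-in for the real photographs that lets every downstream component be
exercised offline.
"""

from __future__ import annotations

import colorsys
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw
from skimage.transform import resize as _sk_resize

log = logging.getLogger(__name__)

__all__ = ["LabeledImageSet", "SplitSpec", "FixtureSpec", "load_image_folder",
           "stratified_split", "preprocess", "generate_fixture"]

_IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png"}


@dataclass
class LabeledImageSet:
    images: list[np.ndarray]            # (h, w, 3) uint8 each
    labels: np.ndarray                  # int64, in [0, K)
    class_names: tuple[str, ...]
    provenance: str = "disk"            # "disk" | "synthetic"
    paths: list[str] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels differ in length")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx) -> "LabeledImageSet":
        idx = np.asarray(idx, dtype=np.int64)
        return LabeledImageSet(
            images=[self.images[i] for i in idx],
            labels=self.labels[idx],
            class_names=self.class_names,
            provenance=self.provenance,
            paths=[self.paths[i] for i in idx] if self.paths else None,
        )

    def preprocessed(self, size: int) -> tuple[np.ndarray, np.ndarray]:
        """Stack into a model-ready (n, size, size, 3) float batch in [-1, 1]."""
        X = np.stack([preprocess(im, size) for im in self.images])
        return X.astype(np.float32), self.labels.copy()

    def to_dir(self, root) -> None:
        root = Path(root)
        for k, name in enumerate(self.class_names):
            (root / name).mkdir(parents=True, exist_ok=True)
        counters = [0] * self.n_classes
        for img, lab in zip(self.images, self.labels):
            name = self.class_names[lab]
            Image.fromarray(img).save(root / name / f"img_{counters[lab]:04d}.png")
            counters[lab] += 1


def load_image_folder(root, strict: bool = False) -> LabeledImageSet:
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"{root} is not a directory")
    class_dirs = sorted((d for d in root.iterdir() if d.is_dir()),
                        key=lambda d: d.name.encode())
    if len(class_dirs) < 2:
        raise ValueError(f"{root} must contain at least 2 class subdirectories, "
                         f"found {len(class_dirs)}")
    images, labels, paths = [], [], []
    for k, d in enumerate(class_dirs):
        n_before = len(images)
        for f in sorted(d.iterdir(), key=lambda p: p.name.encode()):
            if not f.is_file():
                continue
            if f.suffix.lower() not in _IMAGE_SUFFIXES:
                log.warning("skipping non-image file %s", f)
                continue
            try:
                with Image.open(f) as im:
                    arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
            except Exception as exc:
                if strict:
                    raise ValueError(f"unreadable image {f}: {exc}") from exc
                log.warning("skipping unreadable image %s (%s)", f, exc)
                continue
            images.append(arr)
            labels.append(k)
            paths.append(str(f))
        if len(images) == n_before:
            raise ValueError(f"class directory {d} holds no decodable image")
    return LabeledImageSet(images=images, labels=np.asarray(labels),
                           class_names=tuple(d.name for d in class_dirs),
                           provenance="disk", paths=paths)


@dataclass(frozen=True)
class SplitSpec:
    """Fractions over (train, val) or (train, val, test); must sum to 1."""

    fractions: tuple[float, ...] = (0.8, 0.2)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if len(self.fractions) not in (2, 3):
            raise ValueError("need 2 or 3 split fractions")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions sum to {sum(self.fractions)}, not 1")


def _partition_sizes(n: int, fractions) -> list[int]:
    cum = np.round(np.cumsum(fractions) * n).astype(int)
    cum[-1] = n
    sizes = np.diff(np.concatenate([[0], cum]))
    return [int(s) for s in sizes]


def stratified_split(ds: LabeledImageSet, spec: SplitSpec) -> tuple[LabeledImageSet, ...]:
    """Disjoint, exhaustive, per-class seeded partitions (±1 image of target)."""
    rng = np.random.default_rng(spec.seed)
    n_parts = len(spec.fractions)
    buckets: list[list[int]] = [[] for _ in range(n_parts)]
    if spec.stratified:
        for k, name in enumerate(ds.class_names):
            idx = np.flatnonzero(ds.labels == k)
            rng.shuffle(idx)
            sizes = _partition_sizes(len(idx), spec.fractions)
            if any(s < 1 for s in sizes):
                raise ValueError(
                    f"class {name!r} has only {len(idx)} images; "
                    f"cannot fill all {n_parts} partitions with fractions {spec.fractions}"
                )
            start = 0
            for b, s in zip(buckets, sizes):
                b.extend(idx[start : start + s].tolist())
                start += s
    else:
        idx = rng.permutation(len(ds))
        sizes = _partition_sizes(len(ds), spec.fractions)
        start = 0
        for b, s in zip(buckets, sizes):
            b.extend(idx[start : start + s].tolist())
            start += s
    return tuple(ds.subset(sorted(b)) for b in buckets)


def preprocess(image: np.ndarray, size: int = 100) -> np.ndarray:
    """Resize (bilinear, no anti-aliasing) to size×size and map to [-1, 1].

    uint8 inputs are scaled from [0, 255]; float inputs already inside
    [-1, 1] are assumed scaled (making the operation idempotent).
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an RGB (h, w, 3) array, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 127.5 - 1.0
    else:
        arr = arr.astype(np.float32)
        if arr.max(initial=-np.inf) > 1.0 + 1e-6 or arr.min(initial=np.inf) < -1.0 - 1e-6:
            arr = arr / 127.5 - 1.0
    if arr.shape[:2] != (size, size):
        arr = _sk_resize(arr, (size, size), order=1, anti_aliasing=False,
                         mode="edge", preserve_range=True).astype(np.float32)
    return arr


# ---------------------------------------------------------------------------
# synthetic fixtures

_SHAPES = ("circle", "square", "triangle", "star", "cross", "hexagon", "diamond")


@dataclass(frozen=True)
class FixtureSpec:
    """Study-scale synthetic image set: K distinct (shape, hue) families on a
    white background, with pose/size jitter and additive pixel noise."""

    num_classes: int = 5
    images_per_class: int = 40
    image_size: int = 100
    seed: int = 0
    size_jitter: float = 0.15      # relative radius jitter
    noise_level: float = 6.0       # Gaussian sigma in 8-bit pixel units

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.images_per_class < 1:
            raise ValueError("need at least 1 image per class")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")


def _shape_vertices(shape: str, cx: float, cy: float, r: float, theta: float):
    def ring(n, radius, phase=0.0):
        return [(cx + radius * math.cos(theta + phase + 2 * math.pi * i / n),
                 cy + radius * math.sin(theta + phase + 2 * math.pi * i / n))
                for i in range(n)]

    if shape == "square":
        return ring(4, r, math.pi / 4)
    if shape == "triangle":
        return ring(3, r, -math.pi / 2)
    if shape == "hexagon":
        return ring(6, r)
    if shape == "diamond":
        pts = ring(4, r, 0.0)
        return [(cx + 0.6 * (x - cx), y) if i % 2 else (x, y) for i, (x, y) in enumerate(pts)]
    if shape == "star":
        pts = []
        for i in range(10):
            radius = r if i % 2 == 0 else 0.45 * r
            a = theta - math.pi / 2 + math.pi * i / 5
            pts.append((cx + radius * math.cos(a), cy + radius * math.sin(a)))
        return pts
    if shape == "cross":
        w = 0.35 * r
        raw = [(-w, -r), (w, -r), (w, -w), (r, -w), (r, w), (w, w),
               (w, r), (-w, r), (-w, w), (-r, w), (-r, -w), (-w, -w)]
        ct, st = math.cos(theta), math.sin(theta)
        return [(cx + x * ct - y * st, cy + x * st + y * ct) for x, y in raw]
    raise ValueError(f"unknown shape {shape!r}")


def _draw_sample(shape: str, hue: float, size: int, rng: np.random.Generator,
                 size_jitter: float, noise_level: float) -> np.ndarray:
    img = Image.new("RGB", (size, size), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    r = 0.30 * size * (1.0 + size_jitter * (2.0 * rng.random() - 1.0))
    cx = size / 2 + 0.08 * size * (2.0 * rng.random() - 1.0)
    cy = size / 2 + 0.08 * size * (2.0 * rng.random() - 1.0)
    theta = 2.0 * math.pi * rng.random()
    sat = 0.75 + 0.2 * rng.random()
    val = 0.65 + 0.25 * rng.random()
    rgb = tuple(int(round(255 * v)) for v in colorsys.hsv_to_rgb(hue % 1.0, sat, val))
    if shape == "circle":
        ecc = 1.0 + 0.15 * (2.0 * rng.random() - 1.0)
        draw.ellipse([cx - r, cy - r / ecc, cx + r, cy + r / ecc], fill=rgb)
    else:
        draw.polygon(_shape_vertices(shape, cx, cy, r, theta), fill=rgb)
    arr = np.asarray(img, dtype=np.float32)
    if noise_level > 0:
        arr = arr + rng.normal(0.0, noise_level, arr.shape)
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def generate_fixture(spec: FixtureSpec, out_dir=None) -> LabeledImageSet:
    """Deterministic under ``spec.seed``; optionally also written to disk in
    the class-per-folder convention."""
    rng = np.random.default_rng(spec.seed)
    images, labels, names = [], [], []
    for k in range(spec.num_classes):
        shape = _SHAPES[k % len(_SHAPES)]
        hue = k / spec.num_classes
        names.append(f"class_{k:03d}_{shape}")
        for _ in range(spec.images_per_class):
            images.append(_draw_sample(shape, hue, spec.image_size, rng,
                                       spec.size_jitter, spec.noise_level))
            labels.append(k)
    ds = LabeledImageSet(images=images, labels=np.asarray(labels),
                         class_names=tuple(names), provenance="synthetic")
    if out_dir is not None:
        ds.to_dir(out_dir)
    return ds
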