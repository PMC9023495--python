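"""Deterministic synthetic labeled-image datasets.

Each class is defined by a parametric prototype: 2-4 geometric glyphs with
class-specific hue and texture drawn on a correlated-noise background, so
that local crops stay class-informative. Samples are the prototype perturbed
by per-pixel Gaussian noise (``noise_sd``) and, optionally, per-sample
geometric jitter of the glyphs (``jitter``). ``similarity`` interpolates all
class prototypes toward one shared template. Everything is a pure function
of :class:`SynthConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "SynthConfig", "LabeledDataset", "ConfigurationError",
    "generate_dataset", "make_source_target_pair",
    "write_dataset", "load_dataset",
]


class ConfigurationError(ValueError):
    """Invalid synthetic-dataset configuration."""


@dataclass(frozen=True)
class SynthConfig:
    n_classes: int
    n_per_class: int
    image_size: int = 64
    noise_sd: float = 0.05
    similarity: float = 0.0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be a positive integer")
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be a positive integer")
        if self.image_size < 8:
            raise ConfigurationError("image_size must be at least 8 pixels")
        if not (0.0 <= self.noise_sd <= 1.0):
            raise ConfigurationError("noise_sd must lie in [0, 1]")
        if not (0.0 <= self.similarity < 1.0):
            raise ConfigurationError("similarity must lie in [0, 1)")
        if not (0.0 <= self.jitter <= 1.0):
            raise ConfigurationError("jitter must lie in [0, 1]")


@dataclass
class LabeledDataset:
    """Images (uint8 HWC), integer labels in [0, C), and class names."""

    images: List[np.ndarray]
    labels: np.ndarray
    class_names: List[str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ConfigurationError("images and labels length mismatch")
        c = len(self.class_names)
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= c):
            raise ConfigurationError("labels outside declared class ids")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset([self.images[i] for i in idx],
                              self.labels[idx], list(self.class_names))


# ---------------------------------------------------------------------------
# Prototype construction
# ---------------------------------------------------------------------------

_SHAPES = ("disk", "box", "bar", "ring")


def _glyph_params(rng, n_glyphs: int):
    """Class-specific glyph parameters, in fractional image coordinates."""
    glyphs = []
    for _ in range(n_glyphs):
        glyphs.append({
            "shape": _SHAPES[int(rng.integers(0, len(_SHAPES)))],
            "cx": float(rng.uniform(0.2, 0.8)),
            "cy": float(rng.uniform(0.2, 0.8)),
            "r": float(rng.uniform(0.1, 0.28)),
            "color": rng.uniform(0.15, 1.0, size=3),
            "stripe_freq": float(rng.uniform(2.0, 7.0)),
            "stripe_angle": float(rng.uniform(0.0, np.pi)),
            "stripe_amp": float(rng.uniform(0.0, 0.4)),
        })
    return glyphs


def _render(glyphs, background, size: int, jitter_rng=None, jitter: float = 0.0):
    """Paint glyphs over a background; optional per-sample geometric jitter."""
    img = background.copy()
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) / size
    for g in glyphs:
        cx, cy, r = g["cx"], g["cy"], g["r"]
        if jitter_rng is not None and jitter > 0.0:
            cx = float(np.clip(cx + jitter_rng.uniform(-0.15, 0.15) * jitter, 0.05, 0.95))
            cy = float(np.clip(cy + jitter_rng.uniform(-0.15, 0.15) * jitter, 0.05, 0.95))
            r = float(np.clip(r * (1.0 + jitter_rng.uniform(-0.4, 0.4) * jitter), 0.04, 0.45))
        dx, dy = xx - cx, yy - cy
        if g["shape"] == "disk":
            mask = dx * dx + dy * dy <= r * r
        elif g["shape"] == "box":
            mask = (np.abs(dx) <= r) & (np.abs(dy) <= r)
        elif g["shape"] == "bar":
            mask = (np.abs(dx) <= r) & (np.abs(dy) <= 0.4 * r)
        else:  # ring
            d2 = dx * dx + dy * dy
            mask = (d2 <= r * r) & (d2 >= (0.55 * r) ** 2)
        stripes = 1.0 - g["stripe_amp"] * (
            0.5 + 0.5 * np.sin(2.0 * np.pi * g["stripe_freq"] *
                               (xx * np.cos(g["stripe_angle"]) + yy * np.sin(g["stripe_angle"]))))
        color = g["color"][None, None, :] * stripes[:, :, None]
        img = np.where(mask[:, :, None], color, img)
    return img


def _background(rng, size: int):
    """Correlated (low-frequency) noise field with a random tint."""
    coarse = rng.uniform(0.0, 1.0, size=(4, 4, 3))
    img = np.asarray(Image.fromarray((coarse * 255).astype(np.uint8)).resize(
        (size, size), resample=Image.BILINEAR)).astype(np.float64) / 255.0
    tint = rng.uniform(0.2, 0.8, size=3)
    return 0.5 * img + 0.5 * tint[None, None, :]


def _class_prototype(cfg: SynthConfig, k: int):
    """Glyphs + background for class ``k``; pure function of (seed, k)."""
    rng = np.random.default_rng([cfg.seed, 1000 + k])
    n_glyphs = int(rng.integers(2, 5))
    return _glyph_params(rng, n_glyphs), _background(rng, cfg.image_size)


def _shared_template(cfg: SynthConfig):
    rng = np.random.default_rng([cfg.seed, 999_999])
    return _glyph_params(rng, 3), _background(rng, cfg.image_size)


def generate_dataset(cfg: SynthConfig) -> LabeledDataset:
    """Render ``n_classes * n_per_class`` 8-bit RGB images.

    With ``similarity=0`` class prototypes are pairwise distinct; raising
    ``similarity`` alpha-blends each rendered prototype toward one shared
    template image. ``noise_sd=0`` and ``jitter=0`` make all images of a
    class identical to the class prototype.
    """
    size = cfg.image_size
    shared_img = None
    if cfg.similarity > 0.0:
        sg, sb = _shared_template(cfg)
        shared_img = _render(sg, sb, size)
    images: List[np.ndarray] = []
    labels: List[int] = []
    for k in range(cfg.n_classes):
        glyphs, background = _class_prototype(cfg, k)
        sample_rng = np.random.default_rng([cfg.seed, 2_000_000 + k])
        for _ in range(cfg.n_per_class):
            jr = sample_rng if cfg.jitter > 0.0 else None
            img = _render(glyphs, background, size, jitter_rng=jr, jitter=cfg.jitter)
            if shared_img is not None:
                img = (1.0 - cfg.similarity) * img + cfg.similarity * shared_img
            if cfg.noise_sd > 0.0:
                img = img + sample_rng.normal(0.0, cfg.noise_sd, size=img.shape)
            images.append((np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8))
            labels.append(k)
    names = [f"class_{k:03d}" for k in range(cfg.n_classes)]
    return LabeledDataset(images, np.asarray(labels), names)


def make_source_target_pair(source_cfg: SynthConfig,
                            target_cfg: SynthConfig) -> Tuple[LabeledDataset, LabeledDataset]:
    """Two datasets with shared low-level statistics but disjoint categories.

    The class prototypes are keyed by each config's seed, so the configs must
    use different seeds; equal seeds would alias source and target classes.
    """
    if source_cfg.seed == target_cfg.seed:
        raise ConfigurationError(
            "source and target must use disjoint prototype seeds (got equal seeds)")
    return generate_dataset(source_cfg), generate_dataset(target_cfg)


# ---------------------------------------------------------------------------
# Disk layout: <root>/<class_name>/<idx>.png + manifest.tsv + meta.yaml
# ---------------------------------------------------------------------------

def write_dataset(ds: LabeledDataset, root, cfg: SynthConfig = None) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    counters = {k: 0 for k in range(ds.n_classes)}
    rows = []
    for img, label in zip(ds.images, ds.labels):
        name = ds.class_names[label]
        (root / name).mkdir(exist_ok=True)
        rel = f"{name}/{counters[label]:05d}.png"
        Image.fromarray(img).save(root / rel)
        rows.append(f"{rel}\t{int(label)}")
        counters[label] += 1
    (root / "manifest.tsv").write_text("\n".join(rows) + "\n")
    meta = {"class_names": list(ds.class_names)}
    if cfg is not None:
        meta["synth_config"] = dataclasses.asdict(cfg)
    (root / "meta.yaml").write_text(yaml.safe_dump(meta))
    return root


def load_dataset(root) -> LabeledDataset:
    """Read a folder-per-class dataset back via its manifest."""
    root = Path(root)
    manifest = root / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv under {root}")
    images, labels = [], []
    for line in manifest.read_text().splitlines():
        rel, label = line.rsplit("\t", 1)
        images.append(np.asarray(Image.open(root / rel).convert("RGB")))
        labels.append(int(label))
    meta = yaml.safe_load((root / "meta.yaml").read_text()) if (root / "meta.yaml").exists() else {}
    names = meta.get("class_names")
    if names is None:
        names = [f"class_{k:03d}" for k in range(max(labels) + 1)]
    return LabeledDataset(images, np.asarray(labels), names)
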