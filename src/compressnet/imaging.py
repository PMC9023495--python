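"""Train-time augmentation and test-time preprocessing.

Training applies four sequential steps — random scaling (area fraction,
aspect preserved), random ratio (width/height resampled, area preserved),
random crop (location and size within the image), resize to the network
input — then float conversion to [0, 1] and channel-wise normalization.
Testing is deterministic: resize, center crop, float, normalize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from PIL import Image

__all__ = [
    "AugmentationConfig", "InputError",
    "train_transform", "test_transform",
    "sample_augmentation_params", "compute_normalization",
]

MIN_SIDE = 8


class InputError(ValueError):
    """Raised for non-RGB or degenerate input images."""


@dataclass(frozen=True)
class AugmentationConfig:
    scale_range: Tuple[float, float] = (0.08, 1.0)
    ratio_range: Tuple[float, float] = (3.0 / 4.0, 4.0 / 3.0)
    crop_frac_range: Tuple[float, float] = (0.5, 1.0)
    train_out: int = 224
    test_resize: int = 256
    test_crop: int = 224
    mean: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    sd: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"scale_range must satisfy 0 < lo <= hi <= 1, got {self.scale_range}")
        if self.ratio_range[0] > self.ratio_range[1]:
            raise ValueError("ratio_range lower bound exceeds upper bound")
        if self.test_crop > self.test_resize:
            raise ValueError("test_crop must not exceed test_resize")
        if any(s <= 0 for s in self.sd):
            raise ValueError("sd entries must be positive")


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InputError(f"expected an H x W x 3 RGB array, got shape {img.shape}")
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise InputError(f"degenerate image of shape {img.shape}")
    if img.dtype != np.uint8:
        raise InputError(f"expected 8-bit pixels, got dtype {img.dtype}")
    return img


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _side(x: float) -> int:
    return max(MIN_SIDE, _round_half_up(x))


def _resize(img: np.ndarray, w: int, h: int) -> np.ndarray:
    # bilinear; Pillow's `reducing_gap` default already antialiases downscales
    pil = Image.fromarray(img)
    return np.asarray(pil.resize((w, h), resample=Image.BILINEAR))


def sample_augmentation_params(shape: Tuple[int, int], cfg: AugmentationConfig, rng):
    """Draw the randomness of one train-transform application.

    Returns a dict with the sampled area fraction (log-uniform over
    ``scale_range``), width/height ratio (uniform over ``ratio_range``), crop
    fractions and crop anchor fractions, plus the intermediate integer
    geometry. Split out from :func:`train_transform` so the samplers are
    directly checkable.
    """
    h0, w0 = shape
    area_frac = float(np.exp(rng.uniform(np.log(cfg.scale_range[0]),
                                         np.log(cfg.scale_range[1]))))
    side = math.sqrt(area_frac)
    h1, w1 = _side(h0 * side), _side(w0 * side)

    ratio = float(rng.uniform(cfg.ratio_range[0], cfg.ratio_range[1]))
    area = h1 * w1
    w2 = _side(math.sqrt(area * ratio))
    h2 = _side(math.sqrt(area / ratio))

    crop_fh = float(rng.uniform(*cfg.crop_frac_range))
    crop_fw = float(rng.uniform(*cfg.crop_frac_range))
    ch = max(1, min(h2, _round_half_up(h2 * crop_fh)))
    cw = max(1, min(w2, _round_half_up(w2 * crop_fw)))
    top = int(rng.integers(0, h2 - ch + 1))
    left = int(rng.integers(0, w2 - cw + 1))
    return {
        "area_frac": area_frac, "ratio": ratio,
        "scaled_size": (h1, w1), "ratio_size": (h2, w2),
        "crop": (top, left, ch, cw),
    }


def _normalize(img: np.ndarray, cfg: AugmentationConfig) -> np.ndarray:
    x = img.astype(np.float32) / 255.0          # float conversion to [0, 1]
    x = x.transpose(2, 0, 1)                    # CHW
    mean = np.asarray(cfg.mean, dtype=np.float32)[:, None, None]
    sd = np.asarray(cfg.sd, dtype=np.float32)[:, None, None]
    return (x - mean) / sd


def train_transform(image: np.ndarray, cfg: AugmentationConfig, rng) -> np.ndarray:
    """Four-step random augmentation -> float CHW tensor of side ``train_out``."""
    img = _check_image(image)
    p = sample_augmentation_params(img.shape[:2], cfg, rng)
    h1, w1 = p["scaled_size"]
    img = _resize(img, w1, h1)                  # (1) random scaling
    h2, w2 = p["ratio_size"]
    img = _resize(img, w2, h2)                  # (2) random ratio
    top, left, ch, cw = p["crop"]
    img = img[top:top + ch, left:left + cw]     # (3) random crop
    img = _resize(img, cfg.train_out, cfg.train_out)  # (4) resize
    return _normalize(img, cfg)


def test_transform(image: np.ndarray, cfg: AugmentationConfig) -> np.ndarray:
    """Deterministic resize + center crop -> float CHW tensor."""
    img = _check_image(image)
    img = _resize(img, cfg.test_resize, cfg.test_resize)
    off = (cfg.test_resize - cfg.test_crop) // 2
    img = img[off:off + cfg.test_crop, off:off + cfg.test_crop]
    return _normalize(img, cfg)


def compute_normalization(images) -> Tuple[Tuple[float, ...], Tuple[float, ...]]:
    """Per-channel mean/sd of a set of uint8 images, on the [0, 1] scale."""
    acc = np.zeros(3)
    acc2 = np.zeros(3)
    n = 0
    for img in images:
        x = _check_image(img).reshape(-1, 3).astype(np.float64) / 255.0
        acc += x.sum(axis=0)
        acc2 += (x * x).sum(axis=0)
        n += x.shape[0]
    mean = acc / n
    sd = np.sqrt(np.maximum(acc2 / n - mean ** 2, 1e-12))
    return tuple(float(v) for v in mean), tuple(float(v) for v in sd)
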