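"""Accuracy protocol: per-category (macro) top-k accuracy, confusion
matrices, and repeated stratified 70/30 splits with mean +/- std reporting.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from .imaging import AugmentationConfig, test_transform
from .network import ModelState, forward
from .synthetic import LabeledDataset

__all__ = [
    "EvalReport", "predict_logits", "topk_macro_accuracy",
    "confusion_matrix", "stratified_split", "repeated_split_eval",
]


@dataclass
class EvalReport:
    topk: Dict[int, Tuple[float, float]]          # k -> (mean %, std %)
    per_class_accuracy: List[np.ndarray]          # one length-C vector per split
    confusion: List[np.ndarray]                   # one C x C matrix per split
    n_splits: int

    def to_dict(self) -> dict:
        return {
            "topk": {int(k): {"mean": m, "std": s} for k, (m, s) in self.topk.items()},
            "per_class_accuracy": [v.tolist() for v in self.per_class_accuracy],
            "confusion": [m.tolist() for m in self.confusion],
            "n_splits": self.n_splits,
        }


def predict_logits(model: ModelState, images: Sequence[np.ndarray],
                   aug: AugmentationConfig, batch_size: int = 64) -> np.ndarray:
    """Deterministic test-transform inference over a list of uint8 images."""
    out = []
    for i in range(0, len(images), batch_size):
        batch = np.stack([test_transform(img, aug) for img in images[i:i + batch_size]])
        out.append(forward(model, batch, training=False).logits)
    return np.concatenate(out, axis=0)


def _topk_hits(logits: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    # ties broken by ascending class index: stable argsort on the negated scores
    order = np.argsort(-logits, axis=1, kind="stable")
    return (order[:, :k] == labels[:, None]).any(axis=1)


def topk_macro_accuracy(logits: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Unweighted mean over classes of the per-class top-k hit rate, in %.

    Classes absent from ``labels`` are excluded with a warning.
    """
    logits = np.asarray(logits)
    labels = np.asarray(labels)
    n_classes = logits.shape[1]
    if not (1 <= k <= n_classes):
        raise ValueError(f"k must lie in [1, {n_classes}], got {k}")
    hits = _topk_hits(logits, labels, k)
    accs = []
    empty = []
    for c in range(n_classes):
        mask = labels == c
        if not mask.any():
            empty.append(c)
            continue
        accs.append(float(hits[mask].mean()))
    if empty:
        warnings.warn(f"classes {empty} have no test samples; excluded from the macro mean")
    return float(np.mean(accs)) * 100.0


def confusion_matrix(preds: np.ndarray, labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Counts indexed (true label, predicted label)."""
    preds = np.asarray(preds, dtype=int)
    labels = np.asarray(labels, dtype=int)
    for name, a in (("preds", preds), ("labels", labels)):
        if len(a) and (a.min() < 0 or a.max() >= n_classes):
            raise ValueError(f"{name} contain ids outside [0, {n_classes})")
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (labels, preds), 1)
    return mat


def stratified_split(labels: np.ndarray, train_frac: float,
                     rng) -> Tuple[np.ndarray, np.ndarray]:
    """Per-class split: round(train_frac * n_c) to train, remainder to test."""
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has fewer than 2 samples; cannot split")
        idx = rng.permutation(idx)
        n_train = int(math.floor(train_frac * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.asarray(sorted(train_idx)), np.asarray(sorted(test_idx))


def repeated_split_eval(dataset: LabeledDataset,
                        model_factory: Callable[[LabeledDataset, int], ModelState],
                        aug: AugmentationConfig, *, n_repeats: int = 5,
                        train_frac: float = 0.7, seed: int = 0,
                        topk: Sequence[int] = (1, 5)) -> EvalReport:
    """Run the training recipe on ``n_repeats`` seeded stratified splits.

    ``model_factory(train_subset, split_seed)`` returns a trained model; each
    repeat is evaluated on its held-out fraction and top-k means/sample
    standard deviations are aggregated across repeats.
    """
    rng = np.random.default_rng(seed)
    topk = [k for k in topk if k <= dataset.n_classes]
    per_split_topk: Dict[int, List[float]] = {k: [] for k in topk}
    per_class_all, confusions = [], []
    for rep in range(n_repeats):
        split_seed = int(rng.integers(0, 2 ** 31 - 1))
        tr_idx, te_idx = stratified_split(dataset.labels, train_frac,
                                          np.random.default_rng(split_seed))
        model = model_factory(dataset.subset(tr_idx), split_seed)
        logits = predict_logits(model, [dataset.images[i] for i in te_idx], aug)
        te_labels = dataset.labels[te_idx]
        for k in topk:
            per_split_topk[k].append(topk_macro_accuracy(logits, te_labels, k))
        hits1 = _topk_hits(logits, te_labels, 1)
        per_class = np.array([
            hits1[te_labels == c].mean() if (te_labels == c).any() else np.nan
            for c in range(dataset.n_classes)])
        per_class_all.append(per_class)
        confusions.append(confusion_matrix(np.argmax(logits, axis=1), te_labels,
                                           dataset.n_classes))
    agg = {k: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
           for k, v in per_split_topk.items()}
    return EvalReport(topk=agg, per_class_accuracy=per_class_all,
                      confusion=confusions, n_splits=n_repeats)
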