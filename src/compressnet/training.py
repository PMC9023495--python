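"""Supervised training: cross-entropy SGD with the staged learning-rate
ladder, and the pre-train -> fine-tune regimen.

"Iterations" are optimizer steps, not epochs; the loader cycles the dataset
with a reshuffle at every pass, and the train-time augmentation is applied
independently per image from one seeded stream. The same loop also serves
the distillation and retraining stages (they pass a frozen teacher and a
non-zero penalty weight), which is what makes the lambda=0 reduction to
plain cross-entropy training exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .imaging import AugmentationConfig, train_transform
from .network import ModelState, backward, forward
from .network.ops import cross_entropy
from .synthetic import LabeledDataset

__all__ = [
    "TrainConfig", "TraceRow", "DivergenceError", "SGD",
    "train_crossentropy", "pretrain_then_finetune", "run_sgd",
]


class DivergenceError(RuntimeError):
    """Non-finite loss; carries the trace up to the failure."""

    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class TrainConfig:
    lr_schedule: Tuple[Tuple[float, int], ...] = ((0.01, 1000), (0.001, 500), (0.0001, 500))
    batch_size: int = 32
    momentum: float = 0.9
    weight_decay: float = 0.0005
    seed: int = 0
    eval_every: int = 100

    def __post_init__(self):
        object.__setattr__(self, "lr_schedule",
                           tuple((float(r), int(n)) for r, n in self.lr_schedule))
        rates = [r for r, _ in self.lr_schedule]
        if any(r2 >= r1 for r1, r2 in zip(rates, rates[1:])):
            raise ValueError("learning rates must be strictly decreasing across stages")
        if any(r <= 0 for r in rates):
            raise ValueError("learning rates must be positive")
        if any(n < 0 for _, n in self.lr_schedule):
            raise ValueError("stage iteration counts must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch size must be positive")

    @property
    def total_iterations(self) -> int:
        return sum(n for _, n in self.lr_schedule)


@dataclass
class TraceRow:
    iteration: int
    lr: float
    loss: float
    cross_entropy: float
    penalty: float
    batch_top1: float


class SGD:
    """Momentum SGD with decoupled parameter groups.

    Weight decay applies only to the ``decay`` group (conv/dense weight
    matrices); biases and normalization scale/shift are in the ``no_decay``
    group. ``param_groups`` exposes the grouping for inspection.
    """

    def __init__(self, model: ModelState, momentum: float, weight_decay: float):
        self.model = model
        self.momentum = momentum
        decay, no_decay = [], []
        for i, p in enumerate(model.params):
            for k in p:
                if k in ("running_mean", "running_var"):
                    continue
                (decay if k == "W" else no_decay).append((i, k))
        self.param_groups = [
            {"weight_decay": weight_decay, "params": decay},
            {"weight_decay": 0.0, "params": no_decay},
        ]
        self.velocity = {key: np.zeros_like(model.params[key[0]][key[1]])
                         for g in self.param_groups for key in g["params"]}

    def step(self, grads, lr: float) -> None:
        for group in self.param_groups:
            wd = group["weight_decay"]
            for (i, k) in group["params"]:
                g = grads[i].get(k)
                if g is None:
                    continue
                p = self.model.params[i][k]
                if wd:
                    g = g + wd * p
                v = self.velocity[(i, k)]
                v *= self.momentum
                v += g
                p -= (lr * v).astype(p.dtype, copy=False)


def _iter_lr(schedule) -> List[float]:
    out = []
    for rate, n in schedule:
        out.extend([rate] * n)
    return out


def _onehot_top1(logits, labels) -> float:
    return float(np.mean(np.argmax(logits, axis=1) == labels)) * 100.0


def run_sgd(model: ModelState, data: LabeledDataset, aug: AugmentationConfig,
            cfg: TrainConfig, *, teacher: Optional[ModelState] = None,
            penalty_weight: float = 0.0,
            log=None) -> Tuple[ModelState, List[TraceRow]]:
    """The shared mini-batch loop.

    Minimizes mean cross-entropy plus, when a frozen ``teacher`` is given,
    ``penalty_weight`` times the squared distance between student and teacher
    hidden vectors of the SAME augmented batch. The teacher runs in
    evaluation mode and is never written to.
    """
    if model.spec.n_classes != data.n_classes:
        raise ValueError(
            f"model has {model.spec.n_classes} classes, dataset has {data.n_classes}")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model, cfg.momentum, cfg.weight_decay)
    lrs = _iter_lr(cfg.lr_schedule)
    trace: List[TraceRow] = []
    n = len(data)
    order = rng.permutation(n)
    cursor = 0
    for it, lr in enumerate(lrs):
        idx = []
        while len(idx) < cfg.batch_size:
            if cursor == n:
                order = rng.permutation(n)
                cursor = 0
            take = min(cfg.batch_size - len(idx), n - cursor)
            idx.extend(order[cursor:cursor + take])
            cursor += take
        batch = np.stack([train_transform(data.images[i], aug, rng) for i in idx])
        labels = data.labels[np.asarray(idx)]

        res = forward(model, batch, training=True, record=True)
        ce, dlogits = cross_entropy(res.logits, labels)
        penalty = 0.0
        dhidden = None
        if teacher is not None:
            tres = forward(teacher, batch, training=False)
            diff = res.hidden - tres.hidden.astype(res.hidden.dtype)
            penalty = float(penalty_weight * np.sum(diff * diff) / batch.shape[0])
            dhidden = (2.0 * penalty_weight / batch.shape[0]) * diff
        loss = ce + penalty
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at iteration {it}", trace)
        grads = backward(model, res, dlogits, dhidden)
        opt.step(grads, lr)
        if it % cfg.eval_every == 0 or it == len(lrs) - 1:
            row = TraceRow(it, lr, loss, ce, penalty, _onehot_top1(res.logits, labels))
            trace.append(row)
            if log is not None:
                log(row)
    return model, trace


def train_crossentropy(model: ModelState, data: LabeledDataset,
                       aug: AugmentationConfig, cfg: TrainConfig,
                       log=None) -> Tuple[ModelState, List[TraceRow]]:
    """Plain mini-batch cross-entropy training (the pre-train/fine-tune loss)."""
    return run_sgd(model, data, aug, cfg, teacher=None, penalty_weight=0.0, log=log)


def pretrain_then_finetune(model: ModelState, source: LabeledDataset,
                           target: LabeledDataset, pre_cfg: TrainConfig,
                           fine_cfg: TrainConfig, aug: AugmentationConfig,
                           log=None) -> Tuple[ModelState, List[TraceRow]]:
    """Train on the source task, swap the classifier head, fine-tune on target.

    All non-head parameters cross the hand-off bit-exactly; the fresh head is
    seeded from ``fine_cfg.seed``. A zero-iteration pre-train schedule
    degrades to plain fine-tuning.
    """
    from .network import replace_head

    if model.spec.n_classes != source.n_classes:
        raise ValueError("model head must match the source class count for pre-training")
    model, _ = train_crossentropy(model, source, aug, pre_cfg, log=log)
    model = replace_head(model, target.n_classes, seed=fine_cfg.seed + 7919)
    return train_crossentropy(model, target, aug, fine_cfg, log=log)
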