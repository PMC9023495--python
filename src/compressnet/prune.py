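"""Top-down layer-wise filter cut.

For each prunable layer t (deepest first): score every filter by the mean
squared reconstruction error it induces in the nearest downstream feature
map whose size is unchanged (the reference map F_{t+1}), remove the
ceil(C_t * alpha) lowest-scoring filters together with their normalization
parameters, coupled depthwise channels and the matching input slices of the
reference layer, then retrain the cut network under the combined
cross-entropy + hidden-matching objective before moving one layer down.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .imaging import AugmentationConfig, test_transform
from .network import ModelState, NetworkSpec, copy_model, forward, parameter_count
from .network.specs import SpecError
from .distill import TransferConfig, transfer_train
from .synthetic import LabeledDataset
from .training import TraceRow, TrainConfig

__all__ = [
    "CutConfig", "FilterScoreTable", "PruneError", "CompressionReport",
    "cut_counts", "reference_layer", "score_filters", "select_filters",
    "remove_filters", "retrain_layer", "compress", "replay_cut_history",
]


class PruneError(ValueError):
    pass


def _default_retrain() -> TransferConfig:
    return TransferConfig(lambda_=1.0, train=TrainConfig(
        lr_schedule=((0.001, 5000), (0.0001, 2000))))


@dataclass(frozen=True)
class CutConfig:
    """alpha in [0, 1): cut ratio (0 = forced-empty selection, an identity
    pass used by the no-op invariant); subset_size M << N picks the scoring
    subset; the same subset (via subset_seed) is reused for every layer of
    one compress run."""

    alpha: float = 0.5
    subset_size: int = 256
    subset_seed: int = 0
    retrain: TransferConfig = field(default_factory=_default_retrain)

    def __post_init__(self):
        if not (0.0 <= self.alpha < 1.0):
            raise PruneError("cut ratio alpha must lie in [0, 1)")
        if self.subset_size < 1:
            raise PruneError("subset_size must be positive")


@dataclass
class FilterScoreTable:
    """Reconstruction-error score per current filter of one layer."""

    layer: int
    scores: Dict[int, float]

    def __post_init__(self):
        if any(v < 0 for v in self.scores.values()):
            raise PruneError("scores must be non-negative")


def cut_counts(n_filters: int, alpha: float) -> Tuple[int, int]:
    """(removed, reserved) = (ceil(C*alpha), C - ceil(C*alpha)).

    A 1e-9 guard absorbs binary float artifacts such as 10*0.3 -> 3.0000...4
    so that exact products stay exact.
    """
    removed = math.ceil(n_filters * alpha - 1e-9)
    removed = max(0, min(n_filters, removed))
    return removed, n_filters - removed


def reference_layer(spec: NetworkSpec, t: int) -> int:
    """Index of the reference layer for scoring layer ``t``.

    The nearest downstream layer whose output size is unchanged by removing
    a filter of layer ``t``: the next conv/pointwise conv, skipping coupled
    depthwise layers. Raises if only the fully-connected tail remains.
    """
    if not spec.layers[t].prunable:
        raise PruneError(f"layer {spec.layers[t].name} is not prunable")
    j = t + 1
    while j < len(spec.layers):
        kind = spec.layers[j].kind
        if kind == "depthwise_conv":
            j += 1
            continue
        if kind in ("conv", "pointwise_conv"):
            return j
        break
    raise PruneError(
        f"layer {spec.layers[t].name} has no downstream reference map "
        f"(reached the fully-connected tail)")


def _coupled_depthwise(spec: NetworkSpec, t: int, ref: int) -> List[int]:
    return [j for j in range(t + 1, ref) if spec.layers[j].kind == "depthwise_conv"]


def _with_widths(spec: NetworkSpec, widths: Dict[int, int]) -> NetworkSpec:
    """Replace out_filters of several layers atomically (keeps chaining valid)."""
    layers = list(spec.layers)
    for j, w in widths.items():
        layers[j] = dataclasses.replace(layers[j], out_filters=w)
    return dataclasses.replace(spec, layers=tuple(layers))


def _residual_sources(spec: NetworkSpec, start: int, stop: int) -> List[int]:
    out = []
    for j in range(start, stop + 1):
        src = spec.layers[j].residual_from
        if src is not None and src < start:
            out.append(src)
    return out


def remove_filters(model: ModelState, t: int, idx: Sequence[int]) -> ModelState:
    """Structurally remove filters ``idx`` of layer ``t``.

    Slices layer t's filter bank, bias and normalization parameters/statistics,
    every coupled depthwise layer in between, and the input dimension of the
    reference layer. Returns a new ModelState with the cut appended to
    ``cut_history``; the empty set is a bit-exact identity.
    """
    spec = model.spec
    c_t = spec.layers[t].out_filters
    idx = sorted(set(int(i) for i in idx))
    if any(i < 0 or i >= c_t for i in idx):
        raise PruneError(f"filter indices out of range for layer of width {c_t}")
    new = copy_model(model)
    if not idx:
        return new
    if len(idx) >= c_t:
        raise PruneError("removal would leave zero filters")
    ref = reference_layer(spec, t)
    keep = np.asarray([i for i in range(c_t) if i not in idx], dtype=int)

    def slice_out(j):
        p = new.params[j]
        p["W"] = p["W"][keep].copy()
        for k in ("b", "gamma", "beta", "running_mean", "running_var"):
            if k in p:
                p[k] = p[k][keep].copy()

    slice_out(t)
    widths = {t: len(keep)}
    for j in _coupled_depthwise(spec, t, ref):
        slice_out(j)
        widths[j] = len(keep)
    new.params[ref]["W"] = new.params[ref]["W"][:, keep].copy()

    new.spec = _with_widths(spec, widths)
    new.cut_history.append((t, idx))
    new.validate_shapes()
    return new


def replay_cut_history(base_spec: NetworkSpec, history) -> NetworkSpec:
    """Re-derive the current spec shapes by replaying cuts on the base spec."""
    spec = base_spec
    for t, idx in history:
        c_t = spec.layers[t].out_filters
        keep = [i for i in range(c_t) if i not in set(idx)]
        ref = reference_layer(spec, t)
        widths = {t: len(keep)}
        for j in _coupled_depthwise(spec, t, ref):
            widths[j] = len(keep)
        spec = _with_widths(spec, widths)
    return spec


def score_filters(model: ModelState, t: int, inputs: np.ndarray) -> FilterScoreTable:
    """Per-filter reconstruction-error scores for layer ``t``.

    ``Score_i = sum_m ||F_ref^{-i}(X_m) - F_ref(X_m)||_2^2 / M`` where
    ``F_ref^{-i}`` is the reference map recomputed with filter i (its norm
    parameters, coupled depthwise channels and matching input slice of the
    reference layer) structurally removed. Everything runs in evaluation
    mode on the given preprocessed subset.
    """
    inputs = np.asarray(inputs)
    if inputs.ndim == 3:
        inputs = inputs[None]
    m = inputs.shape[0]
    if m == 0:
        raise PruneError("scoring subset is empty")
    spec = model.spec
    ref = reference_layer(spec, t)
    c_t = spec.layers[t].out_filters

    # one prefix pass: the input to layer t, residual sources, and F_ref
    need = set(_residual_sources(spec, t, ref))
    if t > 0:
        need.add(t - 1)
    prefix = forward(model, inputs, training=False, capture={ref},
                     stop_after=ref)
    f_ref = prefix.feature_maps[ref]
    seed_outputs = {j: prefix.outputs[j] for j in need}
    x_start = inputs if t == 0 else prefix.outputs[t - 1]

    scores: Dict[int, float] = {}
    for i in range(c_t):
        cut = remove_filters(model, t, [i])
        res = forward(cut, x_start, training=False, capture={ref},
                      start=t, stop_after=ref, initial_outputs=dict(seed_outputs))
        diff = res.feature_maps[ref] - f_ref
        scores[i] = float(np.sum(diff.astype(np.float64) ** 2) / m)
    return FilterScoreTable(layer=t, scores=scores)


def select_filters(scores: FilterScoreTable, alpha: float) -> Tuple[int, ...]:
    """Indices of the ceil(C*alpha) lowest-scoring filters.

    Ties break by ascending filter index; a pure function of the score
    values, independent of table insertion order. Refuses a selection that
    would leave zero filters.
    """
    if not scores.scores:
        raise PruneError("empty score table")
    c = len(scores.scores)
    n_cut, n_keep = cut_counts(c, alpha)
    if n_cut == 0:
        return ()
    if n_keep == 0:
        raise PruneError(f"cutting {n_cut} of {c} filters would leave zero filters")
    ranked = sorted(scores.scores.items(), key=lambda kv: (kv[1], kv[0]))
    return tuple(sorted(i for i, _ in ranked[:n_cut]))


def retrain_layer(model: ModelState, teacher: ModelState, data: LabeledDataset,
                  aug: AugmentationConfig, cfg: CutConfig,
                  log=None) -> Tuple[ModelState, List[TraceRow]]:
    """Transfer-regularized retraining of a freshly cut model (W_S^t).

    With zero scheduled iterations the model is returned unchanged; with
    lambda=0 this degrades to plain cross-entropy retraining.
    """
    if cfg.retrain.train.total_iterations == 0:
        return model, []
    return transfer_train(model, teacher, data, aug, cfg.retrain, log=log)


@dataclass
class CompressionReport:
    alpha: float
    subset_size: int
    layer_order: List[int]
    layers: List[dict]
    params_before: int
    params_after: int
    prunable_params_before: int
    prunable_params_after: int
    holdout_accuracy: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compress(student: ModelState, teacher: ModelState, data: LabeledDataset,
             aug: AugmentationConfig, cfg: CutConfig,
             holdout: Optional[LabeledDataset] = None,
             log=None, on_layer=None) -> Tuple[ModelState, CompressionReport]:
    """Run score -> select -> remove -> retrain from layer T down to layer 1.

    Layer T starts from the transfer-trained student; each subsequent layer
    starts from the previous stage's retrained output. The scoring subset of
    M images is drawn once (``subset_seed``) and reused for every layer.
    Per-layer retrain seeds derive from the retrain config seed and t so the
    stages draw independent augmentation streams.
    """
    rng = np.random.default_rng(cfg.subset_seed)
    m = min(cfg.subset_size, len(data))
    subset_idx = rng.choice(len(data), size=m, replace=False)
    subset = np.stack([test_transform(data.images[i], aug) for i in subset_idx])

    def holdout_top1(mod):
        from .evaluation import predict_logits, topk_macro_accuracy
        logits = predict_logits(mod, holdout.images, aug)
        return topk_macro_accuracy(logits, holdout.labels, 1)

    report = CompressionReport(
        alpha=cfg.alpha, subset_size=m,
        layer_order=list(reversed(student.spec.prunable_layers())),
        layers=[],
        params_before=parameter_count(student),
        params_after=0,
        prunable_params_before=parameter_count(student, only_prunable=True),
        prunable_params_after=0,
    )
    if holdout is not None:
        report.holdout_accuracy.append({"stage": "initial", "top1": holdout_top1(student)})

    model = student
    for t in report.layer_order:
        table = score_filters(model, t, subset)
        removed = select_filters(table, cfg.alpha)
        model = remove_filters(model, t, removed)
        entry = {
            "layer": t,
            "layer_name": model.spec.layers[t].name,
            "scores": {int(k): v for k, v in table.scores.items()},
            "removed": [int(i) for i in removed],
            "reserved": model.spec.layers[t].out_filters,
        }
        if holdout is not None:
            entry["top1_after_cut"] = holdout_top1(model)
        stage_cfg = dataclasses.replace(
            cfg, retrain=dataclasses.replace(
                cfg.retrain, train=dataclasses.replace(
                    cfg.retrain.train, seed=cfg.retrain.train.seed + 31 * (t + 1))))
        model, _ = retrain_layer(model, teacher, data, aug, stage_cfg, log=log)
        if holdout is not None:
            entry["top1_after_retrain"] = holdout_top1(model)
            report.holdout_accuracy.append(
                {"stage": f"layer_{t}", "top1": entry["top1_after_retrain"]})
        entry["params_after"] = parameter_count(model)
        report.layers.append(entry)
        if on_layer is not None:
            on_layer(t, model)

    report.params_after = parameter_count(model)
    report.prunable_params_after = parameter_count(model, only_prunable=True)
    return model, report
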