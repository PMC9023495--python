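"""Model state, forward/backward execution, parameter accounting, checkpoints.

The execution engine is deliberately tape-based: :func:`forward` optionally
records per-layer caches which :func:`backward` replays in reverse, so the
training modules never touch layer internals. Partial forward (``start`` /
``stop_after``) is what the pruning module uses to re-evaluate a single
block against its reference map without recomputing the whole prefix.
"""

from __future__ import annotations

import dataclasses
import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import yaml

from . import ops
from .specs import CONV_KINDS, LayerSpec, NetworkSpec, SpecError

__all__ = [
    "ModelState", "ForwardResult", "build_network", "forward", "backward",
    "parameter_count", "replace_head", "copy_model",
    "save_checkpoint", "load_checkpoint",
]

PARAM_KEYS = ("W", "b", "gamma", "beta")
BUFFER_KEYS = ("running_mean", "running_var")


@dataclass
class ForwardResult:
    """Outputs of one forward pass.

    ``feature_maps[t]`` is layer t's post-norm (and post-residual-add),
    pre-activation map — the F_t used as reference map during scoring.
    """

    logits: np.ndarray
    hidden: np.ndarray
    softmax: np.ndarray
    feature_maps: Dict[int, np.ndarray] = field(default_factory=dict)
    outputs: Dict[int, np.ndarray] = field(default_factory=dict)
    tape: Optional[list] = None


@dataclass
class ModelState:
    """Parameters + buffers for every layer of ``spec``.

    ``base_spec`` is the spec the model was built from; replaying
    ``cut_history`` (a list of ``(layer_index, removed_filter_indices)``)
    against it reproduces the current ``spec`` shapes.
    """

    spec: NetworkSpec
    params: List[Dict[str, np.ndarray]]
    cut_history: List[tuple] = field(default_factory=list)
    base_spec: Optional[NetworkSpec] = None

    def __post_init__(self):
        if self.base_spec is None:
            self.base_spec = self.spec
        self.validate_shapes()

    @property
    def dtype(self):
        return self.params[0]["W"].dtype

    def validate_shapes(self):
        """Assert every parameter tensor agrees with the current spec."""
        spec = self.spec
        for i, (l, p) in enumerate(zip(spec.layers, self.params)):
            cin = spec.in_filters(i)
            if l.kind == "conv" or l.kind == "pointwise_conv":
                want = (l.out_filters, cin, l.kernel, l.kernel)
            elif l.kind == "depthwise_conv":
                want = (l.out_filters, 1, l.kernel, l.kernel)
            else:
                din = spec.trunk_out_dim() if i == spec.hidden_index else spec.hidden_dim
                want = (l.out_filters, din)
            if p["W"].shape != want:
                raise SpecError(f"layer {l.name}: weight shape {p['W'].shape} != {want}")
            if l.has_norm:
                for k in ("gamma", "beta") + BUFFER_KEYS:
                    if p[k].shape != (l.out_filters,):
                        raise SpecError(f"layer {l.name}: bad {k} shape {p[k].shape}")
            if l.bias and p["b"].shape != (l.out_filters,):
                raise SpecError(f"layer {l.name}: bad bias shape")


def _init_layer(l: LayerSpec, cin: int, din: Optional[int], rng, dtype):
    p: Dict[str, np.ndarray] = {}
    if l.kind in CONV_KINDS:
        fan_in = (1 if l.kind == "depthwise_conv" else cin) * l.kernel * l.kernel
        shape = ((l.out_filters, 1, l.kernel, l.kernel) if l.kind == "depthwise_conv"
                 else (l.out_filters, cin, l.kernel, l.kernel))
    else:
        fan_in = din
        shape = (l.out_filters, din)
    gain = 2.0 if l.activation == "relu" else 1.0
    std = float(np.sqrt(gain / fan_in))
    p["W"] = rng.normal(0.0, std, size=shape).astype(dtype)
    if l.bias:
        p["b"] = np.zeros(l.out_filters, dtype=dtype)
    if l.has_norm:
        p["gamma"] = np.ones(l.out_filters, dtype=dtype)
        p["beta"] = np.zeros(l.out_filters, dtype=dtype)
        p["running_mean"] = np.zeros(l.out_filters, dtype=dtype)
        p["running_var"] = np.ones(l.out_filters, dtype=dtype)
    return p


def build_network(spec: NetworkSpec, seed: int, dtype=np.float32) -> ModelState:
    """Initialize a model from ``spec`` with fan-in (He/Xavier) weights.

    Deterministic per ``(spec, seed)``: parameters are drawn layer by layer
    from one seeded generator.
    """
    rng = np.random.default_rng(seed)
    params = []
    for i, l in enumerate(spec.layers):
        cin = spec.in_filters(i)
        din = None
        if l.kind == "fully_connected":
            din = spec.trunk_out_dim() if i == spec.hidden_index else spec.hidden_dim
        params.append(_init_layer(l, cin, din, rng, dtype))
    return ModelState(spec=spec, params=params)


def copy_model(model: ModelState) -> ModelState:
    params = [{k: v.copy() for k, v in p.items()} for p in model.params]
    return ModelState(spec=model.spec, params=params,
                      cut_history=list(model.cut_history), base_spec=model.base_spec)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

def forward(model: ModelState, x: np.ndarray, *, training: bool = False,
            capture: Iterable[int] = (), record: bool = False,
            start: int = 0, stop_after: Optional[int] = None,
            initial_outputs: Optional[Dict[int, np.ndarray]] = None,
            mask_channels: Optional[Dict[int, Sequence[int]]] = None) -> ForwardResult:
    """Run layers ``start..stop_after`` of the model on batch ``x``.

    ``capture`` collects post-norm pre-activation feature maps F_t.
    ``record`` keeps a tape for :func:`backward`. ``initial_outputs`` seeds
    post-activation outputs of layers below ``start`` (needed when a partial
    run crosses a residual join). ``mask_channels`` zeroes the listed
    channels of a layer's post-normalization activation — the zero-masking
    equivalent of structural filter removal.
    """
    spec = model.spec
    n_layers = len(spec.layers)
    stop = n_layers - 1 if stop_after is None else stop_after
    capture = set(capture)
    mask_channels = mask_channels or {}
    outputs: Dict[int, np.ndarray] = dict(initial_outputs or {})
    feature_maps: Dict[int, np.ndarray] = {}
    tape: Optional[list] = [] if record else None

    if x.ndim == 3:
        x = x[None]
    h = np.ascontiguousarray(x, dtype=model.dtype)
    if start == 0 and h.ndim == 4 and h.shape[2] != spec.input_size and stop >= spec.hidden_index \
            and not spec.global_pool:
        raise ValueError(
            f"input side {h.shape[2]} incompatible with spec input_size {spec.input_size}")

    hidden_vec = None
    logits = None
    for i in range(start, stop + 1):
        l = spec.layers[i]
        p = model.params[i]
        entry = {"layer": i}
        if l.kind == "fully_connected" and i == spec.hidden_index and h.ndim == 4:
            if spec.global_pool:
                h, cache = ops.global_avg_pool_forward(h)
                entry["pool"] = cache
            else:
                entry["flatten"] = h.shape
                h = h.reshape(h.shape[0], -1)
        b = p.get("b")
        if l.kind == "conv" or l.kind == "pointwise_conv":
            h, cache = ops.conv2d_forward(h, p["W"], b, stride=l.stride, pad=l.pad)
        elif l.kind == "depthwise_conv":
            h, cache = ops.dwconv2d_forward(h, p["W"], b, stride=l.stride, pad=l.pad)
        else:
            h, cache = ops.dense_forward(h, p["W"], b)
        entry["main"] = cache
        if l.has_norm:
            h, bn_cache = ops.batchnorm_forward(
                h, p["gamma"], p["beta"], p["running_mean"], p["running_var"],
                training=training)
            entry["bn"] = bn_cache
        if i in mask_channels:
            idx = np.asarray(sorted(mask_channels[i]), dtype=int)
            h = h.copy()
            h[:, idx] = 0.0
            entry["mask"] = idx
        if l.residual_from is not None:
            src = outputs.get(l.residual_from)
            if src is None:
                raise ValueError(
                    f"layer {l.name}: residual source {l.residual_from} not available")
            h = h + src
            entry["residual_from"] = l.residual_from
        if i in capture:
            feature_maps[i] = h.copy()
        if l.activation == "relu":
            h, mask = ops.relu_forward(h)
            entry["relu"] = mask
        outputs[i] = h
        if i == spec.hidden_index:
            hidden_vec = h
        if i == spec.head_index:
            logits = h
        if record:
            tape.append(entry)

    sm = ops.softmax(logits) if logits is not None else None
    return ForwardResult(logits=logits, hidden=hidden_vec, softmax=sm,
                         feature_maps=feature_maps, outputs=outputs, tape=tape)


def backward(model: ModelState, result: ForwardResult, dlogits: np.ndarray,
             dhidden: Optional[np.ndarray] = None) -> List[Dict[str, np.ndarray]]:
    """Reverse-mode sweep over a recorded tape.

    ``dlogits`` is the gradient w.r.t. the logits; ``dhidden`` (optional) is
    an extra gradient injected at the hidden vector — this is how the
    hidden-matching transfer penalty enters without the training code knowing
    about layer structure.
    """
    if result.tape is None:
        raise ValueError("forward pass was not recorded (record=True required)")
    spec = model.spec
    grads: List[Dict[str, np.ndarray]] = [dict() for _ in model.params]
    pending: Dict[int, np.ndarray] = {spec.head_index: np.asarray(dlogits, dtype=model.dtype)}
    if dhidden is not None:
        pending[spec.hidden_index] = np.asarray(dhidden, dtype=model.dtype)

    for entry in reversed(result.tape):
        i = entry["layer"]
        l = spec.layers[i]
        d = pending.pop(i, None)
        if d is None:
            continue
        if "relu" in entry:
            d = ops.relu_backward(d, entry["relu"])
        if "residual_from" in entry:
            j = entry["residual_from"]
            pending[j] = pending.get(j, 0) + d
        if "mask" in entry:
            d = d.copy()
            d[:, entry["mask"]] = 0.0
        if "bn" in entry:
            d, dgamma, dbeta = ops.batchnorm_backward(d, entry["bn"])
            grads[i]["gamma"] = grads[i].get("gamma", 0) + dgamma
            grads[i]["beta"] = grads[i].get("beta", 0) + dbeta
        if l.kind == "conv" or l.kind == "pointwise_conv":
            d, dW, db = ops.conv2d_backward(d, entry["main"])
        elif l.kind == "depthwise_conv":
            d, dW, db = ops.dwconv2d_backward(d, entry["main"])
        else:
            d, dW, db = ops.dense_backward(d, entry["main"])
        grads[i]["W"] = grads[i].get("W", 0) + dW
        if db is not None:
            grads[i]["b"] = grads[i].get("b", 0) + db
        if "pool" in entry:
            d = ops.global_avg_pool_backward(d, entry["pool"])
        elif "flatten" in entry:
            d = d.reshape(entry["flatten"])
        if i > 0:
            pending[i - 1] = pending.get(i - 1, 0) + d
    return grads


def parameter_count(model: ModelState, only_prunable: bool = False) -> int:
    """Exact number of scalar parameters (weights, biases, norm scale/shift).

    With ``only_prunable`` the count is restricted to the filter banks (W) of
    prunable layers. Running statistics are buffers, not parameters.
    """
    total = 0
    for l, p in zip(model.spec.layers, model.params):
        if only_prunable:
            if l.prunable:
                total += p["W"].size
            continue
        for k in PARAM_KEYS:
            if k in p:
                total += p[k].size
    return total


def replace_head(model: ModelState, n_classes: int, seed: int) -> ModelState:
    """Swap the classifier head for a freshly initialized ``n_classes`` head.

    Every non-head parameter is carried over bit-exactly (same arrays).
    """
    def swap(spec: NetworkSpec) -> NetworkSpec:
        layers = list(spec.layers)
        layers[-1] = dataclasses.replace(layers[-1], out_filters=n_classes)
        return dataclasses.replace(spec, layers=tuple(layers), n_classes=n_classes)

    new_spec = swap(model.spec)
    rng = np.random.default_rng(seed)
    head = _init_layer(new_spec.layers[-1], 0, model.spec.hidden_dim, rng, model.dtype)
    params = list(model.params[:-1]) + [head]
    return ModelState(spec=new_spec, params=params,
                      cut_history=list(model.cut_history),
                      base_spec=swap(model.base_spec))


# ---------------------------------------------------------------------------
# Checkpoints: zip archive of spec.yaml + named .npy tensors + cut_history
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: NetworkSpec) -> dict:
    return {
        "layers": [dataclasses.asdict(l) for l in spec.layers],
        "hidden_dim": spec.hidden_dim, "n_classes": spec.n_classes,
        "in_channels": spec.in_channels, "input_size": spec.input_size,
        "global_pool": spec.global_pool,
        "blocks": [list(b) for b in spec.blocks],
    }


def _spec_from_dict(d: dict) -> NetworkSpec:
    layers = tuple(LayerSpec(**ld) for ld in d["layers"])
    return NetworkSpec(layers=layers, hidden_dim=d["hidden_dim"],
                       n_classes=d["n_classes"], in_channels=d["in_channels"],
                       input_size=d["input_size"], global_pool=d["global_pool"],
                       blocks=tuple(tuple(b) for b in d["blocks"]))


def save_checkpoint(model: ModelState, path) -> None:
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("spec.yaml", yaml.safe_dump(_spec_to_dict(model.spec)))
        zf.writestr("base_spec.yaml", yaml.safe_dump(_spec_to_dict(model.base_spec)))
        zf.writestr("cut_history.json", json.dumps(
            [[int(t), [int(i) for i in idx]] for t, idx in model.cut_history]))
        for i, p in enumerate(model.params):
            for k, v in p.items():
                buf = io.BytesIO()
                np.save(buf, v)
                zf.writestr(f"params/{i:03d}.{k}.npy", buf.getvalue())


def load_checkpoint(path) -> ModelState:
    with zipfile.ZipFile(path, "r") as zf:
        spec = _spec_from_dict(yaml.safe_load(zf.read("spec.yaml")))
        base = _spec_from_dict(yaml.safe_load(zf.read("base_spec.yaml")))
        hist = [(t, list(idx)) for t, idx in json.loads(zf.read("cut_history.json"))]
        params: List[Dict[str, np.ndarray]] = [dict() for _ in spec.layers]
        for name in zf.namelist():
            if not name.startswith("params/"):
                continue
            stem = name[len("params/"):-len(".npy")]
            idx_s, key = stem.split(".", 1)
            params[int(idx_s)][key] = np.load(io.BytesIO(zf.read(name)))
    return ModelState(spec=spec, params=params, cut_history=hist, base_spec=base)
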