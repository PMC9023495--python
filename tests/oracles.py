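"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written with explicit Python loops and
``np.delete`` slicing so it shares no code path with the package's im2col
engine or its structural-removal logic.
"""

import numpy as np

BN_EPS = 1e-5


def loop_conv(x, W, b, stride, pad):
    """Explicit-loop cross-correlation for one image (CHW)."""
    cin, h, w = x.shape
    cout, _, k, _ = W.shape
    xp = np.zeros((cin, h + 2 * pad, w + 2 * pad), dtype=np.float64)
    xp[:, pad:pad + h, pad:pad + w] = x
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    out = np.zeros((cout, ho, wo))
    for o in range(cout):
        for i in range(ho):
            for j in range(wo):
                patch = xp[:, i * stride:i * stride + k, j * stride:j * stride + k]
                out[o, i, j] = np.sum(patch * W[o])
        if b is not None:
            out[o] += b[o]
    return out


def bn_eval(x, gamma, beta, rmean, rvar):
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        out[c] = (x[c] - rmean[c]) / np.sqrt(rvar[c] + BN_EPS) * gamma[c] + beta[c]
    return out


def plain_net_reference_map(layer_params, x, upto):
    """Forward a sequential conv net by explicit loops; return the post-norm
    pre-activation map of layer ``upto`` (the reference map definition)."""
    h = x.astype(np.float64)
    for li, p in enumerate(layer_params):
        h = loop_conv(h, p["W"], p.get("b"), p["stride"], p["pad"])
        if "gamma" in p:
            h = bn_eval(h, p["gamma"], p["beta"], p["running_mean"], p["running_var"])
        if li == upto:
            return h
        if p.get("activation", "relu") == "relu":
            h = np.maximum(h, 0.0)
    raise ValueError("upto beyond network depth")


def brute_force_filter_scores(layer_params, images, t):
    """Physically rebuild the net minus each filter of layer ``t`` and
    recompute the reference map of layer t+1 by explicit-loop convolution."""
    ref = t + 1
    m = len(images)
    c_t = layer_params[t]["W"].shape[0]
    base = [plain_net_reference_map(layer_params, x, ref) for x in images]
    scores = {}
    for i in range(c_t):
        cut = []
        for li, p in enumerate(layer_params):
            q = dict(p)
            if li == t:
                for key in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                    if key in q and q[key] is not None:
                        q[key] = np.delete(q[key], i, axis=0)
            if li == ref:
                q["W"] = np.delete(q["W"], i, axis=1)
            cut.append(q)
        total = 0.0
        for x, f0 in zip(images, base):
            fi = plain_net_reference_map(cut, x, ref)
            total += float(np.sum((fi - f0) ** 2))
        scores[i] = total / m
    return scores


def model_to_layer_params(model, n_layers):
    """Export the first ``n_layers`` trunk layers into the oracle's format."""
    out = []
    for i in range(n_layers):
        l = model.spec.layers[i]
        p = model.params[i]
        d = {"W": p["W"].astype(np.float64),
             "b": p["b"].astype(np.float64) if "b" in p else None,
             "stride": l.stride, "pad": l.pad, "activation": l.activation}
        if l.has_norm:
            for key in ("gamma", "beta", "running_mean", "running_var"):
                d[key] = p[key].astype(np.float64)
        out.append(d)
    return out
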