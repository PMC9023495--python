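"""Low-level tensor operations with explicit forward/backward pairs.

All spatial tensors are NCHW. Each ``*_forward`` returns ``(out, cache)``;
the matching ``*_backward`` consumes ``cache`` and the upstream gradient and
returns gradients for every input. Convolutions use im2col + BLAS matmul;
the col2im scatter in the backward pass loops only over the k*k kernel
offsets, so everything heavy stays vectorized.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d_forward", "conv2d_backward",
    "dwconv2d_forward", "dwconv2d_backward",
    "batchnorm_forward", "batchnorm_backward",
    "relu_forward", "relu_backward",
    "dense_forward", "dense_backward",
    "global_avg_pool_forward", "global_avg_pool_backward",
    "softmax", "cross_entropy",
]

BN_EPS = 1e-5


def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d_forward(x, W, b, stride=1, pad=0):
    """Cross-correlation of ``x`` (N,Cin,H,W) with filters ``W`` (Cout,Cin,k,k)."""
    N, Cin, H, Wd = x.shape
    Cout, Cin_w, k, _ = W.shape
    if Cin != Cin_w:
        raise ValueError(f"input has {Cin} channels, filters expect {Cin_w}")
    if k == 1:  # pointwise: a channel matmul, no im2col needed
        xs = x[:, :, ::stride, ::stride]
        out = np.tensordot(W[:, :, 0, 0], xs, axes=([1], [1])).transpose(1, 0, 2, 3)
        if b is not None:
            out = out + b[None, :, None, None]
        return np.ascontiguousarray(out), (x.shape, xs, W, b is not None, stride, pad)
    xp = _pad2d(x, pad)
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (Wd + 2 * pad - k) // stride + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, Cin * k * k)
    out = cols @ W.reshape(Cout, -1).T
    if b is not None:
        out = out + b
    out = np.ascontiguousarray(out.reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2))
    cache = (x.shape, cols, W, b is not None, stride, pad)
    return out, cache


def conv2d_backward(dout, cache):
    xshape, cols, W, has_bias, stride, pad = cache
    N, Cin, H, Wd = xshape
    Cout, _, k, _ = W.shape
    if k == 1:
        xs = cols  # the (strided) input was cached directly
        dW = np.tensordot(dout, xs, axes=([0, 2, 3], [0, 2, 3]))[:, :, None, None]
        db = dout.sum(axis=(0, 2, 3)) if has_bias else None
        dxs = np.tensordot(W[:, :, 0, 0].T, dout, axes=([1], [1])).transpose(1, 0, 2, 3)
        if stride == 1:
            return np.ascontiguousarray(dxs), dW, db
        dx = np.zeros(xshape, dtype=dout.dtype)
        dx[:, :, ::stride, ::stride] = dxs
        return dx, dW, db
    Ho, Wo = dout.shape[2], dout.shape[3]
    dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, Cout)
    dW = (dmat.T @ cols).reshape(W.shape)
    db = dmat.sum(axis=0) if has_bias else None
    dcols = (dmat @ W.reshape(Cout, -1)).reshape(N, Ho, Wo, Cin, k, k)
    dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((N, Cin, H + 2 * pad, Wd + 2 * pad), dtype=dout.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + Ho * stride:stride,
                kj:kj + Wo * stride:stride] += dcols[:, :, :, :, ki, kj]
    dx = dxp[:, :, pad:pad + H, pad:pad + Wd] if pad else dxp
    return dx, dW, db


def dwconv2d_forward(x, W, b, stride=1, pad=0):
    """Depthwise conv: one k*k filter per channel, ``W`` is (C,1,k,k)."""
    N, C, H, Wd = x.shape
    if W.shape[0] != C:
        raise ValueError(f"depthwise filters for {W.shape[0]} channels, input has {C}")
    k = W.shape[2]
    xp = _pad2d(x, pad)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.einsum("nchwij,cij->nchw", win, W[:, 0], optimize=True)
    if b is not None:
        out = out + b[None, :, None, None]
    cache = (x.shape, win, W, b is not None, stride, pad)
    return out, cache


def dwconv2d_backward(dout, cache):
    xshape, win, W, has_bias, stride, pad = cache
    N, C, H, Wd = xshape
    k = W.shape[2]
    Ho, Wo = dout.shape[2], dout.shape[3]
    dW = np.einsum("nchw,nchwij->cij", dout, win, optimize=True)[:, None]
    db = dout.sum(axis=(0, 2, 3)) if has_bias else None
    dxp = np.zeros((N, C, H + 2 * pad, Wd + 2 * pad), dtype=dout.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + Ho * stride:stride,
                kj:kj + Wo * stride:stride] += dout * W[:, 0, ki, kj][None, :, None, None]
    dx = dxp[:, :, pad:pad + H, pad:pad + Wd] if pad else dxp
    return dx, dW, db


def batchnorm_forward(x, gamma, beta, running_mean, running_var,
                      training, momentum=0.9, eps=BN_EPS):
    """Channel-wise batch normalization on NCHW input.

    In training mode batch statistics are used and the running buffers are
    updated in place (``running <- momentum*running + (1-momentum)*batch``);
    in evaluation mode the running statistics are used, making the forward
    pass deterministic.
    """
    if training:
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mu
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    cache = (xhat, gamma, inv_std, training)
    return out, cache


def batchnorm_backward(dout, cache):
    xhat, gamma, inv_std, training = cache
    dgamma = (dout * xhat).sum(axis=(0, 2, 3))
    dbeta = dout.sum(axis=(0, 2, 3))
    g = gamma[None, :, None, None] * inv_std[None, :, None, None]
    if not training:
        return dout * g, dgamma, dbeta
    m = dout.shape[0] * dout.shape[2] * dout.shape[3]
    mean_dout = dout.mean(axis=(0, 2, 3))[None, :, None, None]
    mean_dout_xhat = (dout * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
    dx = g * (dout - mean_dout - xhat * mean_dout_xhat)
    return dx, dgamma, dbeta


def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout, mask):
    return dout * mask


def dense_forward(x, W, b):
    """Fully-connected layer; 4D input is flattened per sample first."""
    xf = x.reshape(x.shape[0], -1)
    if xf.shape[1] != W.shape[1]:
        raise ValueError(f"dense input dim {xf.shape[1]} != weight dim {W.shape[1]}")
    out = xf @ W.T
    if b is not None:
        out = out + b
    return out, (x.shape, xf, W, b is not None)


def dense_backward(dout, cache):
    xshape, xf, W, has_bias = cache
    dW = dout.T @ xf
    db = dout.sum(axis=0) if has_bias else None
    dx = (dout @ W).reshape(xshape)
    return dx, dW, db


def global_avg_pool_forward(x):
    N, C, H, W = x.shape
    return x.mean(axis=(2, 3)), (x.shape,)


def global_avg_pool_backward(dout, cache):
    (xshape,) = cache
    N, C, H, W = xshape
    return np.broadcast_to(dout[:, :, None, None] / (H * W), xshape).astype(dout.dtype).copy()


def softmax(logits):
    """Log-sum-exp stabilized softmax along axis 1."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits, labels):
    """Mean negative log-likelihood of integer ``labels`` (one-hot equivalent).

    Returns ``(loss, dlogits)`` where dlogits is the gradient of the MEAN loss.
    """
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(logsumexp - z[np.arange(n), labels]))
    probs = softmax(logits)
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits
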