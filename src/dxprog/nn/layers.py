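"""Functional layers with explicit forward caches and backward passes."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Convolution (same padding, stride 1) via sliding windows + GEMM
# ---------------------------------------------------------------------------

def _windows(x: np.ndarray, k: int) -> np.ndarray:
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # (B, C, H, W, k, k)
    return sliding_window_view(xp, (k, k), axis=(2, 3))


def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (B,C,H,W); W: (O,C,k,k); returns out (B,O,H,W) and cache."""
    B, C, H, Wd = x.shape
    O, _, k, _ = W.shape
    win = _windows(x, k)
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * Wd, C * k * k)
    out = col @ W.reshape(O, -1).T + b
    out = out.reshape(B, H, Wd, O).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), (col, x.shape, W.shape)


def conv2d_backward(dout: np.ndarray, W: np.ndarray, cache):
    col, x_shape, w_shape = cache
    B, C, H, Wd = x_shape
    O, _, k, _ = w_shape
    dmat = dout.transpose(0, 2, 3, 1).reshape(B * H * Wd, O)
    dW = (dmat.T @ col).reshape(w_shape)
    db = dmat.sum(axis=0)
    # dx = correlation of dout with channel-swapped, spatially flipped kernels
    Wf = W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, k, k)
    win = _windows(dout, k)
    colg = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * Wd, O * k * k)
    dx = colg @ Wf.reshape(C, -1).T
    dx = dx.reshape(B, H, Wd, C).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(dx), dW, db


def avgpool2_forward(x: np.ndarray):
    B, C, H, W = x.shape
    out = x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    return out, x.shape


def avgpool2_backward(dout: np.ndarray, x_shape):
    B, C, H, W = x_shape
    dx = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
    return dx[:, :, :H, :W]


def global_avgpool_forward(x: np.ndarray):
    return x.mean(axis=(2, 3)), x.shape


def global_avgpool_backward(dout: np.ndarray, x_shape):
    B, C, H, W = x_shape
    return np.broadcast_to(dout[:, :, None, None], x_shape) / (H * W)


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, out


def relu_backward(dout: np.ndarray, out: np.ndarray):
    return dout * (out > 0)


def linear_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W.T + b, x


def linear_backward(dout: np.ndarray, W: np.ndarray, x: np.ndarray):
    return dout @ W, dout.T @ x, dout.sum(axis=0)


# ---------------------------------------------------------------------------
# Losses (return loss value and gradient w.r.t. logits)
# ---------------------------------------------------------------------------

def softmax_ce_loss(logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None):
    """Mean (optionally class-weighted) cross-entropy over the batch."""
    B = logits.shape[0]
    p = softmax(logits)
    nll = -np.log(np.clip(p[np.arange(B), labels], 1e-12, None))
    onehot = np.zeros_like(p)
    onehot[np.arange(B), labels] = 1.0
    if class_weights is None:
        w = np.ones(B)
    else:
        w = class_weights[labels]
    wsum = w.sum()
    loss = float((w * nll).sum() / wsum)
    dlogits = (p - onehot) * (w / wsum)[:, None]
    return loss, dlogits


def bce_logit_loss(logits: np.ndarray, labels: np.ndarray):
    """Mean binary cross-entropy on a single-logit head."""
    z = logits.ravel()
    y = labels.astype(float)
    # stable log(1 + exp(-|z|)) formulation
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / len(z)
    return loss, dz.reshape(logits.shape)


# ---------------------------------------------------------------------------
# Batch augmentation: horizontal flips, small rotations, random crop+resize
# ---------------------------------------------------------------------------

def augment_batch(
    x: np.ndarray,
    rng: np.random.Generator,
    max_rotation_deg: float = 10.0,
    crop_scale: float = 0.9,
    flip_prob: float = 0.5,
) -> np.ndarray:
    """Random per-image affine (flip/rotate/crop-zoom) with bilinear resampling.

    x: (B, H, W) float images; returns a new array of the same shape.
    """
    B, H, W = x.shape
    theta = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg, size=B))
    flip = rng.random(B) < flip_prob
    # random crop window between crop_scale and 2-crop_scale of the image
    # (zoom jitter centered at identity so train/test scales match), at a
    # random offset, resized back to the input size
    scale = rng.uniform(crop_scale, 2.0 - crop_scale, size=B)
    max_off = (1.0 - crop_scale) / 2.0 * np.array([H, W])
    off = rng.uniform(-1.0, 1.0, size=(B, 2)) * max_off

    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    ys, xs = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float), indexing="ij")
    yc, xc = ys - cy, xs - cx

    cos, sin = np.cos(theta), np.sin(theta)
    sx = np.where(flip, -1.0, 1.0)
    # input coords = R(theta) @ diag(scale) @ (flip) @ output coords + offset
    a11 = scale * cos
    a12 = -scale * sin * sx
    a21 = scale * sin
    a22 = scale * cos * sx
    src_y = a11[:, None, None] * yc + a12[:, None, None] * xc + cy + off[:, 0, None, None]
    src_x = a21[:, None, None] * yc + a22[:, None, None] * xc + cx + off[:, 1, None, None]

    y0 = np.clip(np.floor(src_y).astype(int), 0, H - 2)
    x0 = np.clip(np.floor(src_x).astype(int), 0, W - 2)
    fy = np.clip(src_y - y0, 0.0, 1.0)
    fx = np.clip(src_x - x0, 0.0, 1.0)
    bidx = np.arange(B)[:, None, None]
    p00 = x[bidx, y0, x0]
    p01 = x[bidx, y0, x0 + 1]
    p10 = x[bidx, y0 + 1, x0]
    p11 = x[bidx, y0 + 1, x0 + 1]
    top = p00 * (1 - fx) + p01 * fx
    bot = p10 * (1 - fx) + p11 * fx
    return (top * (1 - fy) + bot * fy).astype(x.dtype)
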