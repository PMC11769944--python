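"""Minimal functional neural-network toolkit on top of ``autograd``.

Layers are pure functions of ``(params, x)`` where ``params`` is a nested
dict of numpy arrays; gradients are obtained with :func:`autograd.value_and_grad`
over the whole dict.  Everything runs in float32 — on a single CPU the
models here are GEMM-bound and float32 roughly doubles throughput.

Convolutions are implemented as an explicit shift-and-concatenate im2col
followed by one 2-D GEMM, which is the fastest formulation autograd can
differentiate (its matmul VJP is itself a GEMM).
"""

from __future__ import annotations

import numpy as np
import autograd.numpy as anp
from autograd.extend import primitive, defvjp
from autograd.misc import flatten

DTYPE = np.float32


# ---------------------------------------------------------------------------
# gradient plumbing
# ---------------------------------------------------------------------------

@primitive
def stop_gradient(x):
    """Identity with zero gradient (straight-through building block)."""
    return x


defvjp(stop_gradient, lambda ans, x: lambda g: np.zeros_like(g))


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def conv_init(rng: np.random.Generator, c_in: int, c_out: int, kernel: int) -> dict:
    """He-uniform weights stored pre-flattened as (c_out, c_in*kernel).

    Kernel size is recovered at call time from the weight shape and the
    input channel count, so the param dict holds only trainable arrays.
    """
    fan_in = c_in * kernel
    bound = np.sqrt(1.0 / fan_in)
    w = rng.uniform(-bound, bound, size=(c_out, c_in * kernel))
    return {"w": w.astype(DTYPE), "b": np.zeros(c_out, dtype=DTYPE)}


def linear_init(rng: np.random.Generator, n_in: int, n_out: int) -> dict:
    bound = np.sqrt(1.0 / n_in)
    w = rng.uniform(-bound, bound, size=(n_in, n_out))
    return {"w": w.astype(DTYPE), "b": np.zeros(n_out, dtype=DTYPE)}


def batchnorm_init(channels: int) -> dict:
    return {"gamma": np.ones(channels, dtype=DTYPE), "beta": np.zeros(channels, dtype=DTYPE)}


def lstm_init(rng: np.random.Generator, n_in: int, hidden: int) -> dict:
    bound = np.sqrt(1.0 / hidden)
    shape_i = (n_in, 4 * hidden)
    shape_h = (hidden, 4 * hidden)
    return {
        "w_i": rng.uniform(-bound, bound, size=shape_i).astype(DTYPE),
        "w_h": rng.uniform(-bound, bound, size=shape_h).astype(DTYPE),
        "b": np.zeros(4 * hidden, dtype=DTYPE),
    }


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kernel: int, dilation: int, padding: int):
    """x: (B, C, L) -> column matrix (C*K, B*L_out). Pure numpy."""
    batch, c_in, _ = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    l_out = x.shape[2] - dilation * (kernel - 1)
    cols = np.empty((c_in * kernel, batch, l_out), dtype=x.dtype)
    for i in range(kernel):
        tap = x[:, :, i * dilation : i * dilation + l_out]
        cols[i * c_in : (i + 1) * c_in] = np.transpose(tap, (1, 0, 2))
    return cols.reshape(c_in * kernel, batch * l_out), l_out


@primitive
def _conv1d_gemm(w, b, x, dilation=1, padding=0, relu=False):
    """Forward of a 1-D convolution as one GEMM; VJPs are GEMMs too.

    w: (C_out, C_in*K); x: (B, C_in, L) -> (B, C_out, L_out).
    A hand-written primitive keeps the autograd tape short — the generic
    slice/concatenate formulation spends most of its time in np.add.at.
    ``relu`` optionally fuses the activation (backward masks on ans > 0).
    """
    batch, c_in, _ = x.shape
    kernel = w.shape[1] // c_in
    cols, l_out = _im2col(x, kernel, dilation, padding)
    out = w @ cols + b[:, None]
    out = np.ascontiguousarray(
        out.reshape(w.shape[0], batch, l_out).transpose(1, 0, 2))
    if relu:
        np.maximum(out, 0.0, out=out)
    return out


def _conv1d_vjp_w(ans, w, b, x, dilation=1, padding=0, relu=False):
    def vjp(g):
        if relu:
            g = g * (ans > 0)
        batch, c_in, _ = x.shape
        kernel = w.shape[1] // c_in
        cols, l_out = _im2col(x, kernel, dilation, padding)
        g2 = g.transpose(1, 0, 2).reshape(w.shape[0], batch * l_out)
        return g2 @ cols.T
    return vjp


def _conv1d_vjp_b(ans, w, b, x, dilation=1, padding=0, relu=False):
    def vjp(g):
        if relu:
            g = g * (ans > 0)
        return g.sum(axis=(0, 2))
    return vjp


def _conv1d_vjp_x(ans, w, b, x, dilation=1, padding=0, relu=False):
    def vjp(g):
        if relu:
            g = g * (ans > 0)
        batch, c_in, length = x.shape
        kernel = w.shape[1] // c_in
        l_out = g.shape[2]
        g2 = g.transpose(1, 0, 2).reshape(w.shape[0], batch * l_out)
        gcols = (w.T @ g2).reshape(c_in * kernel, batch, l_out)
        gx = np.zeros((batch, c_in, length + 2 * padding), dtype=x.dtype)
        for i in range(kernel):
            block = gcols[i * c_in : (i + 1) * c_in].transpose(1, 0, 2)
            gx[:, :, i * dilation : i * dilation + l_out] += block
        return gx[:, :, padding : padding + length] if padding else gx
    return vjp


defvjp(_conv1d_gemm, _conv1d_vjp_w, _conv1d_vjp_b, _conv1d_vjp_x)


@primitive
def unit_normalize(x, axis=1):
    """x / ||x||₂ along ``axis`` (with a small floor), as one taped op."""
    norm = np.sqrt(np.sum(x * x, axis=axis, keepdims=True) + 1e-12)
    return x / norm


def _unit_normalize_vjp(ans, x, axis=1):
    def vjp(g):
        norm = np.sqrt(np.sum(x * x, axis=axis, keepdims=True) + 1e-12)
        dot = np.sum(g * x, axis=axis, keepdims=True)
        return g / norm - x * dot / norm ** 3
    return vjp


defvjp(unit_normalize, _unit_normalize_vjp)


def conv1d(p: dict, x, dilation: int = 1, padding: int = 0):
    """1-D convolution.  x: (B, C_in, L) -> (B, C_out, L_out)."""
    return _conv1d_gemm(p["w"], p["b"], x, dilation=dilation, padding=padding)


def _im2col_grouped(x: np.ndarray, kernel: int, dilation: int, padding: int):
    """x: (B, H, C, L) -> (H, C*K, B*L_out)."""
    batch, heads, c_in, _ = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (0, 0), (padding, padding)))
    l_out = x.shape[3] - dilation * (kernel - 1)
    cols = np.empty((heads, c_in * kernel, batch * l_out), dtype=x.dtype)
    for i in range(kernel):
        tap = x[:, :, :, i * dilation : i * dilation + l_out]
        cols[:, i * c_in : (i + 1) * c_in, :] = (
            tap.transpose(1, 2, 0, 3).reshape(heads, c_in, batch * l_out))
    return cols, l_out


@primitive
def grouped_conv1d(w, b, x, dilation=1, padding=0, relu=False):
    """Per-group 1-D convolution in one batched GEMM.

    w: (H, C_out, C_in*K); b: (H, C_out); x: (B, H, C_in, L) ->
    (B, H, C_out, L_out).  Used to run many attention heads as one op.
    """
    batch, heads, c_in, _ = x.shape
    kernel = w.shape[2] // c_in
    cols, l_out = _im2col_grouped(x, kernel, dilation, padding)
    out = np.matmul(w, cols) + b[:, :, None]                # (H, C_out, B*L_out)
    c_out = w.shape[1]
    out = np.ascontiguousarray(
        out.reshape(heads, c_out, batch, l_out).transpose(2, 0, 1, 3))
    if relu:
        np.maximum(out, 0.0, out=out)
    return out


def _gconv_vjp_w(ans, w, b, x, dilation=1, padding=0, relu=False):
    def vjp(g):
        if relu:
            g = g * (ans > 0)
        batch, heads, c_in, _ = x.shape
        kernel = w.shape[2] // c_in
        cols, l_out = _im2col_grouped(x, kernel, dilation, padding)
        g2 = g.transpose(1, 2, 0, 3).reshape(heads, w.shape[1], batch * l_out)
        return np.matmul(g2, cols.transpose(0, 2, 1))
    return vjp


def _gconv_vjp_b(ans, w, b, x, dilation=1, padding=0, relu=False):
    def vjp(g):
        if relu:
            g = g * (ans > 0)
        return g.sum(axis=(0, 3))
    return vjp


def _gconv_vjp_x(ans, w, b, x, dilation=1, padding=0, relu=False):
    def vjp(g):
        if relu:
            g = g * (ans > 0)
        batch, heads, c_in, length = x.shape
        kernel = w.shape[2] // c_in
        l_out = g.shape[3]
        g2 = g.transpose(1, 2, 0, 3).reshape(heads, w.shape[1], batch * l_out)
        gcols = np.matmul(w.transpose(0, 2, 1), g2)         # (H, C_in*K, B*L_out)
        gx = np.zeros((batch, heads, c_in, length + 2 * padding), dtype=x.dtype)
        for i in range(kernel):
            block = gcols[:, i * c_in : (i + 1) * c_in, :]
            block = block.reshape(heads, c_in, batch, l_out).transpose(2, 0, 1, 3)
            gx[:, :, :, i * dilation : i * dilation + l_out] += block
        return gx[:, :, :, padding : padding + length] if padding else gx
    return vjp


defvjp(grouped_conv1d, _gconv_vjp_w, _gconv_vjp_b, _gconv_vjp_x)


def linear(p: dict, x):
    return anp.dot(x, p["w"]) + p["b"]


def batchnorm1d(p: dict, x, eps: float = 1e-5):
    """Normalise each channel over (batch, length).

    Uses the statistics of whatever batch it is given, in training and in
    evaluation alike; deterministic evaluation therefore feeds the full
    evaluation set in one batch.
    """
    mean = anp.mean(x, axis=(0, 2), keepdims=True)
    var = anp.var(x, axis=(0, 2), keepdims=True)
    xhat = (x - mean) / anp.sqrt(var + eps)
    return xhat * p["gamma"][None, :, None] + p["beta"][None, :, None]


def relu(x):
    return anp.maximum(x, 0.0)


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def softmax(x, axis=-1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def maxpool1d(x, kernel: int = 2):
    """Non-overlapping max pooling along the band axis (floor division)."""
    batch, channels, length = x.shape
    l_out = length // kernel
    x = x[:, :, : l_out * kernel]
    return anp.max(anp.reshape(x, (batch, channels, l_out, kernel)), axis=3)


@primitive
def _avgpool_nonoverlap(x, kernel=2, padding=0):
    """Non-overlapping average pooling (stride == kernel), one taped op."""
    batch, channels, _ = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    l_out = (x.shape[2] - kernel) // kernel + 1
    x = x[:, :, : l_out * kernel]
    return x.reshape(batch, channels, l_out, kernel).mean(axis=3)


def _avgpool_vjp_x(ans, x, kernel=2, padding=0):
    def vjp(g):
        batch, channels, length = x.shape
        gx = np.zeros((batch, channels, length + 2 * padding), dtype=x.dtype)
        l_out = g.shape[2]
        spread = np.repeat(g / kernel, kernel, axis=2)
        gx[:, :, : l_out * kernel] = spread
        return gx[:, :, padding : padding + length] if padding else gx
    return vjp


defvjp(_avgpool_nonoverlap, _avgpool_vjp_x)


def avgpool1d(x, kernel: int, stride: int, padding: int = 0):
    batch, channels, _ = x.shape
    if stride == kernel:
        return _avgpool_nonoverlap(x, kernel=kernel, padding=padding)
    if padding:
        zeros = anp.zeros((batch, channels, padding), dtype=DTYPE)
        x = anp.concatenate([zeros, x, zeros], axis=2)
    length = x.shape[2]
    l_out = (length - kernel) // stride + 1
    windows = [x[:, :, i * stride : i * stride + kernel] for i in range(l_out)]
    stacked = anp.stack(windows, axis=2)                       # (B, C, L_out, K)
    return anp.mean(stacked, axis=3)


def upsample_nearest(x, target_length: int):
    """Nearest-neighbour x2 upsampling, then crop / edge-pad to target_length."""
    up = anp.repeat(x, 2, axis=2)
    length = up.shape[2]
    if length > target_length:
        return up[:, :, :target_length]
    if length < target_length:
        pad = anp.repeat(up[:, :, -1:], target_length - length, axis=2)
        return anp.concatenate([up, pad], axis=2)
    return up


def lstm(p: dict, x):
    """Unidirectional LSTM over axis 1.  x: (B, L, n_in) -> (B, L, hidden)."""
    batch, steps, _ = x.shape
    hidden = p["w_h"].shape[0]
    h = anp.zeros((batch, hidden), dtype=DTYPE)
    c = anp.zeros((batch, hidden), dtype=DTYPE)
    x_proj = anp.dot(x, p["w_i"]) + p["b"]      # all input projections at once
    outs = []
    for t in range(steps):
        gates = x_proj[:, t, :] + anp.dot(h, p["w_h"])
        sig = sigmoid(gates[:, : 2 * hidden])
        i_g = sig[:, :hidden]
        f_g = sig[:, hidden:]
        g_g = anp.tanh(gates[:, 2 * hidden : 3 * hidden])
        o_g = sigmoid(gates[:, 3 * hidden :])
        c = f_g * c + i_g * g_g
        h = o_g * anp.tanh(c)
        outs.append(h)
    return anp.stack(outs, axis=1)


def dropout(x, rate: float, rng: np.random.Generator | None, train: bool):
    if not train or rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(np.shape(x)) >= rate).astype(DTYPE)
    return x * keep / DTYPE(1.0 - rate)


# ---------------------------------------------------------------------------
# parameter utilities
# ---------------------------------------------------------------------------

def count_parameters(params) -> int:
    """Total number of trainable scalar parameters in a nested param dict."""
    total = 0
    if isinstance(params, dict):
        for val in params.values():
            total += count_parameters(val)
    elif isinstance(params, (list, tuple)):
        for val in params:
            total += count_parameters(val)
    elif isinstance(params, np.ndarray):
        total += params.size
    return total


def tree_map(fn, params):
    if isinstance(params, dict):
        return {k: tree_map(fn, v) for k, v in params.items()}
    if isinstance(params, (list, tuple)):
        return type(params)(tree_map(fn, v) for v in params)
    if isinstance(params, np.ndarray):
        return fn(params)
    return params


# ---------------------------------------------------------------------------
# optimiser: rectified Adam with decoupled-from-loss L2 (added to gradient)
# ---------------------------------------------------------------------------

class RAdam:
    """Rectified Adam (Liu et al. 2020) on a flattened parameter vector."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        flat, self._unflatten = flatten(params)
        self.theta = flat.astype(np.float64)
        self.m = np.zeros_like(self.theta)
        self.v = np.zeros_like(self.theta)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.rho_inf = 2.0 / (1.0 - self.beta2) - 1.0

    @property
    def params(self):
        return tree_map(lambda a: a, self._unflatten(self.theta.astype(DTYPE)))

    def step(self, grads, lr: float | None = None):
        g, _ = flatten(grads)
        g = g.astype(np.float64)
        if self.weight_decay:
            g = g + self.weight_decay * self.theta
        self.t += 1
        lr = self.lr if lr is None else lr
        self.m = self.beta1 * self.m + (1.0 - self.beta1) * g
        self.v = self.beta2 * self.v + (1.0 - self.beta2) * g * g
        m_hat = self.m / (1.0 - self.beta1 ** self.t)
        beta2_t = self.beta2 ** self.t
        rho = self.rho_inf - 2.0 * self.t * beta2_t / (1.0 - beta2_t)
        if rho > 4.0:
            v_hat = np.sqrt(self.v / (1.0 - beta2_t))
            r = np.sqrt(((rho - 4.0) * (rho - 2.0) * self.rho_inf)
                        / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho))
            self.theta = self.theta - lr * r * m_hat / (v_hat + self.eps)
        else:
            self.theta = self.theta - lr * m_hat


def cyclic_lr(epoch: int, base_lr: float = 1e-4, max_lr: float = 1e-3,
              cycle_epochs: int = 50) -> float:
    """Triangular cyclic learning rate, one full cycle per ``cycle_epochs``."""
    half = cycle_epochs / 2.0
    pos = epoch % cycle_epochs
    frac = pos / half if pos <= half else (cycle_epochs - pos) / half
    return base_lr + (max_lr - base_lr) * frac
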