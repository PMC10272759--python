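"""Minimal reverse-mode automatic differentiation on numpy arrays.

The two network architectures in this package (a 1D U-Net and a three-branch
CNN/LSTM regressor) are small enough that a tape-based autodiff over a dozen
fused array operations is both sufficient and fast: every operation lowers to
BLAS matmuls or cheap elementwise kernels on float32 arrays.  Gradients are
accumulated by a reverse topological sweep over the recorded graph.

Only the operations the models need are implemented; each op's backward rule
is hand-derived and covered by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """A node in the computation graph: a value, its gradient, and a backward rule."""

    __slots__ = ("data", "grad", "_parents", "_backward", "name")

    def __init__(self, data, parents=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, name={self.name!r})"

    def backward(self):
        """Accumulate gradients of this (scalar) tensor w.r.t. every ancestor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Convenience operator sugar (used sparingly in model code).
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(DTYPE, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2D matrix product (M,K) @ (K,N)."""
    out = Tensor(a.data @ b.data, (a, b))

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))

    def backward(g):
        _accum(a, g * mask)

    out._backward = backward
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, (a,))

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    out._backward = backward
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, (a,))

    def backward(g):
        _accum(a, g * (1.0 - t * t))

    out._backward = backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), (a,))

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    out._backward = backward
    return out


def concat(tensors, axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    out._backward = backward
    return out


def slice_axis(a: Tensor, axis: int, start: int, size: int) -> Tensor:
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + size)
    idx = tuple(idx)
    out = Tensor(a.data[idx], (a,))

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        _accum(a, full)

    out._backward = backward
    return out


def select_time(a: Tensor, t: int) -> Tensor:
    """Pick timestep t from a (B, T, C) tensor -> (B, C)."""
    out = Tensor(a.data[:, t, :], (a,))

    def backward(g):
        full = np.zeros_like(a.data)
        full[:, t, :] = g
        _accum(a, full)

    out._backward = backward
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 1D convolution.

    x: (B, T, Cin), w: (K, Cin, F), b: (F,) -> (B, T, F).  K must be odd.
    """
    B, T, Cin = x.data.shape
    K, Cin_w, F = w.data.shape
    if Cin_w != Cin:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    # patches: (B, T, K*Cin) via K shifted views
    patches = np.stack([xp[:, k : k + T, :] for k in range(K)], axis=2)
    pm = patches.reshape(B * T, K * Cin)
    wm = w.data.reshape(K * Cin, F)
    out = Tensor((pm @ wm + b.data).reshape(B, T, F), (x, w, b))

    def backward(g):
        gm = g.reshape(B * T, F)
        _accum(w, (pm.T @ gm).reshape(K, Cin, F))
        _accum(b, gm.sum(axis=0))
        gp = (gm @ wm.T).reshape(B, T, K, Cin)
        gxp = np.zeros_like(xp)
        for k in range(K):
            gxp[:, k : k + T, :] += gp[:, :, k, :]
        _accum(x, gxp[:, pad : pad + T, :])

    out._backward = backward
    return out


def _im2col2d(xp: np.ndarray, Ho: int, Wo: int, KH: int, KW: int,
              sh: int = 1, sw: int = 1) -> np.ndarray:
    """Patch matrix (B*Ho*Wo, KH*KW*C) from a padded (B, Hp, Wp, C) array."""
    B, _, _, C = xp.shape
    patches = np.empty((B, Ho, Wo, KH * KW, C), dtype=xp.dtype)
    n = 0
    for i in range(KH):
        for j in range(KW):
            patches[:, :, :, n, :] = \
                xp[:, i : i + sh * Ho : sh, j : j + sw * Wo : sw, :]
            n += 1
    return patches.reshape(B * Ho * Wo, KH * KW * C)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: tuple = (1, 1)) -> Tensor:
    """Same-padded 2D convolution with optional stride.

    x: (B, H, W, Cin), w: (KH, KW, Cin, F), b: (F,) ->
    (B, ceil(H/sh), ceil(W/sw), F).  At stride 1 the input gradient is a
    convolution of the output gradient with the spatially flipped,
    transposed kernel (one GEMM); strided backward scatters per kernel
    offset.
    """
    B, H, W_, Cin = x.data.shape
    KH, KW, Cin_w, F = w.data.shape
    sh, sw = stride
    if Cin_w != Cin:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    ph, pw = KH // 2, KW // 2
    Ho = (H + sh - 1) // sh
    Wo = (W_ + sw - 1) // sw
    # pad so every strided window fits
    ph2 = max(0, (Ho - 1) * sh + KH - ph - H)
    pw2 = max(0, (Wo - 1) * sw + KW - pw - W_)
    xp = np.pad(x.data, ((0, 0), (ph, ph2), (pw, pw2), (0, 0)))
    pm = _im2col2d(xp, Ho, Wo, KH, KW, sh, sw)
    wm = w.data.reshape(KH * KW * Cin, F)
    out = Tensor((pm @ wm + b.data).reshape(B, Ho, Wo, F), (x, w, b))

    def backward(g):
        gm = g.reshape(B * Ho * Wo, F).astype(DTYPE, copy=False)
        _accum(w, (pm.T @ gm).reshape(KH, KW, Cin, F))
        _accum(b, gm.sum(axis=0))
        if (sh, sw) == (1, 1):
            # dx = conv(g, flip(W)^T): full correlation, flipped kernel
            w_flip = w.data[::-1, ::-1].transpose(0, 1, 3, 2)
            gp = np.pad(g.astype(DTYPE, copy=False),
                        ((0, 0), (ph, ph), (pw, pw), (0, 0)))
            gcol = _im2col2d(gp, H, W_, KH, KW)
            _accum(x, (gcol @ w_flip.reshape(KH * KW * F, Cin)
                       ).reshape(B, H, W_, Cin))
        else:
            gp = (gm @ wm.T).reshape(B, Ho, Wo, KH * KW, Cin)
            gxp = np.zeros_like(xp)
            n = 0
            for i in range(KH):
                for j in range(KW):
                    gxp[:, i : i + sh * Ho : sh, j : j + sw * Wo : sw, :] += \
                        gp[:, :, :, n, :]
                    n += 1
            _accum(x, gxp[:, ph : ph + H, pw : pw + W_, :])

    out._backward = backward
    return out


def maxpool1d(x: Tensor, pool: int = 2) -> Tensor:
    """Non-overlapping max pooling along the time axis of (B, T, C).

    Backward routes each gradient to the first position attaining the max
    within its pooling cell.
    """
    B, T, C = x.data.shape
    if T % pool:
        raise ValueError(f"time axis {T} not divisible by pool {pool}")
    r = x.data.reshape(B, T // pool, pool, C)
    m = r.max(axis=2)
    out = Tensor(m, (x,))

    def backward(g):
        gr = np.zeros_like(r)
        free = np.ones(m.shape, dtype=bool)
        for k in range(pool):
            hit = free & (r[:, :, k, :] == m)
            gr[:, :, k, :] = np.where(hit, g, 0.0)
            free &= ~hit
        _accum(x, gr.reshape(B, T, C))

    out._backward = backward
    return out


def maxpool2d(x: Tensor, pool: int = 2) -> Tensor:
    """Non-overlapping (pool x pool) max pooling on (B, H, W, C); trims remainders."""
    B, H, W_, C = x.data.shape
    Ho, Wo = H // pool, W_ // pool
    r = x.data[:, : Ho * pool, : Wo * pool, :].reshape(B, Ho, pool, Wo, pool, C)
    m = r.max(axis=(2, 4))
    out = Tensor(m, (x,))

    def backward(g):
        gr = np.zeros((B, Ho, pool, Wo, pool, C), dtype=x.data.dtype)
        free = np.ones(m.shape, dtype=bool)
        for i in range(pool):
            for j in range(pool):
                hit = free & (r[:, :, i, :, j, :] == m)
                gr[:, :, i, :, j, :] = np.where(hit, g, 0.0)
                free &= ~hit
        gx = np.zeros_like(x.data)
        gx[:, : Ho * pool, : Wo * pool, :] = gr.reshape(B, Ho * pool, Wo * pool, C)
        _accum(x, gx)

    out._backward = backward
    return out


def upsample1d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling along the time axis of (B, T, C)."""
    B, T, C = x.data.shape
    out = Tensor(np.repeat(x.data, factor, axis=1), (x,))

    def backward(g):
        _accum(x, g.reshape(B, T, factor, C).sum(axis=2))

    out._backward = backward
    return out


def layernorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis; gamma/beta have that axis's length."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, (x, gamma, beta))
    C = x.data.shape[-1]

    def backward(g):
        axes = tuple(range(g.ndim - 1))
        _accum(gamma, (g * xhat).sum(axis=axes))
        _accum(beta, g.sum(axis=axes))
        gx = g * gamma.data
        # standard layer-norm backward over the last axis
        gsum = gx.sum(axis=-1, keepdims=True)
        gdot = (gx * xhat).sum(axis=-1, keepdims=True)
        _accum(x, inv * (gx - gsum / C - xhat * gdot / C))

    out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy over all leading axes; returns (loss, probabilities).

    logits: (..., C); onehot: same shape, rows summing to 1.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=-1, keepdims=True)
    n = int(np.prod(logits.data.shape[:-1]))
    eps = 1e-12
    loss_val = -(onehot * np.log(p + eps)).sum() / n
    out = Tensor(loss_val, (logits,))

    def backward(g):
        _accum(logits, g * (p - onehot) / n)

    out._backward = backward
    return out, p


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - np.asarray(target, dtype=DTYPE)
    out = Tensor(np.mean(diff * diff), (pred,))

    def backward(g):
        _accum(pred, g * 2.0 * diff / diff.size)

    out._backward = backward
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    """Plain (non-graph) softmax over the last axis, for inference."""
    z = x - x.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def lstm_forward(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor,
                 return_sequences: bool = False) -> Tensor:
    """Fused unidirectional LSTM over (B, T, C) -> (B, H) or (B, T, H).

    Gate order in the packed kernels: input, forget, cell, output.  The
    whole sequence is one graph node with a hand-derived backward (BPTT),
    which keeps the graph small and the step loop in numpy.
    """
    B, T, C = x.data.shape
    H = wh.data.shape[0]
    xw = (x.data.reshape(B * T, C) @ wx.data).reshape(B, T, 4 * H) + b.data
    h = np.zeros((B, H), dtype=DTYPE)
    c = np.zeros((B, H), dtype=DTYPE)
    cache = []
    hs = np.empty((B, T, H), dtype=DTYPE)
    for t in range(T):
        z = xw[:, t] + h @ wh.data
        i = 1.0 / (1.0 + np.exp(-z[:, :H]))
        f = 1.0 / (1.0 + np.exp(-z[:, H:2 * H]))
        g = np.tanh(z[:, 2 * H:3 * H])
        o = 1.0 / (1.0 + np.exp(-z[:, 3 * H:]))
        c = f * c + i * g
        tc = np.tanh(c)
        cache.append((i, f, g, o, c, tc, h))  # h here is h_{t-1}
        h = o * tc
        hs[:, t] = h
    out = Tensor(hs if return_sequences else h, (x, wx, wh, b))

    def backward(grad):
        dwx = np.zeros_like(wx.data)
        dwh = np.zeros_like(wh.data)
        db = np.zeros_like(b.data)
        dx_rows = np.empty((B, T, 4 * H), dtype=DTYPE)
        dh = np.zeros((B, H), dtype=DTYPE)
        dc = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_t, tc, h_in = cache[t]
            dh_t = dh + (grad[:, t] if return_sequences else
                         (grad if t == T - 1 else 0.0))
            do = dh_t * tc
            dc = dc + dh_t * o * (1.0 - tc * tc)
            c_prev = cache[t - 1][4] if t > 0 else 0.0
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dx_rows[:, t] = dz
            dwh += h_in.T @ dz if t > 0 else 0.0
            # note: h_in stored in cache is the PREVIOUS h (input to step t)
            dh = dz @ wh.data.T
            dc = dc * f
        db += dx_rows.sum(axis=(0, 1))
        flat = dx_rows.reshape(B * T, 4 * H)
        dwx += x.data.reshape(B * T, C).T @ flat
        _accum(x, (flat @ wx.data.T).reshape(B, T, C))
        _accum(wx, dwx)
        _accum(wh, dwh)
        _accum(b, db)

    out._backward = backward
    return out
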