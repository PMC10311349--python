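"""Minimal reverse-mode autodiff engine and neural-network layers.

A small, self-contained tensor/autograd core sized exactly to the needs of
the panel-attention U-net in :mod:`panelhic.model`: stride-1 2D convolution,
2x2 max pooling, dropout, batch/layer normalization, nearest-neighbour
upsampling, softmax attention, and the AdamW and LARS-over-Adam optimizers.
Everything runs on numpy (float64) and is deliberately eager and explicit:
each op records its parents and a backward closure; ``backward()`` walks the
graph in reverse topological order.

Shapes follow the (batch, channels, height, width) convention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "conv2d",
    "relu",
    "maxpool2x2",
    "dropout",
    "batchnorm2d",
    "layernorm",
    "upsample2x",
    "concat_channels",
    "slice_batch",
    "flatten",
    "transpose2d",
    "matmul",
    "softmax_vec",
    "attend_combine",
    "add",
    "scale_mul",
    "rowwise_dot_stack",
    "concat_cols",
    "l1_masked",
    "info_nce",
    "info_nce_pairs",
    "AdamW",
    "LARS",
]


# ---------------------------------------------------------------------------
# Tensor core
# ---------------------------------------------------------------------------

class Tensor:
    """An ndarray plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    def __init__(self, data):
        super().__init__(data)


def _make(data, parents, backward):
    if any(p.requires_grad for p in parents):
        return Tensor(data, parents, backward)
    return Tensor(data, requires_grad=False)


# ---------------------------------------------------------------------------
# Convolution (stride 1, zero padding)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> (B,H,W,C*k*k) patch matrix for a stride-1 k x k conv."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) -> (B, H, W, C*k*k)
    b, c, h, w = x.shape[0], x.shape[1], win.shape[2], win.shape[3]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h, w, c * k * k)


def _conv_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, pad: int):
    """Forward conv; returns (out, cols) with cols cached for the backward."""
    f, c, k, _ = w.shape
    cols = _im2col(x, k, pad)
    out = cols @ w.reshape(f, c * k * k).T  # (B,H,W,F)
    if b is not None:
        out += b
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2)), cols


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, pad: int | None = None) -> Tensor:
    """Same-size stride-1 convolution. weight: (F, C, k, k), bias: (F,)."""
    f, c, k, _ = weight.shape
    if pad is None:
        pad = k // 2
    out, cols = _conv_raw(x.data, weight.data, bias.data if bias is not None else None, pad)

    def backward(g):
        gt = g.transpose(0, 2, 3, 1)  # (B,H,W,F)
        if weight.requires_grad:
            gw = np.tensordot(gt, cols, axes=([0, 1, 2], [0, 1, 2]))  # (F, C*k*k)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gt.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            # grad wrt input = full correlation with the flipped kernel
            wf = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,F,k,k)
            gx, _ = _conv_raw(g, wf, None, k - 1 - pad)
            x._accumulate(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, backward)


# ---------------------------------------------------------------------------
# Elementwise / structural ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return _make(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return _make(out, (a, b), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    r = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(b, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gr = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gx.reshape(b, c, h, w))

    return _make(out, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    out = x.data * keep

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return _make(out, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            b, c, h, w = x.shape
            gx = g.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5))
            x._accumulate(gx)

    return _make(out, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    out = np.concatenate([a.data, b.data], axis=1)
    ca = a.shape[1]

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])

    return _make(out, (a, b), backward)


def slice_batch(x: Tensor, start: int, stop: int | None) -> Tensor:
    sl = slice(start, stop)
    out = x.data[sl]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[sl] = g
            x._accumulate(gx)

    return _make(out, (x,), backward)


def flatten(x: Tensor) -> Tensor:
    shape = x.shape
    out = x.data.reshape(shape[0], -1)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(shape))

    return _make(out, (x,), backward)


def transpose2d(x: Tensor) -> Tensor:
    out = x.data.T.copy()

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.T)

    return _make(out, (x,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(out, (a, b), backward)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

_NORM_EPS = 1e-5


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
                training: bool, momentum: float = 0.1) -> Tensor:
    """Per-channel batch normalization over (B, H, W)."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        var = x.data.var(axis=(0, 2, 3), keepdims=True)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + _NORM_EPS)
    xhat = (x.data - mu) * inv
    g4 = gamma.data.reshape(1, -1, 1, 1)
    out = g4 * xhat + beta.data.reshape(1, -1, 1, 1)
    n = x.shape[0] * x.shape[2] * x.shape[3]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = g * g4
            if training:
                gx = inv / n * (n * gxh - gxh.sum(axis=(0, 2, 3), keepdims=True)
                                - xhat * (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True))
            else:
                gx = gxh * inv
            x._accumulate(gx)

    return _make(out, (x, gamma, beta), backward)


def layernorm(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """Per-sample normalization over (C, H, W) with per-channel affine."""
    mu = x.data.mean(axis=(1, 2, 3), keepdims=True)
    var = x.data.var(axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + _NORM_EPS)
    xhat = (x.data - mu) * inv
    g4 = gamma.data.reshape(1, -1, 1, 1)
    out = g4 * xhat + beta.data.reshape(1, -1, 1, 1)
    n = x.shape[1] * x.shape[2] * x.shape[3]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = g * g4
            gx = inv / n * (n * gxh - gxh.sum(axis=(1, 2, 3), keepdims=True)
                            - xhat * (gxh * xhat).sum(axis=(1, 2, 3), keepdims=True))
            x._accumulate(gx)

    return _make(out, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# Attention pieces
# ---------------------------------------------------------------------------

def softmax_vec(x: Tensor) -> Tensor:
    """Softmax over a flat vector (shape (n,) or (n,1))."""
    z = x.data.reshape(-1)
    e = np.exp(z - z.max())
    s = e / e.sum()

    def backward(g):
        if x.requires_grad:
            gv = g.reshape(-1)
            gx = s * (gv - (gv * s).sum())
            x._accumulate(gx.reshape(x.shape))

    return _make(s.reshape(x.shape), (x,), backward)


def attend_combine(alpha: Tensor, values: Tensor) -> Tensor:
    """out[1,c,h,w] = sum_n alpha[n] * values[n,c,h,w]."""
    a = alpha.data.reshape(-1)
    out = np.tensordot(a, values.data, axes=([0], [0]))[None]

    def backward(g):
        g0 = g[0]
        if alpha.requires_grad:
            ga = np.tensordot(values.data, g0, axes=([1, 2, 3], [0, 1, 2]))
            alpha._accumulate(ga.reshape(alpha.shape))
        if values.requires_grad:
            values._accumulate(a[:, None, None, None] * g0[None])

    return _make(out, (alpha, values), backward)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def l1_masked(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean absolute error over pixels where ``mask`` is True."""
    m = np.broadcast_to(mask, pred.shape)
    n = int(m.sum())
    if n == 0:
        raise ValueError("l1_masked: mask selects no pixels")
    diff = (pred.data - target) * m
    out = np.abs(diff).sum() / n

    def backward(g):
        if pred.requires_grad:
            pred._accumulate(g * np.sign(diff) * m / n)

    return _make(np.asarray(out), (pred,), backward)


def scale_mul(x: Tensor, c: float) -> Tensor:
    out = x.data * c

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * c)

    return _make(out, (x,), backward)


def rowwise_dot_stack(anchors: Tensor, items: Tensor) -> Tensor:
    """out[i, k] = <anchors[i], items[i, k]> for items of shape (B, K, M)."""
    out = np.einsum("im,ikm->ik", anchors.data, items.data)

    def backward(g):
        if anchors.requires_grad:
            anchors._accumulate(np.einsum("ik,ikm->im", g, items.data))
        if items.requires_grad:
            items._accumulate(np.einsum("ik,im->ikm", g, anchors.data))

    return _make(out, (anchors, items), backward)


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    out = np.concatenate([a.data, b.data], axis=1)
    ca = a.shape[1]

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])

    return _make(out, (a, b), backward)


def info_nce_pairs(sims: Tensor) -> Tensor:
    """Cross-entropy over a square similarity matrix with positives on the diagonal.

    Row i is anchor i against all positives in the batch; off-diagonal
    entries act as in-batch negatives (other regions).
    """
    z = sims.data
    b = z.shape[0]
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    out = np.mean(lse - np.diag(z))

    def backward(g):
        if sims.requires_grad:
            p = np.exp(z - zmax)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(b), np.arange(b)] -= 1.0
            sims._accumulate(g * p / b)

    return _make(np.asarray(out), (sims,), backward)


def info_nce(logits: Tensor) -> Tensor:
    """Cross-entropy with in-batch negatives; column 0 holds each anchor's positive.

    loss = mean_i [ logsumexp(logits_i) - logits_i[0] ]
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    out = np.mean(lse - z[:, 0])
    b = z.shape[0]

    def backward(g):
        if logits.requires_grad:
            p = np.exp(z - zmax)
            p /= p.sum(axis=1, keepdims=True)
            p[:, 0] -= 1.0
            logits._accumulate(g * p / b)

    return _make(np.asarray(out), (logits,), backward)


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class AdamW:
    """Decoupled weight-decay Adam (Loshchilov & Hutter)."""

    def __init__(self, params: dict[str, Parameter], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def _adam_direction(self, k: str, p: Parameter) -> np.ndarray:
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
        self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
        mhat = self.m[k] / (1 - self.b1 ** self.t)
        vhat = self.v[k] / (1 - self.b2 ** self.t)
        return mhat / (np.sqrt(vhat) + self.eps)

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            step = self._adam_direction(k, p)
            if self.weight_decay:
                step = step + self.weight_decay * p.data
            p.data -= self.lr * step


class LARS(AdamW):
    """Layer-wise adaptive rate scaling on top of Adam update directions.

    Each multi-dimensional parameter's update is rescaled by the trust ratio
    ||w|| / ||update|| (clipped above at ``max_trust``); one-dimensional
    parameters (biases, norm scales) are excluded from the adaptation and
    take the plain Adam step.
    """

    def __init__(self, params, lr=1e-3, max_trust=10.0, **kw):
        super().__init__(params, lr=lr, **kw)
        self.max_trust = max_trust

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            step = self._adam_direction(k, p)
            if self.weight_decay:
                step = step + self.weight_decay * p.data
            if p.data.ndim > 1:
                wn = np.linalg.norm(p.data)
                sn = np.linalg.norm(step)
                if wn > 0 and sn > 0:
                    step = step * min(wn / sn, self.max_trust)
            p.data -= self.lr * step
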