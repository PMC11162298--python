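"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the compute core for the dual-attention classifier: a small tensor
type with gradient tape, the handful of differentiable operations the network
needs (im2col convolutions, pooling, per-channel normalisation, softmax,
embedding lookup, dense layers), and an Adam optimiser.  Everything runs in float32 on
one CPU; determinism is guaranteed by seeding every stochastic operation from
an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "add", "mul", "matmul", "relu", "sigmoid", "softmax", "concat",
    "mean", "amax", "reshape", "dropout",
    "conv2d", "conv1d", "maxpool2d", "maxpool1d", "embedding",
    "bce_with_logits",
    "Module", "Conv2d", "Conv1d", "Linear", "ChannelNorm", "Embedding",
    "Adam",
]


# ---------------------------------------------------------------- tensor core

class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # the closures reference their output tensor, forming cycles that
        # keep whole batch graphs alive until a gc pass; break them now and
        # drop intermediate gradients (parameters keep theirs)
        for t in topo:
            t._backward = None
            t._parents = ()
            if not isinstance(t, Parameter) and t is not self:
                t.grad = None

    def free_graph(self):
        """Release a graph that will not be backpropagated (eval mode)."""
        stack, seen = [self], set()
        while stack:
            t = stack.pop()
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.extend(t._parents)
            t._backward = None
            t._parents = ()

    # convenience operators used when composing the model
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t, g):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ----------------------------------------------------------------- primitives

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, a.requires_grad or b.requires_grad, (a, b))

    def bwd():
        _accum(a, _unbroadcast(out.grad, a.shape))
        _accum(b, _unbroadcast(out.grad, b.shape))

    out._backward = bwd
    return out


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, a.requires_grad or b.requires_grad, (a, b))

    def bwd():
        _accum(a, _unbroadcast(out.grad * b.data, a.shape))
        _accum(b, _unbroadcast(out.grad * a.data, b.shape))

    out._backward = bwd
    return out


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, a.requires_grad or b.requires_grad, (a, b))

    def bwd():
        _accum(a, out.grad @ b.data.T)
        _accum(b, a.data.T @ out.grad)

    out._backward = bwd
    return out


def relu(x):
    x = _as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))

    def bwd():
        _accum(x, out.grad * (x.data > 0))

    out._backward = bwd
    return out


def _stable_sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(x):
    x = _as_tensor(x)
    y = _stable_sigmoid(x.data)
    out = Tensor(y, x.requires_grad, (x,))

    def bwd():
        _accum(x, out.grad * y * (1.0 - y))

    out._backward = bwd
    return out


def softmax(x, axis):
    """Softmax along ``axis``; weights along that axis sum to 1."""
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def bwd():
        g = out.grad
        _accum(x, y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = bwd
    return out


def reshape(x, shape):
    x = _as_tensor(x)
    out = Tensor(x.data.reshape(shape), x.requires_grad, (x,))

    def bwd():
        _accum(x, out.grad.reshape(x.shape))

    out._backward = bwd
    return out


def concat(tensors, axis=1):
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]

    def bwd():
        splits = np.cumsum(sizes[:-1])
        for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
            _accum(t, g)

    out._backward = bwd
    return out


def mean(x, axis, keepdims=False):
    x = _as_tensor(x)
    axis = tuple(axis) if isinstance(axis, (tuple, list)) else (axis,)
    out = Tensor(x.data.mean(axis=axis, keepdims=keepdims),
                 x.requires_grad, (x,))
    n = int(np.prod([x.shape[a] for a in axis]))

    def bwd():
        g = out.grad
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(x, np.broadcast_to(g, x.shape) / n)

    out._backward = bwd
    return out


def amax(x, axis, keepdims=False):
    """Max reduction; gradient flows to (all tied) argmax positions."""
    x = _as_tensor(x)
    axis = tuple(axis) if isinstance(axis, (tuple, list)) else (axis,)
    m = x.data.max(axis=axis, keepdims=True)
    out = Tensor(m if keepdims else np.squeeze(m, axis),
                 x.requires_grad, (x,))

    def bwd():
        g = out.grad
        if not keepdims:
            g = np.expand_dims(g, axis)
        mask = (x.data == m)
        mask = mask / mask.sum(axis=axis, keepdims=True)
        _accum(x, np.broadcast_to(g, x.shape) * mask)

    out._backward = bwd
    return out


def dropout(x, rate, rng):
    """Inverted dropout; pass rate 0 (or call in eval mode) for identity."""
    x = _as_tensor(x)
    if rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float32) / (1.0 - rate)
    out = Tensor(x.data * keep, x.requires_grad, (x,))

    def bwd():
        _accum(x, out.grad * keep)

    out._backward = bwd
    return out


def embedding(table, idx):
    """Row lookup: table (V, D) indexed by integer array idx (N, L) -> (N, L, D)."""
    table = _as_tensor(table)
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(table.data[idx], table.requires_grad, (table,))

    def bwd():
        g = np.zeros_like(table.data)
        np.add.at(g, idx.ravel(), out.grad.reshape(-1, table.shape[1]))
        _accum(table, g)

    out._backward = bwd
    return out


# -------------------------------------------------------------- convolutions

def _im2col2d(x, k, pad):
    """(N,C,H,W) -> (N, C*k*k, H*W) columns, channels-first (no transposes)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
    return cols.reshape(n, c * k * k, h * w)


def conv2d(x, w, b):
    """Same-padded 2-D convolution: x (N,C,H,W), w (F,C,k,k), b (F,)."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    n, c, h, wd = x.shape
    f, _, k, _ = w.shape
    pad = k // 2
    cols = _im2col2d(x.data, k, pad)                   # (N, C*k*k, H*W)
    w2 = w.data.reshape(f, -1)
    y = np.matmul(w2[None], cols)                      # (N, F, H*W)
    y += b.data[None, :, None]
    out = Tensor(y.reshape(n, f, h, wd),
                 x.requires_grad or w.requires_grad or b.requires_grad,
                 (x, w, b))

    def bwd():
        g = out.grad.reshape(n, f, h * wd)
        _accum(b, g.sum(axis=(0, 2)))
        _accum(w, np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
               .reshape(w.shape))
        if x.requires_grad:
            dcols = np.matmul(w2.T[None], g).reshape(n, c, k, k, h, wd)
            dxp = np.zeros((n, c, h + 2 * pad, wd + 2 * pad), dtype=np.float32)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + h, j:j + wd] += dcols[:, :, i, j]
            _accum(x, dxp[:, :, pad:pad + h, pad:pad + wd])

    out._backward = bwd
    return out


def conv1d(x, w, b):
    """Same-padded 1-D convolution: x (N,C,L), w (F,C,k), b (F,)."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    n, c, l = x.shape
    f, _, k = w.shape
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    cols = np.empty((n, c, k, l), dtype=np.float32)
    for i in range(k):
        cols[:, :, i] = xp[:, :, i:i + l]
    cols = cols.reshape(n, c * k, l)
    w2 = w.data.reshape(f, -1)
    y = np.matmul(w2[None], cols)
    y += b.data[None, :, None]
    out = Tensor(y,
                 x.requires_grad or w.requires_grad or b.requires_grad,
                 (x, w, b))

    def bwd():
        g = out.grad
        _accum(b, g.sum(axis=(0, 2)))
        _accum(w, np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
               .reshape(w.shape))
        if x.requires_grad:
            dcols = np.matmul(w2.T[None], g).reshape(n, c, k, l)
            dxp = np.zeros((n, c, l + 2 * pad), dtype=np.float32)
            for i in range(k):
                dxp[:, :, i:i + l] += dcols[:, :, i]
            _accum(x, dxp[:, :, pad:pad + l])

    out._backward = bwd
    return out


def maxpool2d(x):
    """2x2 / stride-2 max pooling (even H, W)."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def bwd():
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], out.grad[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _accum(x, dx.reshape(n, c, h, w))

    out._backward = bwd
    return out


def maxpool1d(x):
    """Pool of 2 / stride 2 along the last axis (even L)."""
    x = _as_tensor(x)
    n, c, l = x.shape
    flat = x.data.reshape(n, c, l // 2, 2)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def bwd():
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], out.grad[..., None], axis=-1)
        _accum(x, dflat.reshape(n, c, l))

    out._backward = bwd
    return out


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    logits = _as_tensor(logits)
    z = logits.data
    y = np.asarray(targets, dtype=np.float32).reshape(z.shape)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), logits.requires_grad, (logits,))

    def bwd():
        p = 1.0 / (1.0 + np.exp(-z))
        _accum(logits, out.grad * (p - y) / z.size)

    out._backward = bwd
    return out


# --------------------------------------------------------------------- layers

class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, flag):
        for m in self.modules():
            m.training = flag

    training = True


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, c_in, c_out, k=3):
        self.w = Parameter(_he_init(rng, (c_out, c_in, k, k), c_in * k * k))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x):
        return conv2d(x, self.w, self.b)


class Conv1d(Module):
    def __init__(self, rng, c_in, c_out, k=3):
        self.w = Parameter(_he_init(rng, (c_out, c_in, k), c_in * k))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x):
        return conv1d(x, self.w, self.b)


class Linear(Module):
    def __init__(self, rng, d_in, d_out):
        self.w = Parameter(_he_init(rng, (d_in, d_out), d_in))
        self.b = Parameter(np.zeros(d_out, dtype=np.float32))

    def __call__(self, x):
        return add(matmul(x, self.w), self.b)


class Embedding(Module):
    def __init__(self, rng, vocab, dim):
        self.table = Parameter(
            (rng.standard_normal((vocab, dim)) * 0.1).astype(np.float32))

    def __call__(self, idx):
        return embedding(self.table, idx)


class ChannelNorm(Module):
    """Per-sample, per-channel normalisation over the spatial axes.

    Each sample's channel is standardised over its own positions, then an
    affine (gamma, beta) restores expressiveness.  Unlike batch-statistic
    normalisation there is no train/eval gap and no running state, which
    keeps inference exactly deterministic and stable under the highly
    concentrated activations the spatial-attention softmax produces.
    """

    def __init__(self, channels, eps=1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.eps = eps

    def __call__(self, x):
        x = _as_tensor(x)
        axes = tuple(range(2, x.data.ndim))       # spatial axes only
        shape = [1, x.shape[1]] + [1] * (x.data.ndim - 2)
        m = x.data.mean(axis=axes, keepdims=True)
        v = x.data.var(axis=axes, keepdims=True)
        inv = (1.0 / np.sqrt(v + self.eps)).astype(np.float32)
        xhat = (x.data - m) * inv
        out = Tensor(xhat * self.gamma.data.reshape(shape)
                     + self.beta.data.reshape(shape),
                     True, (x, self.gamma, self.beta))
        ch_axes = (0,) + axes

        def bwd():
            g = out.grad
            _accum(self.gamma, (g * xhat).sum(axis=ch_axes))
            _accum(self.beta, g.sum(axis=ch_axes))
            if not x.requires_grad:
                return
            gx = g * self.gamma.data.reshape(shape)
            _accum(x, inv * (gx
                             - gx.mean(axis=axes, keepdims=True)
                             - xhat * (gx * xhat).mean(axis=axes, keepdims=True)))

        out._backward = bwd
        return out


# ------------------------------------------------------------------ optimiser

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
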