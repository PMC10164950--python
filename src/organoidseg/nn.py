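"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the compute substrate for the segmentation network: tensors in
NCHW layout, stride-1 'same' convolutions (spatial resizing is done by
explicit 2x2 max-pooling and bilinear-resize ops, as in nested-U
encoder-decoders), batch normalisation, dropout and an SGD optimiser.
Every op defines its own backward pass; correctness is pinned by
finite-difference gradient tests in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# global state: gradient mode and the RNG used by stochastic layers
# ---------------------------------------------------------------------------

GRAD_ENABLED = True
GLOBAL_RNG = np.random.default_rng(0)


def set_global_seed(seed: int) -> None:
    """Reseed every source of randomness used by the nn layer.

    After this call, layer initialisation performed with ``new_rng()`` and
    dropout draws are bit-reproducible.
    """
    global GLOBAL_RNG
    GLOBAL_RNG = np.random.default_rng(int(seed))


def new_rng(seed: int | None = None) -> np.random.Generator:
    if seed is None:
        return GLOBAL_RNG
    return np.random.default_rng(int(seed))


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global GRAD_ENABLED
        self._prev = GRAD_ENABLED
        GRAD_ENABLED = False

    def __exit__(self, *exc):
        global GRAD_ENABLED
        GRAD_ENABLED = self._prev
        return False


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph --------------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- convenience arithmetic (scalar and tensor) -------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -other)

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division not supported")
        return mul(self, 1.0 / other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _accumulate(t: Tensor, g: np.ndarray):
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad = t.grad + g


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul(a, b):
    if not isinstance(b, Tensor):
        a = _as_tensor(a)
        c = float(b)
        return _node(a.data * c, (a,), lambda g: _accumulate(a, g * c))
    a = _as_tensor(a)

    def bwd(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return _node(x.data * mask, (x,), lambda g: _accumulate(x, g * mask))


def sigmoid(x: Tensor) -> Tensor:
    xd = x.data
    e = np.exp(-np.abs(xd))
    s = np.where(xd >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    return _node(s, (x,), lambda g: _accumulate(x, g * s * (1.0 - s)))


def log(x: Tensor) -> Tensor:
    return _node(np.log(x.data), (x,), lambda g: _accumulate(x, g / x.data))


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values to [lo, hi]; gradient is zero outside the interval."""
    inside = (x.data > lo) & (x.data < hi)
    return _node(np.clip(x.data, lo, hi), (x,), lambda g: _accumulate(x, g * inside))


def tsum(x: Tensor) -> Tensor:
    return _node(
        np.asarray(x.data.sum()),
        (x,),
        lambda g: _accumulate(x, np.broadcast_to(g, x.data.shape).astype(x.data.dtype)),
    )


def tmean(x: Tensor) -> Tensor:
    n = x.data.size
    return _node(
        np.asarray(x.data.mean()),
        (x,),
        lambda g: _accumulate(x, np.broadcast_to(g / n, x.data.shape).astype(x.data.dtype)),
    )


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape
    return _node(x.data.reshape(shape), (x,), lambda g: _accumulate(x, g.reshape(orig)))


def channel_slice(x: Tensor, start: int, stop: int) -> Tensor:
    out = x.data[:, start:stop]

    def bwd(g):
        gx = np.zeros_like(x.data)
        gx[:, start:stop] = g
        _accumulate(x, gx)

    return _node(out, (x,), bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, s0, s1 in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(s0, s1)
            _accumulate(t, g[tuple(sl)])

    return _node(out, tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# spatial ops (NCHW)
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Stride-1 'same' 2D convolution, NCHW.

    Implemented as k*k shifted 1x1 matmuls — fast under BLAS and trivially
    differentiable without an im2col buffer.
    """
    B, Ci, H, W = x.data.shape
    O, Ci2, kh, kw = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"conv2d channel mismatch: input {Ci}, weight expects {Ci2}")
    d = int(dilation)
    ph, pw = d * (kh // 2), d * (kw // 2)
    if ph or pw:
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    else:
        xp = x.data
    out = np.zeros((B, O, H * W), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i * d : i * d + H, j * d : j * d + W].reshape(B, Ci, H * W)
            out += w.data[:, :, i, j] @ xs
    out = out.reshape(B, O, H, W)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)

    def bwd(g):
        gs = g.reshape(B, O, H * W)
        if b is not None:
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad or x._parents
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i * d : i * d + H, j * d : j * d + W].reshape(B, Ci, H * W)
                gw[:, :, i, j] = np.tensordot(gs, xs, axes=([0, 2], [0, 2]))
                if need_x:
                    gxp[:, :, i * d : i * d + H, j * d : j * d + W] += (
                        w.data[:, :, i, j].T @ gs
                    ).reshape(B, Ci, H, W)
        _accumulate(w, gw)
        if need_x:
            if ph or pw:
                _accumulate(x, gxp[:, :, ph : ph + H, pw : pw + W])
            else:
                _accumulate(x, gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, bwd)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2, ceil mode (odd edges padded with -inf)."""
    B, C, H, W = x.data.shape
    H2, W2 = (H + 1) // 2, (W + 1) // 2
    xd = x.data
    if H % 2 or W % 2:
        xd = np.pad(
            xd,
            ((0, 0), (0, 0), (0, 2 * H2 - H), (0, 2 * W2 - W)),
            constant_values=-np.inf,
        )
    win = xd.reshape(B, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, 2 * H2, 2 * W2
        )
        _accumulate(x, gx[:, :, :H, :W])

    return _node(out, (x,), bwd)


_RESIZE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1D bilinear interpolation matrix (align_corners=False)."""
    key = (n_in, n_out)
    m = _RESIZE_CACHE.get(key)
    if m is None:
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        src = np.clip(src, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        w1 = src - i0
        m = np.zeros((n_out, n_in))
        m[np.arange(n_out), i0] += 1.0 - w1
        m[np.arange(n_out), i1] += w1
        _RESIZE_CACHE[key] = m
    return m


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize (align_corners=False), NCHW."""
    B, C, H, W = x.data.shape
    if (H, W) == (out_h, out_w):
        return _node(x.data.copy(), (x,), lambda g: _accumulate(x, g))
    mh = _interp_matrix(H, out_h).astype(x.data.dtype)
    mw = _interp_matrix(W, out_w).astype(x.data.dtype)
    out = np.matmul(np.matmul(mh, x.data), mw.T)

    def bwd(g):
        _accumulate(x, np.matmul(np.matmul(mh.T, g), mw))

    return _node(out, (x,), bwd)


def upsample2(x: Tensor) -> Tensor:
    _, _, H, W = x.data.shape
    return resize_bilinear(x, 2 * H, 2 * W)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC mean over the spatial extent."""
    B, C, H, W = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def bwd(g):
        _accumulate(
            x, np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape).astype(x.data.dtype)
        )

    return _node(out, (x,), bwd)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x: (B, I); w: (O, I); b: (O,)."""
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data

    def bwd(g):
        _accumulate(x, g @ w.data)
        _accumulate(w, g.T @ x.data)
        if b is not None:
            _accumulate(b, g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, bwd)


def dropout(x: Tensor, p: float, training: bool, rng: np.random.Generator | None = None) -> Tensor:
    if not training or p <= 0:
        return x
    if p >= 1:
        raise ValueError("dropout probability must be < 1")
    rng = rng if rng is not None else GLOBAL_RNG
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return _node(x.data * keep, (x,), lambda g: _accumulate(x, g * keep))


def scale_channels(x: Tensor, a: Tensor) -> Tensor:
    """Multiply NCHW map ``x`` by per-channel weights ``a`` of shape (B, C)."""
    aa = a.data[:, :, None, None]
    out = x.data * aa

    def bwd(g):
        _accumulate(x, g * aa)
        _accumulate(a, (g * x.data).sum(axis=(2, 3)))

    return _node(out, (x, a), bwd)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    """Bare-bones layer container with recursive parameter discovery."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_parameters(f"{full}.{i}.")

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield from v.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # checkpoint support ----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.mean"] = m.running_mean.copy()
                state[f"__bn{i}.var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            src = state[name]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {src.shape} vs {p.data.shape}")
            p.data = src.copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"__bn{i}.mean"].copy()
                m.running_var = state[f"__bn{i}.var"].copy()


def _he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, k=3, dilation=1, bias=True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng if rng is not None else GLOBAL_RNG
        self.dilation = dilation
        self.weight = Tensor(
            _he_uniform(rng, (out_ch, in_ch, k, k), in_ch * k * k, dtype), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, ch, eps=1e-5, momentum=0.1, dtype=np.float32):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(ch, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=np.float64)
        self.running_var = np.ones(ch, dtype=np.float64)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.data.shape
        gamma, beta = self.gamma, self.beta
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            n = B * H * W
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean = self.running_mean.astype(x.data.dtype)
            var = self.running_var.astype(x.data.dtype)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) * invstd[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        training = self.training

        def bwd(g):
            _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            _accumulate(beta, g.sum(axis=(0, 2, 3)))
            dxhat = g * gamma.data[None, :, None, None]
            if training:
                n = B * H * W
                t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (invstd[None, :, None, None] / n) * (n * dxhat - t1 - xhat * t2)
            else:
                gx = dxhat * invstd[None, :, None, None]
            _accumulate(x, gx.astype(x.data.dtype))

        return _node(out.astype(x.data.dtype), (x, gamma, beta), bwd)


class Linear(Module):
    def __init__(self, in_f, out_f, rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng if rng is not None else GLOBAL_RNG
        self.weight = Tensor(_he_uniform(rng, (out_f, in_f), in_f, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 decay."""

    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data = p.data + v
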