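"""Minimal numpy CNN engine: reverse-mode autodiff, layers, and Adam.

This module provides exactly what the segmentation networks need —
2-D (grouped/depthwise) convolution, batch normalisation, pooling,
nearest-neighbour upsampling, elementwise activations, concatenation,
softmax and masked cross-entropy — each with an analytic backward pass,
plus a torch-like ``Module`` tree so architectures can be introspected
structurally (parameter counts, block censuses, per-stage freezing).

Conventions
-----------
* Activations are ``(N, C, H, W)`` float arrays ("NCHW").
* A :class:`Parameter` is a leaf tensor with a ``trainable`` flag;
  freezing a stage sets ``trainable = requires_grad = False`` on its
  parameters, which both excludes them from optimiser updates and
  prunes the backward pass through that subgraph.
* All randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "Parameter", "Module", "Sequential", "ModuleList",
    "Conv2d", "BatchNorm2d", "ReLU", "SiLU", "Sigmoid", "Identity",
    "MaxPool2d", "UpsampleNearest2d", "AvgPool3x3", "avg_pool2d_3x3s1",
    "add", "mul", "concat", "relu", "silu", "sigmoid", "softmax",
    "global_avg_pool", "upsample_nearest2x", "conv2d", "batch_norm2d",
    "max_pool2d", "softmax_cross_entropy", "soft_dice_loss",
    "Adam", "SGD",
]


# ---------------------------------------------------------------------------
# Autodiff core
# ---------------------------------------------------------------------------

class Tensor:
    """A node in the computation tape.

    ``backward_fn`` receives the upstream gradient and returns one
    gradient array (or ``None``) per parent, in parent order.
    """

    __slots__ = ("data", "grad", "requires_grad", "parents", "backward_fn")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward_fn: Callable | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self.parents = parents
        self.backward_fn = backward_fn

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this node through the tape."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node.backward_fn is None or node.grad is None:
                continue
            grads = node.backward_fn(node.grad)
            for parent, g in zip(node.parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=False)
                else:
                    parent.grad = parent.grad + g
            if node.backward_fn is not None and node.parents:
                node.grad = None  # free intermediate gradients promptly

    def zero_grad(self) -> None:
        self.grad = None


class Parameter(Tensor):
    """A learnable leaf tensor."""

    __slots__ = ("trainable", "name")

    def __init__(self, data, name: str = ""):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        self.trainable = True
        self.name = name

    def freeze(self) -> None:
        self.trainable = False
        self.requires_grad = False

    def unfreeze(self) -> None:
        self.trainable = True
        self.requires_grad = True


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad for t in tensors)


def _make(data, parents, backward_fn) -> Tensor:
    req = _needs_grad(*parents)
    return Tensor(data, requires_grad=req, parents=tuple(parents),
                  backward_fn=backward_fn if req else None)


# ---------------------------------------------------------------------------
# Elementwise / shape ops
# ---------------------------------------------------------------------------

def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def bw(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _make(out, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def bw(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), bw)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(out, tuple(ts), bw)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = x.data * mask

    def bw(g):
        return (g * mask,)

    return _make(out, (x,), bw)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    s = _stable_sigmoid(x.data)

    def bw(g):
        return (g * s * (1.0 - s),)

    return _make(s, (x,), bw)


def silu(x: Tensor) -> Tensor:
    """x * sigmoid(x) (a.k.a. swish), the EfficientNet activation."""
    x = _as_tensor(x)
    s = _stable_sigmoid(x.data)
    out = x.data * s

    def bw(g):
        return (g * (s + x.data * s * (1.0 - s)),)

    return _make(out, (x,), bw)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        return (p * (g - dot),)

    return _make(p, (x,), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over H and W, keeping dims: (N,C,H,W) -> (N,C,1,1)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3), keepdims=True)

    def bw(g):
        return (np.broadcast_to(g / (h * w), x.data.shape).copy(),)

    return _make(out, (x,), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        n, c, h2, w2 = g.shape
        return (g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)),)

    return _make(out, (x,), bw)


# ---------------------------------------------------------------------------
# Convolution (grouped; groups=C gives depthwise)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, groups: int):
    """Return grouped column matrix (g, N*Ho*Wo, cg*kh*kw) for padded ``x``."""
    n, c, _, _ = x.shape
    cg = c // groups
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (N, C, Ho, Wo, kh, kw)
    ho, wo = win.shape[2], win.shape[3]
    win = win.reshape(n, groups, cg, ho, wo, kh, kw)
    cols = win.transpose(1, 0, 3, 4, 2, 5, 6).reshape(
        groups, n * ho * wo, cg * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _conv_fwd(x: np.ndarray, w: np.ndarray, stride: int, padding: int,
              groups: int) -> np.ndarray:
    """Plain correlation forward (no tape). w: (Co, C/g, kh, kw)."""
    co, _, kh, kw = w.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    n = x.shape[0]
    cols, ho, wo = _im2col(x, kh, kw, stride, groups)
    wmat = w.reshape(groups, co // groups, -1)
    out = cols @ wmat.transpose(0, 2, 1)          # (g, N*Ho*Wo, co/g)
    out = out.reshape(groups, n, ho, wo, co // groups)
    return np.ascontiguousarray(out.transpose(1, 0, 4, 2, 3)).reshape(
        n, co, ho, wo)


def _conv_input_grad(g: np.ndarray, w: np.ndarray, x_shape, stride: int,
                     padding: int, groups: int) -> np.ndarray:
    """Gradient w.r.t. the conv input, via the transposed convolution."""
    n, c, h, wdt = x_shape
    co, cg, kh, kw = w.shape
    ho, wo = g.shape[2], g.shape[3]
    if stride > 1:  # dilate the output gradient
        gd = np.zeros((n, co, (ho - 1) * stride + 1, (wo - 1) * stride + 1),
                      dtype=g.dtype)
        gd[:, :, ::stride, ::stride] = g
    else:
        gd = g
    # flip kernels spatially and swap in/out channels within each group
    wg = w.reshape(groups, co // groups, cg, kh, kw)
    wt = wg.transpose(0, 2, 1, 3, 4)[:, :, :, ::-1, ::-1]
    wt = np.ascontiguousarray(wt.reshape(groups * cg, co // groups, kh, kw))
    full = _conv_fwd(gd, wt, stride=1, padding=max(kh, kw) - 1, groups=groups)
    # full covers positions 0 .. (Ho-1)*s + kh - 1 of the padded input
    hp, wp = h + 2 * padding, wdt + 2 * padding
    dxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
    eh = min(hp, full.shape[2])
    ew = min(wp, full.shape[3])
    dxp[:, :, :eh, :ew] = full[:, :, :eh, :ew]
    if padding:
        return dxp[:, :, padding:hp - padding, padding:wp - padding]
    return dxp


def conv2d(x: Tensor, w: Parameter, b: Parameter | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    x = _as_tensor(x)
    co, cg, kh, kw = w.data.shape
    if x.data.shape[1] != cg * groups:
        raise ValueError(
            f"conv2d: input has {x.data.shape[1]} channels, "
            f"weight expects {cg * groups}")
    out = _conv_fwd(x.data, w.data, stride, padding, groups)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        n = x.data.shape[0]
        ho, wo = g.shape[2], g.shape[3]
        dx = dw = db = None
        if x.requires_grad:
            dx = _conv_input_grad(g, w.data, x.data.shape, stride, padding,
                                  groups)
        if w.requires_grad:
            xp = x.data
            if padding:
                xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding),
                                 (padding, padding)))
            cols, _, _ = _im2col(xp, kh, kw, stride, groups)
            gt = g.reshape(n, groups, co // groups, ho, wo)
            gt = gt.transpose(1, 0, 3, 4, 2).reshape(groups, n * ho * wo,
                                                     co // groups)
            dw = np.einsum("gkc,gkf->gcf", gt, cols,
                           optimize=True).reshape(co, cg, kh, kw)
        if b is not None and b.requires_grad:
            db = g.sum(axis=(0, 2, 3))
        if b is None:
            return dx, dw
        return dx, dw, db

    return _make(out, parents, bw)


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None,
               padding: int = 0) -> Tensor:
    x = _as_tensor(x)
    stride = stride or kernel
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding)),
                    constant_values=-np.inf)
    n, c, hp, wp = xd.shape
    win = sliding_window_view(xd, (kernel, kernel),
                              axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
        ki, kj = np.divmod(idx, kernel)
        oi = np.arange(ho)[None, None, :, None] * stride
        oj = np.arange(wo)[None, None, None, :] * stride
        ri = (oi + ki).ravel()
        rj = (oj + kj).ravel()
        ni = np.repeat(np.arange(n), c * ho * wo)
        ci = np.tile(np.repeat(np.arange(c), ho * wo), n)
        np.add.at(dxp, (ni, ci, ri, rj), g.ravel())
        if padding:
            return (dxp[:, :, padding:hp - padding, padding:wp - padding],)
        return (dxp,)

    return _make(out, (x,), bw)


def _box_mean3(a: np.ndarray) -> np.ndarray:
    """3x3 box mean with zero padding (divisor fixed at 9); self-adjoint."""
    ap = np.pad(a, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(ap, (3, 3), axis=(2, 3))
    return win.mean(axis=(-2, -1))


def avg_pool2d_3x3s1(x: Tensor) -> Tensor:
    """3x3, stride-1, zero-padded average pooling (inception pool branch)."""
    x = _as_tensor(x)
    out = _box_mean3(x.data)

    def bw(g):
        return (_box_mean3(g),)

    return _make(out, (x,), bw)


# ---------------------------------------------------------------------------
# Batch normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Parameter, beta: Parameter,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-3) -> Tensor:
    x = _as_tensor(x)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) * invstd.reshape(1, -1, 1, 1)
    out = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)

    def bw(g):
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        dx = None
        if x.requires_grad:
            gs = g * gamma.data.reshape(1, -1, 1, 1)
            if training:
                t1 = gs.sum(axis=(0, 2, 3), keepdims=True)
                t2 = (gs * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (invstd.reshape(1, -1, 1, 1) / m) * (
                    m * gs - t1 - xhat * t2)
            else:
                dx = gs * invstd.reshape(1, -1, 1, 1)
        return dx, dgamma, dbeta

    return _make(out, (x, gamma, beta), bw)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          ignore: np.ndarray | None = None) -> Tensor:
    """Mean per-pixel cross-entropy over non-ignored pixels.

    ``logits``: (N, C, H, W); ``labels``: (N, H, W) integer class ids;
    ``ignore``: optional (N, H, W) boolean, True = excluded from the loss
    (zero gradient at those pixels).
    """
    logits = _as_tensor(logits)
    n, c, h, w = logits.data.shape
    labels = np.asarray(labels)
    valid = np.ones((n, h, w), dtype=bool) if ignore is None else ~np.asarray(ignore)
    count = int(valid.sum())
    if count == 0:
        raise ValueError("softmax_cross_entropy: every pixel is ignored")
    safe_labels = np.where(valid, labels, 0)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    picked = np.take_along_axis(z, safe_labels[:, None], axis=1)[:, 0]
    nll = (logsumexp - picked) * valid
    loss = nll.sum() / count

    def bw(g):
        p = np.exp(z - logsumexp[:, None])
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, safe_labels[:, None], 1.0, axis=1)
        dz = (p - onehot) * valid[:, None]
        return (g * dz / count,)

    return _make(np.asarray(loss, dtype=logits.dtype), (logits,), bw)


def soft_dice_loss(logits: Tensor, labels: np.ndarray,
                   ignore: np.ndarray | None = None,
                   eps: float = 1.0) -> Tensor:
    """1 - mean soft Dice over classes, non-ignored pixels only."""
    logits = _as_tensor(logits)
    n, c, h, w = logits.data.shape
    labels = np.asarray(labels)
    valid = np.ones((n, h, w), dtype=bool) if ignore is None else ~np.asarray(ignore)
    p = softmax(logits, axis=1)
    onehot = np.zeros((n, c, h, w), dtype=logits.dtype)
    safe = np.where(valid, labels, 0)
    np.put_along_axis(onehot, safe[:, None], 1.0, axis=1)
    onehot *= valid[:, None]
    pm = mul(p, Tensor(valid[:, None].astype(logits.dtype)))
    inter = mul(pm, Tensor(onehot))
    # dice_c = (2*sum(p*y) + eps) / (sum(p) + sum(y) + eps), averaged over c
    num = inter.data.sum(axis=(0, 2, 3)) * 2.0 + eps
    den = pm.data.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3)) + eps
    loss_val = 1.0 - (num / den).mean()

    def bw(g):
        # d loss / d p = -(1/C) * (2*y*den - (2*sum(p*y)+eps)) / den^2, masked
        dnum = 2.0 * onehot
        dp = -(dnum * den.reshape(1, -1, 1, 1)
               - num.reshape(1, -1, 1, 1)) / (den ** 2).reshape(1, -1, 1, 1)
        dp = dp / c * valid[:, None]
        return (g * dp,)

    grad_node = _make(np.asarray(loss_val, dtype=logits.dtype), (pm,), bw)
    return grad_node


# ---------------------------------------------------------------------------
# Module system
# ---------------------------------------------------------------------------

class Module:
    """Base class with torch-style child/parameter registration."""

    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, child in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def modules(self) -> Iterator["Module"]:
        for _, m in self.named_modules():
            yield m

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, mod in self.named_modules(prefix):
            for pname, p in mod._params.items():
                yield (f"{name}.{pname}" if name else pname), p

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    # -- mode / freezing ----------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.freeze()
        return self

    def unfreeze(self) -> "Module":
        for p in self.parameters():
            p.unfreeze()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialisation --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, mod in self.named_modules():
            if isinstance(mod, BatchNorm2d):
                key = f"{name}." if name else ""
                state[f"{key}running_mean"] = mod.running_mean.copy()
                state[f"{key}running_var"] = mod.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=np.float32).copy()
        for name, mod in self.named_modules():
            if isinstance(mod, BatchNorm2d):
                key = f"{name}." if name else ""
                if f"{key}running_mean" in state:
                    mod.running_mean[...] = state[f"{key}running_mean"]
                    mod.running_var[...] = state[f"{key}running_var"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._order = [str(i) for i in range(len(mods))]

    def __iter__(self):
        return (self._modules[k] for k in self._order)

    def __len__(self):
        return len(self._order)

    def __getitem__(self, i):
        return self._modules[self._order[i]]

    def forward(self, x):
        for key in self._order:
            x = self._modules[key](x)
        return x


class ModuleList(Module):
    def __init__(self, mods: Iterable[Module] = ()):
        super().__init__()
        self._order: list[str] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        key = str(len(self._order))
        setattr(self, key, m)
        self._order.append(key)
        return self

    def __iter__(self):
        return (self._modules[k] for k in self._order)

    def __len__(self):
        return len(self._order)

    def __getitem__(self, i):
        return self._modules[self._order[i]]

    def forward(self, *a, **k):  # pragma: no cover - container only
        raise NotImplementedError("ModuleList is a container")


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(1, fan_in)),
                      size=shape).astype(np.float32)


class Conv2d(Module):
    """2-D convolution; ``role`` tags main-path vs projection-shortcut convs
    so architecture censuses can distinguish them by traversal."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int | None = None,
                 groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 role: str = "conv"):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if in_ch % groups or out_ch % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.groups = kernel, stride, groups
        self.padding = kernel // 2 if padding is None else padding
        self.role = role
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Parameter(
            _he_init(rng, (out_ch, in_ch // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.groups)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-3):
        super().__init__()
        self.gamma = Parameter(np.ones(ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum,
                            self.eps)


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class SiLU(Module):
    def forward(self, x):
        return silu(x)


class Sigmoid(Module):
    def forward(self, x):
        return sigmoid(x)


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2, stride: int | None = None,
                 padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride or kernel, padding

    def forward(self, x):
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class UpsampleNearest2d(Module):
    def forward(self, x):
        return upsample_nearest2x(x)


class AvgPool3x3(Module):
    def forward(self, x):
        return avg_pool2d_3x3s1(x)


# ---------------------------------------------------------------------------
# Optimisers
# ---------------------------------------------------------------------------

class Adam:
    """Adam over the trainable parameters of a module."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if not p.trainable or p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGD:
    def __init__(self, params: Iterable[Parameter], lr: float = 1e-2,
                 momentum: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum = lr, momentum
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if not p.trainable or p.grad is None:
                continue
            self.v[i] = self.momentum * self.v[i] - self.lr * p.grad
            p.data = p.data + self.v[i]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
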