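"""Minimal reverse-mode automatic differentiation on numpy arrays.

A deliberately small CPU engine: dense float32 tensors, a handful of
elementwise/reduction ops, 2-D convolution via im2col + BLAS matmul,
nearest/bilinear upsampling, channel softmax, and an Adam optimizer with
per-parameter-group learning rates.  Everything is single-threaded
deterministic given seeded initialisation, which the training code relies
on for reproducible runs.

Conventions: image tensors are (B, C, H, W); gradients accumulate in
``Tensor.grad`` as float32 arrays of the same shape as ``data``.
"""

from __future__ import annotations

import numpy as np

try:  # compiled 3x3 conv kernels; the numpy im2col path is the fallback
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "InstanceNorm2d",
    "SelfAttention2d",
    "Adam",
    "relu",
    "leaky_relu",
    "tanh",
    "sigmoid",
    "softmax_channel",
    "conv2d",
    "upsample_nearest",
    "upsample_bilinear",
    "cat_channels",
    "concat_rows",
    "slice_rows",
    "no_grad",
]

_F32 = np.float32

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference paths)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(_F32, copy=False)
    return np.asarray(x, dtype=_F32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure that back-propagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = _GRAD_ENABLED and (
            bool(requires_grad) or any(p.requires_grad for p in parents)
        )
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(_as_array(grad))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, k: float):
        out_data = self.data**k

        def bwd(g):
            self._accum(g * k * self.data ** (k - 1))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape)
                )
            if other.requires_grad:
                other._accum(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape)
                )

        return Tensor(out_data, parents=(self, other), backward=bwd)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out_data = self.data.transpose(*axes)

        def bwd(g):
            self._accum(g.transpose(*inv))

        return Tensor(out_data, parents=(self,), backward=bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).astype(_F32))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g):
            self._accum(g / self.data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def abs(self):
        sign = np.sign(self.data)
        out_data = np.abs(self.data)

        def bwd(g):
            self._accum(g * sign)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def clamp(self, lo: float | None = None, hi: float | None = None):
        out_data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask *= self.data >= lo
        if hi is not None:
            mask *= self.data <= hi

        def bwd(g):
            self._accum(g * mask)

        return Tensor(out_data, parents=(self,), backward=bwd)


class Parameter(Tensor):
    """A trainable tensor (leaf node)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def bwd(g):
        x._accum(g * mask)

    return Tensor(out_data, parents=(x,), backward=bwd)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(x.data > 0, _F32(1.0), _F32(slope))
    out_data = x.data * factor

    def bwd(g):
        x._accum(g * factor)

    return Tensor(out_data, parents=(x,), backward=bwd)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def bwd(g):
        x._accum(g * (1.0 - out_data**2))

    return Tensor(out_data, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=bwd)


def softmax_channel(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accum(out_data * (g - dot))

    return Tensor(out_data, parents=(x,), backward=bwd)


def concat_rows(xs: list[Tensor]) -> Tensor:
    """Concatenate along the batch axis (inverse of ``slice_rows``)."""
    sizes = [t.data.shape[0] for t in xs]
    out_data = np.concatenate([t.data for t in xs], axis=0)
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(xs, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(g[a:b])

    return Tensor(out_data, parents=tuple(xs), backward=bwd)


def slice_rows(x: Tensor, start: int, stop: int) -> Tensor:
    """View rows [start:stop) of the batch axis, with scatter backward."""
    out_data = x.data[start:stop]

    def bwd(g):
        full = np.zeros_like(x.data)
        full[start:stop] = g
        x._accum(full)

    return Tensor(out_data, parents=(x,), backward=bwd)


def cat_channels(xs: list[Tensor]) -> Tensor:
    sizes = [t.data.shape[1] for t in xs]
    out_data = np.concatenate([t.data for t in xs], axis=1)
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(xs, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(g[:, a:b])

    return Tensor(out_data, parents=tuple(xs), backward=bwd)


# -- convolution -------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(B,C,Hp,Wp) -> strided view (B, Ho, Wo, C, kh, kw); no copy."""
    b, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    sb, sc, sh, sw = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, ho, wo, c, kh, kw),
        strides=(sb, sh * stride, sw * stride, sc, sh, sw),
        writeable=False,
    )
    return view, ho, wo


@_njit(cache=True, fastmath=True)
def _nb_conv3x3(xp, w, stride):  # pragma: no cover - exercised via conv2d
    bsz, cin, hp, wp = xp.shape
    cout = w.shape[0]
    ho = (hp - 3) // stride + 1
    wo = (wp - 3) // stride + 1
    out = np.empty((bsz, cout, ho, wo), dtype=np.float32)
    buf = np.empty(wo, dtype=np.float32)
    for bb in range(bsz):
        for o in range(cout):
            for yy in range(ho):
                for xx in range(wo):
                    buf[xx] = 0.0
                for c in range(cin):
                    for ky in range(3):
                        xrow = xp[bb, c, yy * stride + ky]
                        w0 = w[o, c, ky, 0]
                        w1 = w[o, c, ky, 1]
                        w2 = w[o, c, ky, 2]
                        for xx in range(wo):
                            p = xx * stride
                            buf[xx] += w0 * xrow[p] + w1 * xrow[p + 1] + w2 * xrow[p + 2]
                out[bb, o, yy] = buf
    return out


@_njit(cache=True, fastmath=True)
def _nb_conv3x3_gw(xp, g, stride):  # pragma: no cover - exercised via conv2d
    bsz, cin, hp, wp = xp.shape
    cout, ho, wo = g.shape[1], g.shape[2], g.shape[3]
    gw = np.zeros((cout, cin, 3, 3), dtype=np.float32)
    for bb in range(bsz):
        for o in range(cout):
            for c in range(cin):
                for ky in range(3):
                    for kx in range(3):
                        s = np.float32(0.0)
                        for yy in range(ho):
                            grow = g[bb, o, yy]
                            xrow = xp[bb, c, yy * stride + ky]
                            for xx in range(wo):
                                s += grow[xx] * xrow[xx * stride + kx]
                        gw[o, c, ky, kx] += s
    return gw


def _pad2d(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    b, c, h, w = x.shape
    out = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
    out[:, :, pad:pad + h, pad:pad + w] = x
    return out


def _conv2d_raw(x: np.ndarray, w: np.ndarray, stride: int, pad: int,
                return_ctx: bool = False):
    """Plain cross-correlation, NCHW x (O,C,kh,kw) -> NOHW.

    When ``return_ctx`` the saved intermediate needed by the weight
    gradient is returned too: the padded input (compiled kernel path) or
    the im2col matrix (numpy fallback), tagged accordingly.
    """
    o, c, kh, kw = w.shape
    if kh == 1 and kw == 1 and stride == 1 and pad == 0:
        b, _, h, wd = x.shape
        y = np.matmul(w.reshape(o, c)[None], x.reshape(b, c, h * wd))
        y = y.reshape(b, o, h, wd)
        return (y, None) if return_ctx else y
    xp = _pad2d(x, pad)
    # compiled kernel only where the im2col GEMM is badly shaped (thin
    # weight matrices: decoder/discriminator output layers); BLAS wins
    # everywhere else
    if kh == 3 and kw == 3 and _HAVE_NUMBA and o * c <= 16:
        xp = np.ascontiguousarray(xp)
        y = _nb_conv3x3(xp, np.ascontiguousarray(w), stride)
        return (y, ("pad", xp)) if return_ctx else y
    view, ho, wo = _im2col(xp, kh, kw, stride)
    cols = view.reshape(-1, c * kh * kw)  # the single im2col copy
    y = cols @ w.reshape(o, -1).T
    y = y.reshape(x.shape[0], ho, wo, o).transpose(0, 3, 1, 2)
    return (y, ("cols", cols)) if return_ctx else y


def _dilate(g: np.ndarray, stride: int) -> np.ndarray:
    if stride == 1:
        return g
    b, c, h, w = g.shape
    out = np.zeros((b, c, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=g.dtype)
    out[:, :, ::stride, ::stride] = g
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), bias broadcast over space.

    Output size floor-divides as usual; ``pad`` must be <= kernel-1 so the
    input gradient is the exact transpose of the forward map.
    """
    o, c, kh, kw = w.data.shape
    bsz, cin, h, wdt = x.data.shape
    if cin != c:
        raise ValueError(f"conv2d: input has {cin} channels, kernel expects {c}")
    if h + 2 * pad < kh or wdt + 2 * pad < kw:
        raise ValueError("conv2d: input smaller than kernel")
    if pad > kh - 1 or pad > kw - 1:
        raise ValueError("conv2d: pad larger than kernel-1 is not supported")
    is_1x1 = kh == 1 and kw == 1 and stride == 1 and pad == 0
    out_data, ctx = _conv2d_raw(x.data, w.data, stride, pad, return_ctx=True)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if is_1x1:
            gm = g.reshape(g.shape[0], o, -1)
            xm = x.data.reshape(bsz, c, -1)
            if w.requires_grad:
                gw = np.matmul(gm, xm.transpose(0, 2, 1)).sum(axis=0)
                w._accum(gw.reshape(o, c, 1, 1))
            if x.requires_grad:
                gx = np.matmul(w.data.reshape(o, c).T[None], gm)
                x._accum(gx.reshape(x.data.shape))
            return
        if w.requires_grad:
            kind, saved = ctx
            if kind == "pad":
                gw = _nb_conv3x3_gw(saved, np.ascontiguousarray(g), stride)
            else:
                gw = (g.transpose(0, 2, 3, 1).reshape(-1, o).T @ saved
                      ).reshape(o, c, kh, kw)
            w._accum(gw)
        if x.requires_grad:
            # full correlation of the dilated output-grad with the flipped kernel;
            # trailing zeros restore rows lost to the stride's floor division
            gd = _dilate(g, stride)
            th = (h + 2 * pad - kh) + 1 - gd.shape[2]
            tw = (wdt + 2 * pad - kw) + 1 - gd.shape[3]
            if th or tw:
                padded = np.zeros(gd.shape[:2] + (gd.shape[2] + th, gd.shape[3] + tw),
                                  dtype=gd.dtype)
                padded[:, :, :gd.shape[2], :gd.shape[3]] = gd
                gd = padded
            w_flip = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            gx = _conv2d_raw(gd, w_flip, 1, kh - 1 - pad)
            x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bwd)


# -- upsampling --------------------------------------------------------------

def upsample_nearest(x: Tensor, k: int) -> Tensor:
    out_data = x.data.repeat(k, axis=2).repeat(k, axis=3)

    def bwd(g):
        b, c, h, w = x.data.shape
        gg = g.reshape(b, c, h, k, w, k).sum(axis=(3, 5))
        x._accum(gg)

    return Tensor(out_data, parents=(x,), backward=bwd)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Bilinear interpolation matrix (align_corners=False convention)."""
    m = np.zeros((n_out, n_in), dtype=_F32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[i, lo_c] += 1.0 - frac
        m[i, hi_c] += frac
    return m


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    if key not in _INTERP_CACHE:
        _INTERP_CACHE[key] = _interp_matrix(n_out, n_in)
    return _INTERP_CACHE[key]


def upsample_bilinear(x: Tensor, size: int) -> Tensor:
    b, c, h, w = x.data.shape
    mr, mc = _interp(size, h), _interp(size, w)
    # (S,H) @ (B,C,H,W) @ (W,S) via broadcasting matmul
    out_data = np.matmul(np.matmul(mr, x.data), mc.T)

    def bwd(g):
        gx = np.matmul(np.matmul(mr.T, g), mc)
        x._accum(gx.astype(_F32))

    return Tensor(out_data, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Parameter container with named registry (for checkpoints and grouping)."""

    def parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                out[name] = val
            elif isinstance(val, Module):
                for k, v in val.parameters().items():
                    out[f"{name}.{k}"] = v
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for k, v in item.parameters().items():
                            out[f"{name}.{i}.{k}"] = v
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in params.items():
            p.data = _as_array(state[k]).reshape(p.data.shape)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Fused per-image, per-channel normalisation with learnable affine."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = xc * inv
    out_data = xn * gamma.data + beta.data

    def bwd(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)).reshape(beta.data.shape))
        if gamma.requires_grad:
            gamma._accum((g * xn).sum(axis=(0, 2, 3)).reshape(gamma.data.shape))
        if x.requires_grad:
            gh = g * gamma.data
            m1 = gh.mean(axis=(2, 3), keepdims=True)
            m2 = (gh * xn).mean(axis=(2, 3), keepdims=True)
            x._accum((inv * (gh - m1 - xn * m2)).astype(_F32))

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)


class InstanceNorm2d(Module):
    """Per-image, per-channel normalisation over the spatial axes with a
    learnable affine.  Removes global intensity statistics — the main cue
    separating imaging modalities — which is what makes a shared
    encoder/decoder pair align two domains at all."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta, self.eps)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        # He initialisation, suits the relu-heavy nets here
        std = np.sqrt(2.0 / fan_in)
        self.w = Parameter(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.b = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.pad)


class SelfAttention2d(Module):
    """Non-local self-attention over a feature grid.

    Query/key/value/output maps are 1x1 convolutions (full channel width);
    the attention map ``A`` is the row-softmaxed Gram matrix of the
    query/key projections over the N = H*W spatial positions.  The output
    is gated by a learnable scalar that starts at zero, so a freshly
    initialised module is exactly the identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        self.c1 = Conv2d(channels, channels, 1, rng=rng)
        self.c2 = Conv2d(channels, channels, 1, rng=rng)
        self.c3 = Conv2d(channels, channels, 1, rng=rng)
        self.c4 = Conv2d(channels, channels, 1, rng=rng)
        self.gate = Parameter(np.zeros(()))
        self.last_attention: np.ndarray | None = None

    def attention_map(self, f: Tensor) -> Tensor:
        b, c, h, w = f.shape
        n = h * w
        q = self.c1(f).reshape(b, c, n)           # C x N
        k = self.c2(f).reshape(b, c, n)
        logits = q.transpose(0, 2, 1) @ k          # N x N Gram matrix
        return softmax_channel(logits, axis=2)     # rows sum to 1

    def __call__(self, f: Tensor) -> Tensor:
        b, c, h, w = f.shape
        n = h * w
        a = self.attention_map(f)
        self.last_attention = a.data
        v = self.c3(f).reshape(b, c, n)
        # position j of the output attends over all positions i with row A[j]
        mixed = v @ a.transpose(0, 2, 1)           # (B,C,N)
        f_att = self.c4(mixed.reshape(b, c, h, w))
        return self.gate * f_att + f


class Adam(Module):
    """Adam over explicit (param, lr, betas) groups; moments keyed by identity."""

    def __init__(self, groups: list[tuple[list[Parameter], float, tuple[float, float]]],
                 eps: float = 1e-8):
        self.groups = groups
        self.eps = eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t: dict[int, int] = {}

    def step(self, params: list[Parameter] | None = None):
        """Apply one update to ``params`` (default: every grouped param with a grad)."""
        allowed = None if params is None else {id(p) for p in params}
        for plist, lr, (b1, b2) in self.groups:
            for p in plist:
                if p.grad is None:
                    continue
                if allowed is not None and id(p) not in allowed:
                    continue
                key = id(p)
                m = self._m.setdefault(key, np.zeros_like(p.data))
                v = self._v.setdefault(key, np.zeros_like(p.data))
                t = self._t.get(key, 0) + 1
                self._t[key] = t
                g = p.grad
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                p.data -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_F32)

    def zero_grad(self):
        for plist, _, _ in self.groups:
            for p in plist:
                p.grad = None
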