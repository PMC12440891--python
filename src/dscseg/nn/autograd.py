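"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: every differentiable operation
builds a node holding a backward closure, and :meth:`Tensor.backward`
walks the graph in reverse topological order.  All arithmetic is float32;
convolutions are evaluated as kernel-tap loops over BLAS matmuls rather
than a monolithic im2col, which keeps peak memory proportional to the
activations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "is_grad_enabled",
    "add",
    "mul",
    "matmul",
    "relu",
    "relu6",
    "sigmoid",
    "conv2d",
    "batch_norm",
    "upsample_bilinear",
    "mean",
    "amax",
    "concat",
    "reshape",
    "dropout",
    "softmax_cross_entropy",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_f32(a) -> np.ndarray:
    arr = np.asarray(a)
    if arr.dtype != np.float32:
        arr = arr.astype(np.float32)
    return arr


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior state promptly
                node._backward = None

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), Tensor(-1.0)))

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def reshape(self, *shape):
        return reshape(self, shape)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters stay trainable under no_grad


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise -----------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0).astype(np.float32)

    def backward(g):
        x._accumulate(g * mask)

    return _make(out_data, (x,), backward)


def relu6(x: Tensor) -> Tensor:
    out_data = np.clip(x.data, 0.0, 6.0)
    mask = (x.data > 0) & (x.data < 6.0)

    def backward(g):
        x._accumulate(g * mask)

    return _make(out_data, (x,), backward)


_SIGMOID_LO = np.float32(1e-30)
_SIGMOID_HI = np.nextafter(np.float32(1.0), np.float32(0.0))


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic: exp is only taken of non-positive values;
    # the output is clamped one representable step away from 0 and 1 so that
    # gate values stay strictly inside (0, 1) even where float32 saturates
    pos = x.data >= 0
    ex = np.exp(np.where(pos, -x.data, x.data))
    out_data = np.where(pos, 1.0 / (1.0 + ex), ex / (1.0 + ex)).astype(np.float32)
    np.clip(out_data, _SIGMOID_LO, _SIGMOID_HI, out=out_data)

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(old))

    return _make(out_data, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tuple(tensors), backward)


# -- reductions ------------------------------------------------------------


def mean(x: Tensor, axis, keepdims: bool = True) -> Tensor:
    axis = tuple(np.atleast_1d(axis))
    out_data = x.data.mean(axis=axis, keepdims=keepdims)
    count = int(np.prod([x.data.shape[a] for a in axis]))

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis=axis)
        x._accumulate(np.broadcast_to(g / count, x.data.shape))

    return _make(out_data, (x,), backward)


def amax(x: Tensor, axis, keepdims: bool = True) -> Tensor:
    axis = tuple(np.atleast_1d(axis))
    out_data = x.data.max(axis=axis, keepdims=True)
    mask = x.data == out_data
    # ties share the gradient equally, keeping backward deterministic
    norm = mask.sum(axis=axis, keepdims=True)
    res = out_data if keepdims else out_data.squeeze(axis=axis)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis=axis)
        x._accumulate(mask * (g / norm))

    return _make(res, (x,), backward)


# -- convolution -----------------------------------------------------------


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding=0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation with stride/padding/dilation.

    Kernels may be rectangular (e.g. 3x1 for strip convolutions);
    ``padding`` is then a (pad_h, pad_w) pair.  ``groups`` must be 1
    (dense) or equal to the input channel count (depthwise with depth
    multiplier 1) — the only two cases this architecture uses.
    """
    n, cin, h, wd = x.data.shape
    cout, cin_g, kh, kw = w.data.shape
    s, d = stride, dilation
    ph, pw = (padding, padding) if np.isscalar(padding) else padding
    depthwise = groups == cin and cin > 1
    if not depthwise and groups != 1:
        raise ValueError("groups must be 1 or in_channels")
    if depthwise and (cin_g != 1 or cout != cin):
        raise ValueError("depthwise conv requires weight shape (C, 1, kh, kw)")
    if not depthwise and cin_g != cin:
        raise ValueError(
            f"weight expects {cin_g} input channels, feature map has {cin}"
        )
    ho = (h + 2 * ph - (d * (kh - 1) + 1)) // s + 1
    wo = (wd + 2 * pw - (d * (kw - 1) + 1)) // s + 1
    if ho < 1 or wo < 1:
        raise ValueError("convolution output would be empty")

    if ph > 0 or pw > 0:
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    else:
        xp = x.data

    taps = []  # (u, v, strided view of xp)
    for u in range(kh):
        for v in range(kw):
            view = xp[
                :,
                :,
                u * d : u * d + (ho - 1) * s + 1 : s,
                v * d : v * d + (wo - 1) * s + 1 : s,
            ]
            taps.append((u, v, view))

    if depthwise:
        out = np.zeros((n, cout, ho, wo), dtype=np.float32)
        wk = w.data[:, 0]  # (C, k, k)
        for u, v, view in taps:
            out += wk[None, :, u, v, None, None] * view
    else:
        acc = np.zeros((n, ho, wo, cout), dtype=np.float32)
        for u, v, view in taps:
            cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1)).reshape(-1, cin)
            acc += (cols @ w.data[:, :, u, v].T).reshape(n, ho, wo, cout)
        out = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
    if b is not None:
        out += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            if depthwise:
                for u, v, view in taps:
                    gw[:, 0, u, v] = (g * view).sum(axis=(0, 2, 3))
            else:
                gflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
                for u, v, view in taps:
                    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1)).reshape(
                        -1, cin
                    )
                    gw[:, :, u, v] = gflat.T @ cols
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros((n, cin, h + 2 * ph, wd + 2 * pw), dtype=np.float32)
            if depthwise:
                wk = w.data[:, 0]
                for u in range(kh):
                    for v in range(kw):
                        gxp[
                            :,
                            :,
                            u * d : u * d + (ho - 1) * s + 1 : s,
                            v * d : v * d + (wo - 1) * s + 1 : s,
                        ] += wk[None, :, u, v, None, None] * g
            else:
                gflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
                for u in range(kh):
                    for v in range(kw):
                        gx_tap = (gflat @ w.data[:, :, u, v]).reshape(n, ho, wo, cin)
                        gxp[
                            :,
                            :,
                            u * d : u * d + (ho - 1) * s + 1 : s,
                            v * d : v * d + (wo - 1) * s + 1 : s,
                        ] += gx_tap.transpose(0, 3, 1, 2)
            if ph > 0 or pw > 0:
                gxp = gxp[:, :, ph : ph + h, pw : pw + wd]
            x._accumulate(gxp)

    return _make(out, parents, backward)


# -- batch normalization ---------------------------------------------------


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel normalization of an (N, C, H, W) map.

    Running statistics are updated in place during training (unbiased
    variance, matching the usual deep-learning convention).
    """
    axes = (0, 2, 3)
    if training:
        m = x.data.mean(axis=axes)
        v = x.data.var(axis=axes)
        cnt = x.data.size // x.data.shape[1]
        running_mean *= 1.0 - momentum
        running_mean += momentum * m
        running_var *= 1.0 - momentum
        running_var += momentum * v * (cnt / max(cnt - 1, 1))
    else:
        m = running_mean
        v = running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if x.requires_grad:
            gi = g * gamma.data[None, :, None, None]
            if training:
                cnt = x.data.size // x.data.shape[1]
                gm = gi.sum(axis=axes, keepdims=True)
                gv = (gi * xhat).sum(axis=axes, keepdims=True)
                gx = (
                    inv[None, :, None, None]
                    * (gi - gm / cnt - xhat * gv / cnt)
                )
            else:
                gx = gi * inv[None, :, None, None]
            x._accumulate(gx.astype(np.float32))

    return _make(out.astype(np.float32), (x, gamma, beta), backward)


# -- bilinear resampling ---------------------------------------------------


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel centers)."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        frac = src - i0
        a[o, i0] += 1.0 - frac
        a[o, i1] += frac
    return a


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix_cached(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    if key not in _INTERP_CACHE:
        _INTERP_CACHE[key] = _interp_matrix(n_out, n_in)
    return _INTERP_CACHE[key]


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of an (N, C, H, W) map; corner alignment disabled."""
    n, c, h, w = x.data.shape
    ah = _interp_matrix_cached(out_h, h)
    aw = _interp_matrix_cached(out_w, w)
    out = np.matmul(np.matmul(ah[None, None], x.data), aw.T[None, None])

    def backward(g):
        gx = np.matmul(np.matmul(ah.T[None, None], g), aw[None, None])
        x._accumulate(gx.astype(np.float32))

    return _make(out.astype(np.float32), (x,), backward)


def dropout(x: Tensor, p: float, training: bool, rng: np.random.Generator) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = 1.0 - p
    mask = (rng.random(x.data.shape) < keep).astype(np.float32) / keep

    def backward(g):
        x._accumulate(g * mask)

    return _make(x.data * mask, (x,), backward)


# -- loss ------------------------------------------------------------------


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, ignore_label: int = 255
) -> tuple[Tensor, int]:
    """Mean per-pixel cross-entropy of (N, M, H, W) logits.

    Pixels whose label equals ``ignore_label`` contribute neither to the
    sum nor to the pixel count N.  Returns the scalar loss and the number
    of scored pixels (0 means the loss is defined as zero).
    """
    n, m, h, w = logits.data.shape
    labels = np.asarray(labels)
    if labels.shape != (n, h, w):
        raise ValueError("labels must have shape (batch, H, W)")
    valid = labels != ignore_label
    count = int(valid.sum())
    lv = np.where(valid, labels, 0).astype(np.int64)
    if np.any((lv < 0) | (lv >= m)):
        raise ValueError("label outside [0, num_classes)")

    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    prob = ez / ez.sum(axis=1, keepdims=True)
    picked = np.take_along_axis(prob, lv[:, None], axis=1)[:, 0]
    nll = -np.log(np.maximum(picked, 1e-30)) * valid
    loss_val = nll.sum() / count if count > 0 else 0.0

    def backward(g):
        if count == 0:
            return
        onehot = np.zeros_like(prob)
        np.put_along_axis(onehot, lv[:, None], 1.0, axis=1)
        gx = (prob - onehot) * valid[:, None] / count
        logits._accumulate(gx.astype(np.float32) * g)

    out = _make(np.float32(loss_val), (logits,), backward)
    return out, count
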