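"""Layer abstractions over the autograd core.

Mirrors the familiar module container pattern: parameters and submodules
register themselves on attribute assignment, ``state_dict`` flattens the
tree into name → array, and a process-wide profiling tape (used by the
complexity profiler) records every leaf call with its shapes.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

__all__ = [
    "Module",
    "Sequential",
    "Identity",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "ReLU6",
    "Sigmoid",
    "Dropout",
    "GlobalAvgPool2d",
    "UpsampleBilinear",
    "profiling_tape",
]

_PROFILE_TAPE: list | None = None


class profiling_tape:
    """Context manager collecting (module, in_shape, out_shape) per leaf call."""

    def __enter__(self):
        global _PROFILE_TAPE
        self.records: list = []
        self._prev = _PROFILE_TAPE
        _PROFILE_TAPE = self.records
        return self

    def __exit__(self, *exc):
        global _PROFILE_TAPE
        _PROFILE_TAPE = self._prev
        return False


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------------

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for name, mod in self.named_modules(prefix):
            for pname, p in mod._parameters.items():
                yield (f"{name}.{pname}" if name else pname), p

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, mod in self.named_modules(prefix):
            for bname, b in mod._buffers.items():
                yield (f"{name}.{bname}" if name else bname), b

    def num_parameters(self, trainable_only: bool = True) -> int:
        return sum(
            p.data.size
            for p in self.parameters()
            if p.requires_grad or not trainable_only
        )

    # -- modes & state -------------------------------------------------------

    def train(self, mode: bool = True):
        # recurse through children so subclasses can override (e.g. a frozen
        # backbone that must stay in inference mode during training)
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def requires_grad_(self, flag: bool = True):
        for p in self.parameters():
            p.requires_grad = flag
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for name, b in self.named_buffers():
            out[name] = np.asarray(b).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = []
        for name in list(params) + [n for n, _ in self.named_buffers()]:
            if name not in state:
                missing.append(name)
        if missing:
            raise KeyError(f"state dict is missing entries: {missing[:5]} ...")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()
        for name, mod in self.named_modules():
            for bname in mod._buffers:
                full = f"{name}.{bname}" if name else bname
                mod._buffers[bname][...] = state[full]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as npz:
            self.load_state_dict({k: npz[k] for k in npz.files})

    # -- call ----------------------------------------------------------------

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        out = self.forward(*args, **kwargs)
        if _PROFILE_TAPE is not None and not self._modules:
            xin = args[0] if args and isinstance(args[0], Tensor) else None
            if xin is not None and isinstance(out, Tensor):
                _PROFILE_TAPE.append((self, xin.shape, out.shape))
        return out


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._order = []
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
            self._order.append(str(i))

    def __iter__(self):
        return (getattr(self, n) for n in self._order)

    def __len__(self):
        return len(self._order)

    def __getitem__(self, i):
        return getattr(self, self._order[i])

    def append(self, mod):
        name = str(len(self._order))
        setattr(self, name, mod)
        self._order.append(name)
        return self

    def forward(self, x):
        for name in self._order:
            x = getattr(self, name)(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        stride: int = 1,
        padding=0,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        kh, kw = (
            (kernel_size, kernel_size) if np.isscalar(kernel_size) else kernel_size
        )
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel size must be odd")
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        if groups not in (1, in_channels):
            raise ValueError("groups must be 1 or in_channels")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = (kh, kw)
        self.stride = stride
        self.padding = (padding, padding) if np.isscalar(padding) else tuple(padding)
        self.dilation = dilation
        self.groups = groups
        rng = rng if rng is not None else np.random.default_rng(0)
        cin_g = in_channels // groups
        fan_in = cin_g * kh * kw
        self.weight = Parameter(_kaiming(rng, (out_channels, cin_g, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if bias else None

    def forward(self, x):
        return ag.conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
            groups=self.groups,
        )

    def macs(self, in_shape, out_shape) -> int:
        _, _, ho, wo = out_shape
        cin_g = self.in_channels // self.groups
        kh, kw = self.kernel_size
        return int(kh * kw * cin_g * self.out_channels * ho * wo)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, np.float32))
        self.bias = Parameter(np.zeros(num_features, np.float32))
        self._buffers["running_mean"] = np.zeros(num_features, np.float32)
        self._buffers["running_var"] = np.ones(num_features, np.float32)

    def forward(self, x):
        stats_training = self.training and ag.is_grad_enabled()
        return ag.batch_norm(
            x,
            self.weight,
            self.bias,
            self._buffers["running_mean"],
            self._buffers["running_var"],
            training=stats_training,
            momentum=self.momentum,
            eps=self.eps,
        )

    def macs(self, in_shape, out_shape) -> int:
        # one multiply-add per element (scale and shift)
        return int(np.prod(out_shape))


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x):
        out = ag.matmul(x, self.weight)
        if self.bias is not None:
            out = ag.add(out, self.bias)
        return out

    def macs(self, in_shape, out_shape) -> int:
        batch = int(np.prod(in_shape[:-1]))
        return batch * self.in_features * self.out_features


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class ReLU6(Module):
    def forward(self, x):
        return ag.relu6(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class Dropout(Module):
    def __init__(self, p: float = 0.1, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x):
        return ag.dropout(x, self.p, self.training and ag.is_grad_enabled(), self.rng)


class GlobalAvgPool2d(Module):
    def forward(self, x):
        return ag.mean(x, axis=(2, 3), keepdims=True)


class UpsampleBilinear(Module):
    """Bilinear resize to a fixed scale factor (corner alignment disabled)."""

    def __init__(self, scale: int):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        _, _, h, w = x.shape
        return ag.upsample_bilinear(x, h * self.scale, w * self.scale)
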