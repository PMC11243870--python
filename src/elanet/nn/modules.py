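"""Layer and container classes on top of the autodiff core.

The surface intentionally mirrors the conventions of mainstream deep
learning frameworks (``Conv2d``, ``BatchNorm2d``, ``Sequential`` ...), so
the network definition reads like any segmentation code base.  Each leaf
layer additionally knows its *analytic* trainable-parameter count and its
multiply-accumulate cost for a given input shape; the complexity module
aggregates these without running any arithmetic.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor, is_grad_enabled

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "Sigmoid",
    "Identity",
    "Sequential",
]


class Module:
    """Base class: child-module/parameter registration and tree walking."""

    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, Tensor):
            self._params[name] = value
        object.__setattr__(self, name, value)

    # -- tree walking ----------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, child in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for _, mod, name, p in self._named_entries(prefix, "_params"):
            yield name, p

    def _named_entries(self, prefix, slot):
        for mpath, mod in self.named_modules(prefix):
            for pname, p in getattr(mod, slot).items():
                full = f"{mpath}.{pname}" if mpath else pname
                yield mpath, mod, full, p

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def initialize(self, rng: np.random.Generator):
        """(Re-)initialize every leaf layer, in deterministic tree order."""
        for _, m in self.named_modules():
            if hasattr(m, "reset_parameters"):
                m.reset_parameters(rng)
        return self

    # -- serialization ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for _, mod, name, p in self._named_entries("", "_params"):
            out[name] = p.data.copy()
        for _, mod, name, b in self._named_entries("", "_buffers"):
            out[name] = b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for _, mod, name, p in self._named_entries("", "_params"):
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.shape)
        for _, mod, name, b in self._named_entries("", "_buffers"):
            mod._buffers[name.rsplit(".", 1)[-1]][...] = state[name]

    # -- complexity ------------------------------------------------------
    def param_count(self) -> int:
        """Analytic trainable-scalar count (leaf classes override)."""
        return sum(m._own_param_count() for _, m in self.named_modules())

    def _own_param_count(self) -> int:
        return 0

    def macs(self, in_shape: tuple[int, int, int]) -> int:
        """Multiply-accumulate count for one (C, H, W) input (leaf override)."""
        return 0

    def out_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        return in_shape

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, dilation=1,
                 groups=1, bias=True):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if cin % groups or cout % groups:
            raise ValueError(f"channels ({cin}->{cout}) not divisible by groups={groups}")
        self.cin, self.cout, self.kh, self.kw = cin, cout, kh, kw
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        self.weight = Tensor(np.zeros((cout, cin // groups, kh, kw)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def reset_parameters(self, rng):
        fan_in = self.cin // self.groups * self.kh * self.kw
        std = np.sqrt(2.0 / fan_in)  # Kaiming-normal for ReLU networks
        self.weight.data = rng.normal(0.0, std, self.weight.shape).astype(np.float32)
        if self.bias is not None:
            self.bias.data = np.zeros(self.cout, dtype=np.float32)

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.dilation, self.groups)

    def _own_param_count(self):
        n = self.kh * self.kw * (self.cin // self.groups) * self.cout
        return n + (self.cout if self.bias is not None else 0)

    def out_shape(self, in_shape):
        _, h, w = in_shape
        ho = (h + 2 * self.padding - self.dilation * (self.kh - 1) - 1) // self.stride + 1
        wo = (w + 2 * self.padding - self.dilation * (self.kw - 1) - 1) // self.stride + 1
        return (self.cout, ho, wo)

    def macs(self, in_shape):
        c, ho, wo = self.out_shape(in_shape)
        return self.kh * self.kw * (self.cin // self.groups) * self.cout * ho * wo


class BatchNorm2d(Module):
    """Batch normalization; eval mode uses running statistics."""

    def __init__(self, num_features, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features, self.eps, self.momentum = num_features, eps, momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(num_features, dtype=np.float32)
        self._buffers["running_var"] = np.ones(num_features, dtype=np.float32)

    def reset_parameters(self, rng):
        self.gamma.data = np.ones(self.num_features, dtype=np.float32)
        self.beta.data = np.zeros(self.num_features, dtype=np.float32)
        self._buffers["running_mean"][...] = 0.0
        self._buffers["running_var"][...] = 1.0

    def identity_mode(self):
        """Freeze to the exact identity transform (for block-level oracles):
        running_var is set to 1 - eps so (var + eps) normalizes by 1.0."""
        self.reset_parameters(None)
        self._buffers["running_var"][...] = 1.0 - self.eps
        self.eval()
        return self

    def forward(self, x):
        c = self.num_features
        if self.training and is_grad_enabled():
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.size // c
            self._buffers["running_mean"] *= 1 - self.momentum
            self._buffers["running_mean"] += self.momentum * mu.data.reshape(c)
            unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
            self._buffers["running_var"] *= 1 - self.momentum
            self._buffers["running_var"] += self.momentum * unbiased
            xhat = xc * _rsqrt(var, self.eps)
        else:
            mu = self._buffers["running_mean"].reshape(1, c, 1, 1)
            var = self._buffers["running_var"].reshape(1, c, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / np.sqrt(var + self.eps))
        g = self.gamma.reshape(1, c, 1, 1)
        b = self.beta.reshape(1, c, 1, 1)
        return xhat * g + b

    def _own_param_count(self):
        return 2 * self.num_features


def _rsqrt(var: Tensor, eps: float) -> Tensor:
    s = np.sqrt(var.data + eps)

    def backward(g):
        if var.requires_grad:
            var._accum(g * (-0.5) / (s * (var.data + eps)))

    return Tensor._node(1.0 / s, (var,), backward)


class Linear(Module):
    def __init__(self, fin, fout, bias=True):
        super().__init__()
        self.fin, self.fout = fin, fout
        self.weight = Tensor(np.zeros((fout, fin)), requires_grad=True)
        self.bias = Tensor(np.zeros(fout), requires_grad=True) if bias else None

    def reset_parameters(self, rng):
        std = np.sqrt(2.0 / self.fin)
        self.weight.data = rng.normal(0.0, std, self.weight.shape).astype(np.float32)
        if self.bias is not None:
            self.bias.data = np.zeros(self.fout, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        """x: (..., fin) -> (..., fout) via explicit sum products."""
        w = self.weight
        lead = x.shape[:-1]
        x2 = x.reshape(int(np.prod(lead)) if lead else 1, self.fin)
        out = _matmul(x2, w)
        if self.bias is not None:
            out = out + self.bias.reshape(1, self.fout)
        return out.reshape(*lead, self.fout) if lead else out.reshape(self.fout)

    def _own_param_count(self):
        return self.fin * self.fout + (self.fout if self.bias is not None else 0)

    def macs(self, in_shape=None):
        return self.fin * self.fout


def _matmul(x: Tensor, w: Tensor) -> Tensor:
    """(n, fin) @ (fout, fin)^T with gradients for both operands."""
    out = x.data @ w.data.T

    def backward(g):
        if x.requires_grad:
            x._accum(g @ w.data)
        if w.requires_grad:
            w._accum(g.T @ x.data)

    return Tensor._node(out, (x, w), backward)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def out_shape(self, in_shape):
        for layer in self.layers:
            in_shape = layer.out_shape(in_shape)
        return in_shape

    def macs(self, in_shape):
        total = 0
        for layer in self.layers:
            total += layer.macs(in_shape)
            in_shape = layer.out_shape(in_shape)
        return total
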