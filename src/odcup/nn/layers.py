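"""Parameterised layers built on the autograd engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Minimal module tree: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise ValueError(f"checkpoint is missing entries: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape}, model {p.data.shape}"
                )
            p.data = arr.copy()
        for name, b in buffers.items():
            arr = np.asarray(state[name], dtype=b.dtype)
            if arr.shape != b.shape:
                raise ValueError(f"shape mismatch for buffer {name}")
            b[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def kaiming_conv(rng: np.random.Generator, shape, dtype=np.float32) -> Tensor:
    """He fan-in normal initialisation for a convolution weight."""
    fan_in = int(np.prod(shape[1:]))
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, padding: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.padding = padding
        self.weight = kaiming_conv(rng, (out_ch, in_ch, kernel, kernel))
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, padding=self.padding)


class ConvTranspose2dX2(Module):
    """Kernel-2 stride-2 transposed convolution (deterministic x2 upsample)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.weight = kaiming_conv(rng, (in_ch, out_ch, 2, 2))
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d_x2(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.normal(0.0, std, size=(out_f, in_f)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, _transpose(self.weight)), self.bias)


def _transpose(t: Tensor) -> Tensor:
    out_data = t.data.T

    def backward(g):
        t._accumulate(g.T)

    return ag._make(out_data, (t,), backward)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(num_features, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, np.float32)
        self.running_var = np.ones(num_features, np.float32)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training,
                              momentum=self.momentum, eps=self.eps)
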