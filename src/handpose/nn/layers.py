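"""Layers and blocks: convolution, batch norm, squeeze-and-excitation
residual blocks and the SE-Hourglass encoder-decoder."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "SEResidual", "Hourglass"]


class Module:
    """Minimal module container: parameter registry, train/eval mode, state dict."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data for k, v in self._params.items()}
        out.update({prefix + k: v for k, v in self._buffers.items()})
        for name, m in self._modules.items():
            out.update(m.named_state(prefix + name + "."))
        return out

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, t in self._params.items():
            t.data = np.asarray(state[prefix + k], dtype=np.float32).copy()
        for k in self._buffers:
            arr = np.asarray(state[prefix + k], dtype=np.float32).copy()
            self._buffers[k] = arr
            object.__setattr__(self, k, arr)
        for name, m in self._modules.items():
            m.load_state(state, prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)   # He initialization for ReLU nets
        self.register_param("weight", rng.normal(0.0, std, (cout, cin, k, k)).astype(np.float32))
        if bias:
            self.register_param("bias", np.zeros(cout, dtype=np.float32))
        else:
            self.bias = None
        self.stride, self.pad, self.cin = stride, pad, cin

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        return x.conv2d(self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.register_param("gamma", np.ones(c, dtype=np.float32))
        self.register_param("beta", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))
        self.eps, self.momentum, self.c = eps, momentum, c

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, self.c, 1, 1)
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            rm = self._buffers["running_mean"] * (1 - m) + mean.data.reshape(-1) * m
            rv = self._buffers["running_var"] * (1 - m) + var.data.reshape(-1) * m
            self.register_buffer("running_mean", rm)
            self.register_buffer("running_var", rv)
            inv = (var + self.eps).sqrt()
            xn = centered / inv
        else:
            mean = Tensor(self._buffers["running_mean"].reshape(shape))
            inv = Tensor(np.sqrt(self._buffers["running_var"] + self.eps).reshape(shape))
            xn = (x - mean) / inv
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / cin)
        self.register_param("weight", rng.normal(0.0, std, (cin, cout)).astype(np.float32))
        self.register_param("bias", np.zeros(cout, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class SEResidual(Module):
    """Pre-activation bottleneck residual block with squeeze-and-excitation.

    Branch: BN-ReLU-Conv3x3 (C -> C/2) -> BN-ReLU-Conv3x3 (C/2 -> C),
    gated channel-wise by an SE module (global average pool, two FC
    layers, sigmoid) before the identity addition.  ``force_gate`` pins
    the gate to a constant, which turns the block into a plain residual
    block (gate 1) or the identity (gate 0 with any branch).
    """

    def __init__(self, c: int, se_ratio: int = 16, rng: np.random.Generator | None = None):
        super().__init__()
        mid = max(c // 2, 4)
        hidden = max(c // se_ratio, 4)
        self.bn1 = BatchNorm2d(c)
        self.conv1 = Conv2d(c, mid, 3, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, c, 3, pad=1, rng=rng)
        self.fc1 = Linear(c, hidden, rng=rng)
        self.fc2 = Linear(hidden, c, rng=rng)
        self.c = c
        self.force_gate: float | None = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.c:
            raise ValueError(f"expected {self.c} channels, got {x.shape[1]}")
        h = self.conv1(self.bn1(x).relu())
        h = self.conv2(self.bn2(h).relu())
        if self.force_gate is None:
            squeeze = h.mean(axis=(2, 3))                       # (N, C)
            gate = self.fc2(self.fc1(squeeze).relu()).sigmoid()
            n, c = gate.shape
            h = h * gate.reshape(n, c, 1, 1)
        elif self.force_gate != 1.0:
            h = h * self.force_gate
        return x + h


class Hourglass(Module):
    """Recursive encoder-decoder with a skip connection at every level,
    built entirely from SE-residual blocks."""

    def __init__(self, c: int, depth: int, se_ratio: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if depth < 1:
            raise ValueError("hourglass depth must be >= 1")
        self.skip = SEResidual(c, se_ratio, rng)
        self.down = SEResidual(c, se_ratio, rng)
        if depth > 1:
            self.inner: Module = Hourglass(c, depth - 1, se_ratio, rng)
        else:
            self.inner = SEResidual(c, se_ratio, rng)
        self.up = SEResidual(c, se_ratio, rng)
        self.depth = depth

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % (2 ** self.depth) or w % (2 ** self.depth):
            raise ValueError(f"spatial size {h}x{w} not divisible by 2^{self.depth}")
        up = self.skip(x)
        low = self.down(x.maxpool2())
        low = self.inner(low)
        low = self.up(low)
        return up + low.upsample2()
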