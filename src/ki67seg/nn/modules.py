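"""Lightweight layer/module system on top of the autograd engine."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .autograd import Parameter, Tensor

__all__ = ["Module", "ModuleList", "Conv2d", "DropBlock2d"]


class Module:
    """Base class tracking parameters, submodules and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, (Module, ModuleList)):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def modules(self):
        for m in self._modules.values():
            if isinstance(m, ModuleList):
                yield from m
            else:
                yield m

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            if isinstance(m, ModuleList):
                for i, sub in enumerate(m):
                    yield from sub.named_parameters(f"{prefix}{name}.{i}.")
            else:
                yield from m.named_parameters(f"{prefix}{name}.")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self.modules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    """A plain list of modules that participates in parameter discovery."""


class Conv2d(Module):
    """k x k convolution, 'same' padding at stride 1, LeCun-normal init.

    LeCun scaling (std = 1/sqrt(fan_in)) keeps activations near unit
    variance under SeLU, which the network uses in place of batch
    normalization.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, *, stride: int = 1,
                 dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        super().__init__()
        self.stride, self.dilation = stride, dilation
        if zero_init:
            w = np.zeros((cout, cin, k, k), dtype=np.float32)
        else:
            rng = rng or np.random.default_rng()
            std = 1.0 / np.sqrt(cin * k * k)
            w = rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        dilation=self.dilation)

    @property
    def n_params(self) -> int:
        return self.weight.data.size + (self.bias.data.size if self.bias else 0)


class DropBlock2d(Module):
    """Structured dropout: contiguous block_size x block_size feature-map
    regions are zeroed during training; inactive in evaluation mode.

    The seed rate gamma is chosen so the expected fraction of surviving
    activations equals keep_prob; surviving activations are rescaled to
    preserve the expected feature magnitude.
    """

    def __init__(self, block_size: int = 5, keep_prob: float = 0.9,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if not 0 < keep_prob <= 1:
            raise ValueError("keep_prob must be in (0, 1]")
        self.block_size = block_size
        self.keep_prob = keep_prob
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.keep_prob >= 1.0:
            return x
        n, c, h, w = x.shape
        b = min(self.block_size, h, w)
        valid_h, valid_w = h - b + 1, w - b + 1
        gamma = (1.0 - self.keep_prob) / b**2 * (h * w) / (valid_h * valid_w)
        seeds = np.zeros((n, c, h, w), dtype=bool)
        off = (b - 1) // 2
        region = self.rng.random((n, c, valid_h, valid_w)) < gamma
        seeds[:, :, off : off + valid_h, off : off + valid_w] = region
        blocked = ndimage.maximum_filter(
            seeds.astype(np.float32), size=(1, 1, b, b), mode="constant"
        )
        mask = 1.0 - blocked
        keep = mask.mean()
        if keep == 0:
            return x * Tensor(mask)
        return x * Tensor(mask / keep)
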