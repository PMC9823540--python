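"""Layer modules built on the autograd core: Conv2d, BatchNorm2d, Module tree.

Modules hold named :class:`Parameter` leaves and optional non-trainable
buffers (BatchNorm running statistics).  ``state_dict``/``load_state_dict``
give flat name->array serialization used by the checkpoint format.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Parameter, Tensor, conv2d

__all__ = ["Module", "Conv2d", "BatchNorm2d"]


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        yield from self._params.values()
        for child in self._children.values():
            yield from child.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> "Module":
        self.training = True
        for c in self._children.values():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self._children.values():
            c.eval()
        return self

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            state[prefix + name] = p.data.copy()
        for name, b in self._buffers.items():
            state[prefix + name] = np.asarray(getattr(self, name)).copy()
        for cname, child in self._children.items():
            state.update(child.state_dict(prefix + cname + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._params.items():
            p.data = np.asarray(state[prefix + name], dtype=np.float64).copy()
        for name in self._buffers:
            value = np.asarray(state[prefix + name], dtype=np.float64).copy()
            self._buffers[name] = value
            object.__setattr__(self, name, value)
        for cname, child in self._children.items():
            child.load_state_dict(state, prefix + cname + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Stride-1 same-padding convolution; He-normal init from ``rng``."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            he_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels))
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel normalization over (batch, H, W).

    Training mode normalizes with batch statistics and updates running
    estimates; eval mode uses the running estimates as constants.  The
    normalization is composed from autograd primitives, so gradients flow
    through the batch statistics as in standard batch norm.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones((1, num_channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_channels, 1, 1)))
        self.eps = eps
        self.momentum = momentum
        self.register_buffer("running_mean", np.zeros((1, num_channels, 1, 1)))
        self.register_buffer("running_var", np.ones((1, num_channels, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (1 - m) * self._buffers[
                "running_mean"
            ] + m * mu.data
            self._buffers["running_var"] = (1 - m) * self._buffers[
                "running_var"
            ] + m * var.data
            object.__setattr__(self, "running_mean", self._buffers["running_mean"])
            object.__setattr__(self, "running_var", self._buffers["running_var"])
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self._buffers["running_mean"])) * (
                (Tensor(self._buffers["running_var"]) + self.eps) ** -0.5
            )
        return xhat * self.gamma + self.beta
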