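"""Layer modules on top of the autodiff core: parameter containers,
He-initialised convolutions, and an SGD optimiser with momentum and
weight decay (the classic formulation: decay added to the gradient)."""

from __future__ import annotations

import numpy as np

from . import core
from .core import Tensor


class Module:
    """Minimal parameter container; submodules are discovered by attribute."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch while loading weights")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch while loading weights")
            p.data = np.asarray(a, dtype=np.float32)


class Conv2d(Module):
    """3x3 / 2x2 / 1x1 convolution, stride 1, spatial-size preserving.

    Even kernels use asymmetric (0, k-1) padding so output size equals
    input size, keeping the fully-convolutional shape contract.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 std: float | None = None):
        # He-normal by default; output heads pass a small std so initial
        # logits start near zero (initial CE ~ ln 2), which keeps the full
        # momentum-SGD protocol stable at the default learning rate.
        fan_in = in_ch * kernel * kernel
        if std is None:
            std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        if kernel % 2:
            self.padding = kernel // 2
        else:
            self.padding = (0, kernel - 1, 0, kernel - 1)

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv2d(x, self.weight, self.bias, self.padding)


class ConvBlock(Module):
    """Two 3x3 convolutions, each followed by ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return core.relu(self.conv2(core.relu(self.conv1(x))))


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            if self.momentum:
                v *= self.momentum
                v += g
                g = v
            p.data -= self.lr * g
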