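"""Layer objects over the autodiff core: convolutions, batch norm, helpers.

Layers own their parameters (``Tensor`` objects with ``requires_grad=True``)
plus any non-trainable state (batch-norm running statistics).  ``state_dict``
and ``load_state_dict`` give flat name->array views used for checkpointing.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Layer:
    """Base class; subclasses register sublayers/parameters as attributes."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.parameters())
        return out

    def _named(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for k, v in vars(self).items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v.data
            elif isinstance(v, Layer):
                out.update(v._named(key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Layer):
                        out.update(item._named(f"{key}.{i}."))
            elif isinstance(v, np.ndarray) and k.startswith("running_"):
                out[key] = v
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return self._named()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self._named()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing arrays: {sorted(missing)[:5]} ...")
        for k, arr in own.items():
            src = np.asarray(state[k])
            if src.shape != arr.shape:
                raise ValueError(f"shape mismatch for {k}: {src.shape} vs {arr.shape}")
            arr[...] = src


class Conv2d(Layer):
    """Stride-1 same convolution; bias off by default (batch norm follows)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        dilation: int = 1,
        bias: bool = False,
        weight_decay: bool = True,
    ):
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU networks
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)),
            requires_grad=True,
        )
        self.weight.name = "conv.weight"
        self.weight_decay = weight_decay
        self.dilation = dilation
        self.bias: Optional[Tensor] = None
        if bias:
            self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2x2(Layer):
    """Kernel-2 stride-2 transposed convolution: doubles spatial dimensions."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, bias: bool = False):
        scale = np.sqrt(2.0 / (in_ch * 4))
        self.weight = Tensor(
            rng.normal(0.0, scale, (in_ch, out_ch, 2, 2)), requires_grad=True
        )
        self.weight.name = "upconv.weight"
        self.weight_decay = True
        self.bias: Optional[Tensor] = None
        if bias:
            self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return T.batchnorm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training,
            self.momentum,
            self.eps,
        )


class ConvBNReLU(Layer):
    """3x3 (or given kernel) convolution -> batch norm -> ReLU."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        rng: np.random.Generator,
        kernel: int = 3,
        dilation: int = 1,
    ):
        self.conv = Conv2d(in_ch, out_ch, kernel, rng, dilation=dilation)
        self.bn = BatchNorm2d(out_ch)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return T.relu(self.bn(self.conv(x), training))


class Adam:
    """Adam optimizer with optional decoupled-style L2 on flagged kernels.

    The L2 penalty ``l2 * ||w||^2`` contributes ``2 * l2 * w`` to the gradient
    of every convolution kernel whose layer was created with
    ``weight_decay=True``; biases and batch-norm affines are exempt.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        l2: float = 0.0,
        decay_params: Optional[list[Tensor]] = None,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.l2 = l2
        decay_ids = {id(p) for p in (decay_params or [])}
        self.decay_flags = [id(p) in decay_ids for p in params]
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if self.l2 > 0.0 and self.decay_flags[i]:
                g = g + 2.0 * self.l2 * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
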