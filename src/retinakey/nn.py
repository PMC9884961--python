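"""Layers and parameter containers for the keypoint network.

Modules hold named :class:`~retinakey.autodiff.Tensor` parameters and compose
into the encoder-decoder.  Everything operates on unbatched channel-first
feature maps (C, H, W); the training batch size is 1 throughout.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, channel_norm, conv2d

__all__ = ["Module", "Conv2d", "ChannelNorm", "ConvBlock", "SGD"]


class Module:
    """Base class: recursive parameter collection and train/eval flag."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> dict[str, Tensor]:
        out = dict(self._params)
        for cname, child in self._children.items():
            for pname, p in child.parameters().items():
                out[f"{cname}.{pname}"] = p
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state dict mismatch (missing={missing}, extra={extra})")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Conv2d(Module):
    """Stride-1 'same' convolution with He-normal initialisation."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(rng.normal(0.0, std, size=(cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class ChannelNorm(Module):
    """Per-channel spatial standardisation with a learned affine map.

    Equivalent to instance normalisation for batch size 1 — the statistics a
    batch-norm layer would see in this training regime.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((channels, 1, 1)), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return channel_norm(x, self.gamma, self.beta, self.eps)


class ConvBlock(Module):
    """conv3x3 -> norm -> ReLU, twice."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.norm1 = ChannelNorm(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.norm2 = ChannelNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(self.conv1(x)).relu()
        return self.norm2(self.conv2(x)).relu()


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay."""

    def __init__(self, params: dict[str, Tensor], lr: float = 0.01,
                 momentum: float = 0.9, weight_decay: float = 1e-3):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v = self._velocity[k]
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
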