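"""Spatially-varying context aggregation operators.

The key idea: instead of re-weighting features with a globally pooled factor,
predict a small depth-wise convolution kernel *from the feature map itself* and
use it to aggregate context.  Two operators are provided:

* :class:`SCAModule` — single-scale spatially-varying context aggregation: a
  key map (H, W, C) and a query map (H, W, s^2) are projected from the input by
  1x1 convolutions; their inner product over all H*W positions yields an
  (s^2, C) context kernel, which (after normalisation) modulates the input via
  depth-wise convolution, a point-wise convolution and a sigmoid gate.
* :class:`SAPCAModule` — the pyramid variant: the same predicted kernel drives
  three parallel depth-wise convolutions with dilation rates 1, 3 and 5; each
  branch produces a sigmoid gate and the gates are fused by element-wise sum,
  so the fused weight lies in (0, 3).

All tensors are channel-first: feature maps (C, H, W), kernels (C, s, s).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, conv2d, depthwise_conv2d
from .nn import Conv2d, Module

__all__ = [
    "project_key_query",
    "predict_context_kernel",
    "depthwise_dilated_conv",
    "SCAModule",
    "SAPCAModule",
    "sca_forward",
    "sapca_forward",
]


def project_key_query(X: Tensor, key_weights, query_weights,
                      key_bias=None, query_bias=None) -> tuple[Tensor, Tensor]:
    """1x1-convolve the input into a key map (C channels) and a query map
    (s^2 channels).

    ``key_weights`` is (C, C, 1, 1); ``query_weights`` is (s^2, C, 1, 1).
    """
    X = as_tensor(X)
    K = conv2d(X, as_tensor(key_weights), None if key_bias is None else as_tensor(key_bias))
    Q = conv2d(X, as_tensor(query_weights),
               None if query_bias is None else as_tensor(query_bias))
    return K, Q


def predict_context_kernel(K: Tensor, Q: Tensor, gamma: Tensor | None = None,
                           beta: Tensor | None = None, normalize: bool = True,
                           norm_mode: str = "channel", eps: float = 1e-5) -> Tensor:
    """Contract key and query maps over all spatial positions into a context
    kernel.

    With K' the (H*W, C) reshape of the key map and Q' the (H*W, s^2) reshape
    of the query map, the raw kernel is S' = Q'^T K' of shape (s^2, C) — entry
    (i, j) sums Q'(q, i) * K'(q, j) over every pixel q, so every pair of pixel
    locations interacts.  S' is then standardised ("channel": per output
    channel over its s^2 taps, the batch-size-1 batch-norm statistic;
    "global": over all s^2*C entries) with an optional learned affine map, and
    reshaped row-major to a (C, s, s) depth-wise kernel.
    """
    K, Q = as_tensor(K), as_tensor(Q)
    C, H, W = K.shape
    s2, Hq, Wq = Q.shape
    if (H, W) != (Hq, Wq):
        raise ValueError(f"key/query spatial mismatch: {(H, W)} vs {(Hq, Wq)}")
    s = int(round(np.sqrt(s2)))
    if s * s != s2 or s % 2 == 0:
        raise ValueError(f"query channel count {s2} is not an odd square")
    Kp = K.transpose(1, 2, 0).reshape(H * W, C)
    Qp = Q.transpose(1, 2, 0).reshape(H * W, s2)
    Sp = Qp.T @ Kp  # (s^2, C)
    if normalize:
        if norm_mode == "channel":
            mu = Sp.mean(axis=0, keepdims=True)
            var = ((Sp - mu) ** 2).mean(axis=0, keepdims=True)
        elif norm_mode == "global":
            mu = Sp.mean()
            var = ((Sp - mu) ** 2).mean()
        else:
            raise ValueError(f"unknown norm_mode {norm_mode!r}")
        Sp = (Sp - mu) / ((var + eps) ** 0.5)
        if gamma is not None:
            Sp = Sp * as_tensor(gamma)
        if beta is not None:
            Sp = Sp + as_tensor(beta)
    # row-major over the s^2 axis -> (s, s, C), then channel-first (C, s, s)
    return Sp.reshape(s, s, C).transpose(2, 0, 1)


def depthwise_dilated_conv(X: Tensor, S: Tensor, dilation: int = 1) -> Tensor:
    """Apply the (C, s, s) context kernel channel-by-channel at the given
    dilation rate; 'same' zero padding keeps the spatial size."""
    return depthwise_conv2d(as_tensor(X), as_tensor(S), dilation)


class SCAModule(Module):
    """Single-scale spatially-varying context aggregation."""

    def __init__(self, channels: int, kernel_size: int = 5,
                 rng: np.random.Generator | None = None,
                 norm_mode: str = "channel"):
        super().__init__()
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and positive")
        rng = np.random.default_rng(0) if rng is None else rng
        self.channels = channels
        self.kernel_size = kernel_size
        self.norm_mode = norm_mode
        self.key = Conv2d(channels, channels, 1, rng)
        self.query = Conv2d(channels, kernel_size ** 2, 1, rng)
        self.gamma = Tensor(np.ones((1, channels)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels)), requires_grad=True)
        self.pointwise = Conv2d(channels, channels, 1, rng)

    def context_kernel(self, X: Tensor) -> Tensor:
        K, Q = self.key(X), self.query(X)
        return predict_context_kernel(K, Q, self.gamma, self.beta,
                                      norm_mode=self.norm_mode)

    def gate(self, X: Tensor) -> Tensor:
        """The spatially-varying weight factor F in (0, 1)^(C, H, W)."""
        S = self.context_kernel(X)
        return self.pointwise(depthwise_dilated_conv(X, S, 1)).sigmoid()

    def __call__(self, X: Tensor) -> Tensor:
        return self.gate(X) * X


class SAPCAModule(Module):
    """Pyramid context aggregation: one shared predicted kernel, three dilated
    depth-wise branches whose sigmoid gates are summed."""

    def __init__(self, channels: int, kernel_size: int = 5,
                 dilations: tuple[int, ...] = (1, 3, 5),
                 rng: np.random.Generator | None = None,
                 norm_mode: str = "channel", presum_sigmoid: bool = False):
        super().__init__()
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and positive")
        if any(d < 1 for d in dilations):
            raise ValueError("dilations must be >= 1")
        rng = np.random.default_rng(0) if rng is None else rng
        self.channels = channels
        self.kernel_size = kernel_size
        self.dilations = tuple(dilations)
        self.norm_mode = norm_mode
        self.presum_sigmoid = presum_sigmoid
        self.key = Conv2d(channels, channels, 1, rng)
        self.query = Conv2d(channels, kernel_size ** 2, 1, rng)
        self.gamma = Tensor(np.ones((1, channels)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels)), requires_grad=True)
        self.branches = [Conv2d(channels, channels, 1, rng) for _ in dilations]

    def context_kernel(self, X: Tensor) -> Tensor:
        K, Q = self.key(X), self.query(X)
        return predict_context_kernel(K, Q, self.gamma, self.beta,
                                      norm_mode=self.norm_mode)

    def branch_gates(self, X: Tensor) -> list[Tensor]:
        S = self.context_kernel(X)
        gates = []
        for pw, d in zip(self.branches, self.dilations):
            pre = pw(depthwise_dilated_conv(X, S, d))
            gates.append(pre if self.presum_sigmoid else pre.sigmoid())
        return gates

    def gate(self, X: Tensor) -> Tensor:
        """Fused weight factor R = R1 + R2 + R3, elementwise in (0, 3)."""
        gates = self.branch_gates(X)
        R = gates[0]
        for g in gates[1:]:
            R = R + g
        return R.sigmoid() if self.presum_sigmoid else R

    def __call__(self, X: Tensor) -> Tensor:
        return self.gate(X) * X


def sca_forward(X, module: SCAModule) -> Tensor:
    """Functional alias for a configured :class:`SCAModule`."""
    return module(as_tensor(X))


def sapca_forward(X, module: SAPCAModule) -> Tensor:
    """Functional alias for a configured :class:`SAPCAModule`."""
    return module(as_tensor(X))
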