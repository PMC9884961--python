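"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The networks in this package are small (batch size 1, tens of channels), so a
compact tape-based engine (float64 by default; float32 selectable for faster
training) is both fast enough and precise enough for
finite-difference validation of every gradient path.  Only the operations the
keypoint network and its losses actually need are implemented: elementwise
arithmetic with broadcasting, matrix products, reductions, reshapes, 2-D
convolutions (standard and depth-wise dilated), 2x2 max pooling, bilinear
resampling and fancy indexing.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "set_default_dtype",
    "default_dtype",
    "as_tensor",
    "concat",
    "stack",
    "conv2d",
    "depthwise_conv2d",
    "maxpool2x2",
    "upsample_bilinear",
    "bilinear_sample",
    "logsumexp",
]


_DEFAULT_DTYPE = np.float64


def default_dtype():
    return _DEFAULT_DTYPE


def set_default_dtype(dtype) -> None:
    """Set the dtype newly created tensors use (float64 or float32)."""
    global _DEFAULT_DTYPE
    dtype = np.dtype(dtype).type
    if dtype not in (np.float64, np.float32):
        raise ValueError("dtype must be float32 or float64")
    _DEFAULT_DTYPE = dtype


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=default_dtype())
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(p for p in _parents if p.requires_grad)
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        order: list[Tensor] = []
        seen: set[int] = set()
        done: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be deep for long loss chains)
        while stack:
            node = stack[-1]
            if id(node) not in seen:
                seen.add(id(node))
                stack.extend(p for p in node._parents if id(p) not in seen)
                continue
            stack.pop()
            if id(node) not in done:
                done.add(id(node))
                order.append(node)
        self.grad = (np.ones_like(self.data) if grad is None
                     else np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))

        def bwd(g):
            self._accumulate(g * out.data)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bwd(g):
            self._accumulate(g / self.data)

        out._backward = bwd
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _parents=(self,))

        def bwd(g):
            self._accumulate(g * 0.5 / out.data)

        out._backward = bwd
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))

        def bwd(g):
            self._accumulate(g * s * (1.0 - s))

        out._backward = bwd
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))

        def bwd(g):
            self._accumulate(g * mask)

        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclipped."""
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))

        def bwd(g):
            self._accumulate(g * mask)

        out._backward = bwd
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bwd(g):
            self._accumulate(g.reshape(old))

        out._backward = bwd
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))

        def bwd(g):
            self._accumulate(g.transpose(inv))

        out._backward = bwd
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bwd
        return out

    # ----------------------------------------------------------- linear algebra
    def matmul(self, other: "Tensor"):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    __matmul__ = matmul


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def bwd(g):
        parts = np.moveaxis(g, axis, 0)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    out._backward = bwd
    return out


# --------------------------------------------------------------------- conv ops
def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 'same' cross-correlation (im2col + one matrix product).

    x: (Cin, H, W); w: (Cout, Cin, k, k) with odd k; b: (Cout,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    cin, H, W = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input has {cin}, kernel expects {cin_w}")
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw)))
    # (Cin, H, W, kh, kw) view -> (Cin*kh*kw, H*W) patch matrix
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = windows.transpose(0, 3, 4, 1, 2).reshape(cin * kh * kw, H * W)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out_data = (wmat @ cols).reshape(cout, H, W)
    parents = (x, w) if b is None else (x, w, as_tensor(b))
    if b is not None:
        b = parents[2]
        out_data += b.data[:, None, None]
    out = Tensor(out_data, _parents=parents)

    def bwd(g):
        gmat = g.reshape(cout, H * W)
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=1))
        if w.requires_grad:
            w._accumulate((gmat @ cols.T).reshape(w.data.shape))
        if x.requires_grad:
            gcols = (wmat.T @ gmat).reshape(cin, kh, kw, H, W)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i : i + H, j : j + W] += gcols[:, i, j]
            x._accumulate(gxp[:, ph : ph + H, pw : pw + W] if ph or pw else gxp)

    out._backward = bwd
    return out


def depthwise_conv2d(x: Tensor, kernel: Tensor, dilation: int = 1) -> Tensor:
    """Per-channel 'same' cross-correlation with a (C, k, k) kernel.

    Zero padding of (k-1)//2 * dilation preserves the spatial size; kernel taps
    are spaced ``dilation`` pixels apart (atrous convolution).
    """
    x, kernel = as_tensor(x), as_tensor(kernel)
    C, H, W = x.shape
    ck, kh, kw = kernel.shape
    if C != ck:
        raise ValueError(f"channel mismatch: input has {C}, kernel has {ck}")
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    ph, pw = (kh - 1) // 2 * dilation, (kw - 1) // 2 * dilation
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw)))
    out_data = np.zeros((C, H, W), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            out_data += kernel.data[:, i, j][:, None, None] * xp[
                :, i * dilation : i * dilation + H, j * dilation : j * dilation + W
            ]
    out = Tensor(out_data, _parents=(x, kernel))

    def bwd(g):
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i * dilation : i * dilation + H, j * dilation : j * dilation + W]
                if kernel.requires_grad:
                    if kernel.grad is None:
                        kernel.grad = np.zeros_like(kernel.data)
                    kernel.grad[:, i, j] += (g * patch).sum(axis=(1, 2))
                if gxp is not None:
                    gxp[
                        :, i * dilation : i * dilation + H, j * dilation : j * dilation + W
                    ] += kernel.data[:, i, j][:, None, None] * g
        if gxp is not None:
            x._accumulate(gxp[:, ph : ph + H, pw : pw + W] if ph or pw else gxp)

    out._backward = bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; H and W must be even."""
    x = as_tensor(x)
    C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial size")
    xr = x.data.reshape(C, H // 2, 2, W // 2, 2)
    out_data = xr.max(axis=(2, 4))
    # mask of (first) argmax positions; gradient split evenly across exact ties
    eq = xr == out_data[:, :, None, :, None]
    counts = eq.sum(axis=(2, 4), keepdims=True)
    mask = eq / counts
    out = Tensor(out_data, _parents=(x,))

    def bwd(g):
        gx = (mask * g[:, :, None, :, None]).reshape(C, H, W)
        x._accumulate(gx)

    out._backward = bwd
    return out


def _bilinear_weights(n_out: int, n_in: int):
    """align_corners=False resize sample positions, clamped to the grid."""
    coords = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    coords = np.clip(coords, 0, n_in - 1)
    lo = np.floor(coords).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = coords - lo
    return lo, hi, frac


_RESIZE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _resize_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense (n_out, n_in) 1-D bilinear interpolation operator."""
    key = (n_out, n_in, _DEFAULT_DTYPE)
    R = _RESIZE_CACHE.get(key)
    if R is None:
        lo, hi, frac = _bilinear_weights(n_out, n_in)
        R = np.zeros((n_out, n_in), dtype=_DEFAULT_DTYPE)
        rows = np.arange(n_out)
        np.add.at(R, (rows, lo), 1 - frac)
        np.add.at(R, (rows, hi), frac)
        _RESIZE_CACHE[key] = R
    return R


def upsample_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of a (C, H, W) tensor to (C, *out_hw).

    Separable: out = Ry @ x @ Rx^T per channel, with 1-D interpolation
    matrices Ry, Rx (align_corners=False convention).
    """
    x = as_tensor(x)
    C, H, W = x.shape
    Ho, Wo = out_hw
    Ry = _resize_matrix(Ho, H)
    Rx = _resize_matrix(Wo, W)
    out = Tensor(Ry @ x.data @ Rx.T, _parents=(x,))

    def bwd(g):
        x._accumulate(Ry.T @ g @ Rx)

    out._backward = bwd
    return out


def bilinear_sample(fmap: Tensor, points: np.ndarray) -> Tensor:
    """Sample a (C, H, W) map at sub-pixel (x, y) points -> (N, C).

    Points are constants (no gradient w.r.t. coordinates); out-of-bounds points
    raise, matching the keypoint-sampling contract.
    """
    fmap = as_tensor(fmap)
    C, H, W = fmap.shape
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    xs, ys = pts[:, 0], pts[:, 1]
    if np.any(xs < 0) or np.any(xs > W - 1) or np.any(ys < 0) or np.any(ys > H - 1):
        raise ValueError("keypoint outside feature-map bounds")
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    fx = (xs - x0)[:, None]
    fy = (ys - y0)[:, None]
    d = fmap.data
    out_data = (
        d[:, y0, x0].T * (1 - fx) * (1 - fy)
        + d[:, y0, x1].T * fx * (1 - fy)
        + d[:, y1, x0].T * (1 - fx) * fy
        + d[:, y1, x1].T * fx * fy
    )
    out = Tensor(out_data, _parents=(fmap,))

    def bwd(g):
        gm = np.zeros_like(d)
        for yy, xx, w in (
            (y0, x0, (1 - fx) * (1 - fy)),
            (y0, x1, fx * (1 - fy)),
            (y1, x0, (1 - fx) * fy),
            (y1, x1, fx * fy),
        ):
            np.add.at(gm, (slice(None), yy, xx), (g * w).T)
        fmap._accumulate(gm)

    out._backward = bwd
    return out


def channel_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel spatial standardisation of a (C, H, W) tensor with a
    learned affine map (instance normalisation at batch size 1), fused into a
    single tape node for speed."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    C, H, W = x.shape
    n = H * W
    mu = x.data.mean(axis=(1, 2), keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=(1, 2), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, _parents=(x, gamma, beta))

    def bwd(g):
        if beta.requires_grad:
            beta._accumulate(
                _unbroadcast(g, beta.data.shape)
            )
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if x.requires_grad:
            gh = g * gamma.data
            m1 = gh.mean(axis=(1, 2), keepdims=True)
            m2 = (gh * xhat).mean(axis=(1, 2), keepdims=True)
            x._accumulate(inv * (gh - m1 - xhat * m2))

    out._backward = bwd
    return out


def logsumexp(x: Tensor, axis=None) -> Tensor:
    """Numerically stable log-sum-exp built from primitive ops."""
    x = as_tensor(x)
    m = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(m)
    s = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if axis is not None:
        return s.reshape(np.squeeze(s.data, axis=axis).shape)
    return s.reshape(())
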