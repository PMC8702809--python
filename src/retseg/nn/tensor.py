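"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the segmentation network needs: broadcasted
add/mul, elementwise nonlinearities, stride-1 "same" (optionally dilated)
convolution via im2col, 2x2/stride-2 transposed convolution and max-pooling,
batch normalization, dropout, channel concatenation and reductions.  Layout is
NCHW throughout; parameters and activations are float32.

Convolution gradients avoid scatter-adds: for a stride-1 same convolution the
input gradient is itself a stride-1 same convolution of the output gradient
with the spatially flipped, channel-transposed kernel, so both directions run
through the same im2col matmul path.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

DTYPE = np.float32


class Tensor:
    """A NumPy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple = (),
        _backward: Optional[Callable[[], None]] = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray, fresh: bool = False) -> None:
        """Accumulate a gradient; `fresh` marks a newly allocated array that
        may be adopted without copying (it must not alias another tensor)."""
        if self.grad is None:
            g = np.asarray(g, dtype=DTYPE)
            self.grad = g if fresh and g.dtype == DTYPE else g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from a scalar output through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            if node._parents:
                # interior gradients are consumed by the node's own backward;
                # drop them (and the closure's buffer refs) to bound memory
                node.grad = None
                node._backward = None

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _const(-1.0)))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, _const(-1.0)))

    def __neg__(self):
        return mul(self, _const(-1.0))

    def item(self) -> float:
        return float(self.data)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _const(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=DTYPE))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to `shape` undoing NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, a.requires_grad or b.requires_grad, (a, b))

    def _bw():
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(out.grad, a.data.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(out.grad, b.data.shape))

    out._backward = _bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, a.requires_grad or b.requires_grad, (a, b))

    def _bw():
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(out.grad * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(out.grad * a.data, b.data.shape))

    out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))

    def _bw():
        x._accum(out.grad * (x.data > 0))

    out._backward = _bw
    return out


_SIGMOID_EPS = 1e-7


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic, clamped away from the endpoints so outputs
    # stay strictly inside (0, 1) even where float32 would round to 0 or 1
    e = np.exp(-np.abs(x.data))
    s = np.where(x.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    s = np.clip(s, _SIGMOID_EPS, 1.0 - _SIGMOID_EPS)
    out = Tensor(s, x.requires_grad, (x,))

    def _bw():
        x._accum(out.grad * s * (1.0 - s))

    out._backward = _bw
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), x.requires_grad, (x,))

    def _bw():
        x._accum(out.grad / x.data)

    out._backward = _bw
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with pass-through gradient inside [lo, hi], zero outside."""
    out = Tensor(np.clip(x.data, lo, hi), x.requires_grad, (x,))

    def _bw():
        inside = (x.data >= lo) & (x.data <= hi)
        x._accum(out.grad * inside)

    out._backward = _bw
    return out


def tsum(x: Tensor) -> Tensor:
    out = Tensor(x.data.sum(), x.requires_grad, (x,))

    def _bw():
        x._accum(np.broadcast_to(out.grad, x.data.shape))

    out._backward = _bw
    return out


def tmean(x: Tensor) -> Tensor:
    n = x.data.size
    out = Tensor(x.data.mean(), x.requires_grad, (x,))

    def _bw():
        x._accum(np.broadcast_to(out.grad / n, x.data.shape))

    out._backward = _bw
    return out


def concat(xs: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([x.data for x in xs], axis=axis)
    out = Tensor(data, any(x.requires_grad for x in xs), tuple(xs))
    sizes = [x.data.shape[axis] for x in xs]
    splits = np.cumsum(sizes)[:-1]

    def _bw():
        pieces = np.split(out.grad, splits, axis=axis)
        for x, g in zip(xs, pieces):
            x._accum(g)

    out._backward = _bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(DTYPE) / keep
    out = Tensor(x.data * mask, x.requires_grad, (x,))

    def _bw():
        x._accum(out.grad * mask, fresh=True)

    out._backward = _bw
    return out


# -- convolution ------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) columns for a stride-1 same convolution."""
    n, c, h, w = x.shape
    if k == 1:
        return x.reshape(n, c, h * w)
    eff = dilation * (k - 1) + 1
    pad = (eff - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            di, dj = i * dilation, j * dilation
            cols[:, :, i, j] = xp[:, :, di : di + h, dj : dj + w]
    return cols.reshape(n, c * k * k, h * w)


# above this size the im2col buffer is worth avoiding: use shift-and-add GEMMs
_IM2COL_BYTE_LIMIT = 48 * 1024 * 1024


def _conv_forward(x: np.ndarray, w: np.ndarray, dilation: int) -> np.ndarray:
    """Stride-1 same convolution; x (N,C,H,W), w (F,C,k,k) -> (N,F,H,W)."""
    n, c, h, wd = x.shape
    f, _, k, _ = w.shape
    if k == 1:
        return np.matmul(w.reshape(f, c)[None], x.reshape(n, c, h * wd)).reshape(
            n, f, h, wd
        )
    if 9 * c * h * wd * n * x.itemsize <= _IM2COL_BYTE_LIMIT:
        cols = _im2col(x, k, dilation)
        w2 = w.reshape(f, c * k * k)
        return np.matmul(w2[None], cols).reshape(n, f, h, wd)
    # shift-and-add: one GEMM per kernel tap on the contiguous, unpadded input
    pad = dilation * (k - 1) // 2
    out = np.zeros((n, f, h, wd), dtype=x.dtype)
    x3 = x.reshape(n, c, h * wd)
    for ki in range(k):
        si = ki * dilation - pad
        i0, i1 = max(0, -si), min(h, h - si)
        for kj in range(k):
            sj = kj * dilation - pad
            j0, j1 = max(0, -sj), min(wd, wd - sj)
            y = np.matmul(w[:, :, ki, kj][None], x3).reshape(n, f, h, wd)
            out[:, :, i0:i1, j0:j1] += y[:, :, i0 + si : i1 + si, j0 + sj : j1 + sj]
    return out


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None, dilation: int = 1) -> Tensor:
    """Stride-1 spatial-shape-preserving convolution with odd kernel size.

    The backward pass builds one im2col of the *output* gradient (usually far
    smaller than an im2col of the input) and reuses it for both the weight
    gradient and the input gradient, so no forward buffer is retained.
    """
    n, c, h, wd = x.data.shape
    f, cin, k, _ = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {cin}")
    if k % 2 == 0:
        raise ValueError("conv2d requires an odd kernel size")
    out_data = _conv_forward(x.data, w.data, dilation)
    if b is not None:
        out_data += b.data.reshape(1, f, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, True, parents)

    def _bw():
        g = out.grad
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        if k == 1:
            g2 = g.reshape(n, f, h * wd)
            x3 = x.data.reshape(n, c, h * wd)
            gw = np.matmul(g2, x3.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
            if x.requires_grad or x._parents:
                gx = np.matmul(w.data.reshape(f, c).T[None], g2)
                x._accum(gx.reshape(n, c, h, wd), fresh=True)
            return
        cols_g = _im2col(g, k, dilation)  # (N, F*k*k, H*W)
        # gw[f,c,ki,kj] = sum_px x[c,px] * gpad[f, px - s(ki,kj)]
        x3 = x.data.reshape(n, c, h * wd)
        m = np.matmul(x3, cols_g.transpose(0, 2, 1)).sum(axis=0)  # (C, F*k*k)
        gw = m.reshape(c, f, k, k)[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        w._accum(np.ascontiguousarray(gw))
        if x.requires_grad or x._parents:
            # gx = conv(g, w rotated): contract the same columns with w
            w_rot = w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
            w_rot2 = np.ascontiguousarray(w_rot).reshape(c, f * k * k)
            gx = np.matmul(w_rot2[None], cols_g).reshape(n, c, h, wd)
            x._accum(gx, fresh=True)

    out._backward = _bw
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Transposed convolution, kernel 2x2 stride 2: doubles height and width.

    Weight shape (C_in, C_out, 2, 2); each input pixel paints a 2x2 block, and
    with stride 2 the blocks tile without overlap.
    """
    n, c, h, wd = x.data.shape
    cin, f, _, _ = w.data.shape
    if cin != c:
        raise ValueError("conv_transpose2x2 channel mismatch")
    # out[n,f,2i+a,2j+b] = sum_c x[n,c,i,j] * w[c,f,a,b]: one GEMM per (a,b)
    # tap on the contiguous input, written into the strided output lattice
    x3 = x.data.reshape(n, c, h * wd)
    out_data = np.empty((n, f, 2 * h, 2 * wd), dtype=x.data.dtype)
    for a in range(2):
        for bb in range(2):
            y = np.matmul(w.data[:, :, a, bb].T[None], x3).reshape(n, f, h, wd)
            out_data[:, :, a::2, bb::2] = y
    if b is not None:
        out_data += b.data.reshape(1, f, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, True, parents)

    def _bw():
        if b is not None:
            b._accum(out.grad.sum(axis=(0, 2, 3)))
        need_gx = x.requires_grad or x._parents
        gx = np.zeros_like(x.data) if need_gx else None
        gw = np.empty_like(w.data)
        for a in range(2):
            for bb in range(2):
                g3 = np.ascontiguousarray(out.grad[:, :, a::2, bb::2]).reshape(
                    n, f, h * wd
                )
                gw[:, :, a, bb] = np.matmul(x3, g3.transpose(0, 2, 1)).sum(axis=0)
                if need_gx:
                    gx += np.matmul(w.data[:, :, a, bb][None], g3).reshape(
                        n, c, h, wd
                    )
        w._accum(gw, fresh=True)
        if need_gx:
            x._accum(gx, fresh=True)

    out._backward = _bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, x.requires_grad, (x,))

    def _bw():
        onehot = np.zeros_like(r)
        np.put_along_axis(onehot, idx[..., None], 1.0, axis=-1)
        g = onehot * out.grad[..., None]
        g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(g.reshape(n, c, h, w), fresh=True)

    out._backward = _bw
    return out


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    In training mode the batch statistics normalize and the running statistics
    are updated in place; in eval mode the running statistics normalize.
    """
    c = x.data.shape[1]
    g = gamma.data.reshape(1, c, 1, 1)
    bt = beta.data.reshape(1, c, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        var = x.data.var(axis=(0, 2, 3), keepdims=True)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu.reshape(c)
        running_var *= 1.0 - momentum
        running_var += momentum * var.reshape(c)
    else:
        mu = running_mean.reshape(1, c, 1, 1)
        var = running_var.reshape(1, c, 1, 1)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = Tensor(g * xhat + bt, True, (x, gamma, beta))

    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def _bw():
        go = out.grad
        gamma._accum((go * xhat).sum(axis=(0, 2, 3)))
        beta._accum(go.sum(axis=(0, 2, 3)))
        if not (x.requires_grad or x._parents):
            return
        gxhat = go * g
        if training:
            s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = inv_std / m * (m * gxhat - s1 - xhat * s2)
        else:
            gx = gxhat * inv_std
        x._accum(gx, fresh=True)

    out._backward = _bw
    return out


def collect_parameters(tensors: Iterable[Tensor]) -> list[Tensor]:
    return [t for t in tensors if t.requires_grad]
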