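"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set needed by the 2D encoder–decoder
segmentation networks and their training losses: broadcasting arithmetic,
matmul, exp/log/relu, reductions, gather, concatenation, 3x3 "same"
convolution (im2col, so the inner loop is a BLAS matmul), 2x2 max-pooling
and nearest-neighbour 2x upsampling.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which topologically sorts the recorded tape. All operations are
deterministic; dtype follows the input arrays (float32 in training,
float64 in gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, data, prev, backward) -> "Tensor":
        req = _GRAD_ENABLED[-1] and any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req, _prev=prev if req else ())
        if req:
            out._backward = backward
        return out

    def _acc(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            self._acc(_unbroadcast(g, self.data.shape))
            other._acc(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            self._acc(_unbroadcast(g * other.data, self.data.shape))
            other._acc(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            self._acc(_unbroadcast(g / other.data, self.data.shape))
            other._acc(
                _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._acc(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            self._acc(g @ other.data.T)
            other._acc(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # -------------------------------------------------------------- pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._acc(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._acc(g / self.data)

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0)

        def backward(g):
            self._acc(g * mask)

        return self._make(out_data, (self,), backward)

    def clip_min(self, lo: float):
        mask = self.data > lo
        out_data = np.where(mask, self.data, lo)

        def backward(g):
            self._acc(g * mask)

        return self._make(out_data, (self,), backward)

    # -------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        src = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            self._acc(g.reshape(src))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        out_data = np.transpose(self.data, axes)
        inv = np.argsort(axes)

        def backward(g):
            self._acc(np.transpose(g, inv))

        return self._make(out_data, (self,), backward)

    def take(self, indices):
        """Gather along the first axis (or fancy-index with a tuple)."""
        out_data = self.data[indices]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, indices, g)
            self._acc(full)

        return self._make(out_data, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        src = self.data.shape

        def backward(g):
            if axis is None:
                self._acc(np.broadcast_to(g, src).copy())
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._acc(np.broadcast_to(g, src).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    @staticmethod
    def cat(tensors, axis: int = 0) -> "Tensor":
        tensors = [Tensor._wrap(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._acc(g[tuple(sl)])

        proto = tensors[0]
        return proto._make(out_data, tuple(tensors), backward)

    # ----------------------------------------------------- spatial primitives
    @staticmethod
    def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
        """(N,C,H,W) -> (N*H*W, C*kh*kw) patches for 'same' stride-1 conv."""
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * kh * kw
        )

    def conv2d(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """Stride-1 'same' 2D convolution: x (N,Cin,H,W), w (Cout,Cin,kh,kw)."""
        x, w = self.data, weight.data
        n, cin, h, wd = x.shape
        cout, _, kh, kw = w.shape
        cols = self._im2col(x, kh, kw)
        wmat = w.reshape(cout, -1)
        out = cols @ wmat.T + bias.data
        out_data = out.reshape(n, h, wd, cout).transpose(0, 3, 1, 2)

        def backward(g):
            gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * wd, cout)
            weight._acc((gf.T @ cols).reshape(w.shape))
            bias._acc(gf.sum(axis=0))
            if self.requires_grad:
                # dx is the correlation of g with the flipped, transposed
                # kernel — a second im2col + matmul, BLAS-bound like forward
                wrot = np.ascontiguousarray(
                    w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                ).reshape(cin, cout * kh * kw)
                gcols = self._im2col(np.ascontiguousarray(g), kh, kw)
                dx = (gcols @ wrot.T).reshape(n, h, wd, cin).transpose(0, 3, 1, 2)
                self._acc(dx)

        return self._make(out_data, (self, weight, bias), backward)

    def maxpool2x2(self) -> "Tensor":
        n, c, h, w = self.data.shape
        h2, w2 = h // 2, w // 2
        xr = (
            self.data[:, :, : h2 * 2, : w2 * 2]
            .reshape(n, c, h2, 2, w2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2, w2, 4)
        )
        idx = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gr = np.zeros((n, c, h2, w2, 4), dtype=g.dtype)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = gr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            full = np.zeros_like(self.data)
            full[:, :, : h2 * 2, : w2 * 2] = gr.reshape(n, c, h2 * 2, w2 * 2)
            self._acc(full)

        return self._make(out_data, (self,), backward)

    def upsample2x(self) -> "Tensor":
        out_data = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)
        n, c, h, w = self.data.shape

        def backward(g):
            self._acc(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return self._make(out_data, (self,), backward)

    # -------------------------------------------------------------- reductions
    def softmax(self, axis: int = 1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = 1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    # --------------------------------------------------------------- autodiff
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
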