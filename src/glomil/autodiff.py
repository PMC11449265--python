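"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small convolutional networks (a per-slice encoder, a
patch encoder, gated attention and linear heads) and only needs a compact
set of differentiable primitives: broadcasting arithmetic, matmul, 2D
convolution, pointwise nonlinearities, reductions and a top-k mean used by
the saliency pooling.  Everything is dense float64/float32 numpy; there is
no graph compilation, no device handling.

Gradients are checked against central finite differences in the test
suite; any new primitive added here should get the same treatment.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "conv2d", "topk_mean"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims that were added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over dims that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- pointwise nonlinearities ----------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def tanh(self):
        y = np.tanh(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * (1.0 - y**2))

        return self._make(y, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        return self._make(y, (self,), backward)

    def exp(self):
        y = np.exp(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * y)

        return self._make(y, (self,), backward)

    def log(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero outside [lo, hi] (hard clip)."""
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * inside)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    def abs(self):
        s = np.sign(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * s)

        return self._make(np.abs(self.data), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, out):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, idx, g)
                self._accum(gx)

        return self._make(self.data[idx], (self,), backward)

    # -- reductions and shape ops ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g2, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g, out):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    # -- autodiff driver --------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad, t)

    def zero_grad(self):
        self.grad = None


# -- convolution ----------------------------------------------------------------


def _im2col_indices(x_shape, kh, kw, stride, padding):
    _, c, h, w = x_shape
    out_h = (h + 2 * padding - kh) // stride + 1
    out_w = (w + 2 * padding - kw) // stride + 1
    i0 = np.tile(np.repeat(np.arange(kh), kw), c)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j0 = np.tile(np.arange(kw), kh * c)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    k = np.repeat(np.arange(c), kh * kw).reshape(-1, 1)
    return k, i, j, out_h, out_w


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2D cross-correlation, NCHW layout, via an im2col gather.

    x: (N, C_in, H, W); weight: (C_out, C_in, kh, kw); bias: (C_out,).
    """
    n, c_in, h, w = x.data.shape
    c_out, c_in_w, kh, kw = weight.data.shape
    if c_in != c_in_w:
        raise ValueError(f"conv2d channel mismatch: input has {c_in}, weight expects {c_in_w}")
    k, i, j, out_h, out_w = _im2col_indices(x.data.shape, kh, kw, stride, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = xp[:, k, i, j]  # (N, C_in*kh*kw, out_h*out_w)
    wmat = weight.data.reshape(c_out, -1)
    out = wmat @ cols  # (N, C_out, out_h*out_w)
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1)
    out = out.reshape(n, c_out, out_h, out_w)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g, _):
        gr = g.reshape(n, c_out, -1)
        if bias is not None and bias.requires_grad:
            bias._accum(gr.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.einsum("ncl,nkl->ck", gr, cols)
            weight._accum(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = wmat.T @ gr  # (N, C_in*kh*kw, L)
            gxp = np.zeros_like(xp)
            np.add.at(gxp, (np.arange(n)[:, None, None], k, i, j), gcols)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    return Tensor._make(out, parents, backward)


def topk_mean(x: Tensor, n: int) -> Tensor:
    """Mean of the n largest entries of x (flattened).

    The gradient distributes 1/n to each pooled entry.  Ties at the n-th
    rank are resolved by numpy's partition order; the forward value does
    not depend on which of the tied entries is chosen.
    """
    flat = x.data.ravel()
    if n < 1 or n > flat.size:
        raise ValueError(f"topk_mean: n={n} out of range for {flat.size} entries")
    if n == flat.size:
        idx = np.arange(flat.size)
    else:
        idx = np.argpartition(-flat, n - 1)[:n]
    val = flat[idx].mean()

    def backward(g, _):
        if x.requires_grad:
            gf = np.zeros_like(flat)
            gf[idx] = float(g) / n
            x._accum(gf.reshape(x.data.shape))

    return Tensor._make(val, (x,), backward)


# -- optimizer --------------------------------------------------------------------


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
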