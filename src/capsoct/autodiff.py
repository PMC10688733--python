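"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set needed by the capsule network: broadcasted
arithmetic, matmul/einsum, 2-D convolution (im2col), elementwise
nonlinearities, reductions, reshapes, and a straight-through op for
non-differentiable enhancement layers.  Gradients are accumulated by
topological sort over the recorded graph; every op's backward pass is checked
against central finite differences in the test suite.

Arrays keep whatever float dtype they come in with (float32 for training,
float64 for gradient checks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _as_float(data):
    a = np.asarray(data)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad=False, name=None):
        self.data = _as_float(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()
        self.name = name

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g, dtype=self.data.dtype), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative post-order DFS: a recursive closure would reference
        # itself, creating a gc cycle that pins the whole graph in memory
        topo, seen = [], set()
        stack = [(self, False)]
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
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def bwd(g):
            self._accum(g)
            other._accum(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        out._parents = (self,)
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data)
        out._parents = (self, other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data)
        out._parents = (self, other)

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p):
        p = float(p)
        out = Tensor(self.data**p)
        out._parents = (self,)
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data)
        out._parents = (self, other)

        def bwd(g):
            self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out._backward = bwd
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0))
        out._parents = (self,)
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    # NB: backward closures must not capture `out` itself — that would make a
    # reference cycle (out -> _backward -> out) and per-step graphs carrying
    # large arrays would pile up until a full gc pass.  Capture the value.

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val)
        out._parents = (self,)
        out._backward = lambda g: self._accum(g * val * (1.0 - val))
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val)
        out._parents = (self,)
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data))
        out._parents = (self,)
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val)
        out._parents = (self,)
        out._backward = lambda g: self._accum(g * 0.5 / val)
        return out

    # -- reductions / reshapes --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out._parents = (self,)

        def bwd(g):
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape))
        out._parents = (self,)
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes))
        out._parents = (self,)
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out


def einsum(subscripts, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with autodiff (no ellipsis, no repeated indices)."""
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)
    ins, out_sub = subscripts.replace(" ", "").split("->")
    sa, sb = ins.split(",")
    out = Tensor(np.einsum(subscripts, a.data, b.data))
    out._parents = (a, b)

    def bwd(g):
        a._accum(np.einsum(f"{out_sub},{sb}->{sa}", g, b.data))
        b._accum(np.einsum(f"{out_sub},{sa}->{sb}", g, a.data))

    out._backward = bwd
    return out


def softmax(x: Tensor, axis=-1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def straight_through(x: Tensor, fn) -> Tensor:
    """Apply numpy function `fn` to the value; pass gradients through unchanged.

    Used for the in-network CLAHE layers: the tile-histogram mapping is
    piecewise constant, so its true Jacobian is zero almost everywhere and
    would stop all learning upstream of a mid-network enhancement layer.
    """
    out = Tensor(fn(x.data))
    if out.shape != x.shape:
        raise ValueError("straight_through requires a shape-preserving fn")
    out._parents = (x,)
    out._backward = lambda g: x._accum(g)
    return out


def _pad_amounts(in_size, k, stride, padding):
    if padding == "valid":
        return 0, 0
    out = -(-in_size // stride)  # ceil
    total = max((out - 1) * stride + k - in_size, 0)
    return total // 2, total - total // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding="valid") -> Tensor:
    """NHWC 2-D convolution via im2col.  w: (kh, kw, C, OC)."""
    B, H, W, C = x.shape
    kh, kw, wc, OC = w.shape
    if wc != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {wc}")
    pt, pb = _pad_amounts(H, kh, stride, padding)
    pl, pr = _pad_amounts(W, kw, stride, padding)
    if padding == "valid" and (kh > H or kw > W):
        raise ValueError("kernel larger than input under valid padding")
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    Ho, Wo = win.shape[1], win.shape[2]
    # win: (B, Ho, Wo, C, kh, kw) -> cols (B*Ho*Wo, kh*kw*C)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(B * Ho * Wo, kh * kw * C)
    wflat = w.data.reshape(kh * kw * C, OC)
    out_data = cols @ wflat
    if b is not None:
        out_data = out_data + b.data
    out = Tensor(out_data.reshape(B, Ho, Wo, OC))
    out._parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gflat = g.reshape(B * Ho * Wo, OC)
        w._accum((cols.T @ gflat).reshape(w.shape))
        if b is not None:
            b._accum(gflat.sum(axis=0))
        dcols = (gflat @ wflat.T).reshape(B, Ho, Wo, kh, kw, C)
        dxp = np.zeros_like(xp)
        for ki in range(kh):
            for kj in range(kw):
                dxp[
                    :,
                    ki : ki + stride * (Ho - 1) + 1 : stride,
                    kj : kj + stride * (Wo - 1) + 1 : stride,
                    :,
                ] += dcols[:, :, :, ki, kj, :]
        x._accum(dxp[:, pt : pt + H, pl : pl + W, :])

    out._backward = bwd
    return out


class Adam:
    """Adam with Keras-style per-step learning-rate decay lr/(1 + decay*t)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8, decay=0.0):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps, self.decay = lr, beta1, beta2, eps, decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * self.t)
        b1, b2 = self.beta1, self.beta2
        corr = lr_t * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= corr * m / (np.sqrt(v) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
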