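"""A minimal reverse-mode automatic-differentiation engine on NumPy arrays.

Covers exactly the operations the reconstruction network needs: 2-D
convolution, ReLU, sigmoid, broadcast add/multiply, channel concatenation,
pixel shuffle (sub-pixel recombination), global average pooling and MSE
loss.  Gradients are accumulated on a dynamically built tape; everything is
deterministic.

Array layout is NCHW throughout: (batch, channels, height, width).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "relu", "sigmoid", "add", "mul", "concat",
           "pixel_shuffle", "global_avg_pool", "mse_loss", "Adam"]


class Tensor:
    """A node of the computation graph wrapping a float ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Reverse-accumulate gradients from this node."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(parents)
    out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        ),
    )


def relu(x) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    return _make(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return _make(s, (x,), lambda g: (g * s * (1.0 - s),))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    edges = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, np.arange(edges[i], edges[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def conv2d(x, w, b=None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW input, OIHW weights."""
    x, w = _as_tensor(x), _as_tensor(w)
    n, c, h, wd = x.data.shape
    o, ci, kh, kw = w.data.shape
    assert ci == c, f"channel mismatch: input {c}, weights expect {ci}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    y = np.zeros((n, o, ho, wo))
    for i in range(kh):
        for j in range(kw):
            view = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
            y += np.einsum("nchw,oc->nohw", view, w.data[:, :, i, j], optimize=True)
    parents = [x, w]
    if b is not None:
        b = _as_tensor(b)
        y = y + b.data.reshape(1, -1, 1, 1)
        parents.append(b)

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                view = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
                dw[:, :, i, j] = np.einsum("nohw,nchw->oc", g, view, optimize=True)
                dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                    np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
                )
        dx = dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp
        grads = [dx, dw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return _make(y, parents, backward)


def pixel_shuffle(x, r: int = 2) -> Tensor:
    """Sub-pixel recombination: (N, C·r², H, W) → (N, C, rH, rW).

    Each group of r² channels is rearranged into an r×r spatial block, so
    the element count is conserved exactly.
    """
    x = _as_tensor(x)
    n, crr, h, w = x.data.shape
    assert crr % (r * r) == 0, f"channels {crr} not divisible by r^2={r*r}"
    c = crr // (r * r)
    y = (
        x.data.reshape(n, c, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, c, h * r, w * r)
    )

    def backward(g):
        gx = (
            g.reshape(n, c, h, r, w, r)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, crr, h, w)
        )
        return (gx,)

    return _make(y, (x,), backward)


def global_avg_pool(x) -> Tensor:
    """Mean over the spatial axes, keeping (N, C, 1, 1)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    y = x.data.mean(axis=(2, 3), keepdims=True)
    return _make(y, (x,), lambda g: (np.broadcast_to(g, x.data.shape) / (h * w),))


def mse_loss(pred, target) -> Tensor:
    """Mean squared error over every element."""
    pred = _as_tensor(pred)
    target = np.asarray(target.data if isinstance(target, Tensor) else target, dtype=float)
    diff = pred.data - target
    with np.errstate(over="ignore"):  # overflow -> inf signals divergence
        value = np.array(np.mean(diff**2))
    return _make(
        value,
        (pred,),
        lambda g: (g * 2.0 * diff / diff.size,),
    )


class Adam:
    """Adaptive-moment first-order optimiser (β1=0.9, β2=0.999)."""

    def __init__(self, params, lr: float = 4e-5, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
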