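"""A compact reverse-mode autodiff engine for small volumetric CNNs.

Tensors are float32 numpy arrays in channel-first layout ``(C, X, Y, Z)``.
Every op builds a node on a tape; :func:`backward` walks the tape in reverse
topological order.  The op set is exactly what an attention-gated residual
3-D U-Net needs: 3x3x3 / 1x1x1 convolutions, kernel-2 stride-2 transposed
convolution, max/average pooling by 2, ReLU, sigmoid, add, broadcast
multiply, channel concatenation and a masked mean-squared-error head.
"""

from __future__ import annotations

import numpy as np

F = np.float32


class Var:
    """A node in the computation graph."""

    __slots__ = ("v", "grad", "parents", "_bwd", "name")

    def __init__(self, value, parents=(), bwd=None, name=""):
        self.v = np.asarray(value, dtype=F)
        self.grad = None
        self.parents = tuple(parents)
        self._bwd = bwd
        self.name = name

    @property
    def shape(self):
        return self.v.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=F).copy()
        else:
            self.grad += g


def backward(loss: Var):
    """Reverse-mode sweep from a scalar loss node."""
    topo, seen = [], set()

    def visit(node):
        stack = [(node, False)]
        while stack:
            n, done = stack.pop()
            if done:
                topo.append(n)
                continue
            if id(n) in seen:
                continue
            seen.add(id(n))
            stack.append((n, True))
            for p in n.parents:
                stack.append((p, False))

    visit(loss)
    loss.grad = np.ones_like(loss.v)
    for node in reversed(topo):
        if node._bwd is not None and node.grad is not None:
            node._bwd(node.grad)


# ---------------------------------------------------------------------------
# Ops

from numba import njit


@njit(fastmath=True)
def _conv3_kernel(xp, W, out):
    """Direct 3x3x3 convolution over a padded volume (numba, z-unrolled)."""
    O, C = W.shape[0], W.shape[1]
    Xo, Yo, Zo = out.shape[1], out.shape[2], out.shape[3]
    for o in range(O):
        for c in range(C):
            for i in range(3):
                for j in range(3):
                    w0, w1, w2 = W[o, c, i, j, 0], W[o, c, i, j, 1], W[o, c, i, j, 2]
                    for xx in range(Xo):
                        for yy in range(Yo):
                            for zz in range(Zo):
                                out[o, xx, yy, zz] += (
                                    w0 * xp[c, xx + i, yy + j, zz]
                                    + w1 * xp[c, xx + i, yy + j, zz + 1]
                                    + w2 * xp[c, xx + i, yy + j, zz + 2]
                                )


@njit(fastmath=True)
def _conv3_wgrad(xp, g, dW):
    O, C = g.shape[0], xp.shape[0]
    Xo, Yo, Zo = g.shape[1], g.shape[2], g.shape[3]
    for o in range(O):
        for c in range(C):
            for i in range(3):
                for j in range(3):
                    a0 = np.float32(0.0)
                    a1 = np.float32(0.0)
                    a2 = np.float32(0.0)
                    for xx in range(Xo):
                        for yy in range(Yo):
                            for zz in range(Zo):
                                gv = g[o, xx, yy, zz]
                                a0 += gv * xp[c, xx + i, yy + j, zz]
                                a1 += gv * xp[c, xx + i, yy + j, zz + 1]
                                a2 += gv * xp[c, xx + i, yy + j, zz + 2]
                    dW[o, c, i, j, 0] = a0
                    dW[o, c, i, j, 1] = a1
                    dW[o, c, i, j, 2] = a2


def conv3(x: Var, W: Var, b: Var) -> Var:
    """Same-padded 3x3x3 convolution; ``W`` has shape (O, C, 3, 3, 3)."""
    C, X, Y, Z = x.v.shape
    O = W.v.shape[0]
    xp = np.pad(x.v, ((0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.broadcast_to(b.v[:, None, None, None], (O, X, Y, Z)).astype(F).copy()
    _conv3_kernel(xp, W.v, out)

    def bwd(g):
        g = np.ascontiguousarray(g, dtype=F)
        dW = np.empty_like(W.v)
        _conv3_wgrad(xp, g, dW)
        W.accumulate(dW)
        b.accumulate(g.sum(axis=(1, 2, 3)))
        gp = np.pad(g, ((0, 0), (1, 1), (1, 1), (1, 1)))
        Wt = np.ascontiguousarray(
            W.v[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        dx = np.zeros_like(x.v)
        _conv3_kernel(gp, Wt, dx)
        x.accumulate(dx)

    return Var(out, (x, W, b), bwd, "conv3")


def conv1(x: Var, W: Var, b: Var | None = None) -> Var:
    """1x1x1 convolution; ``W`` has shape (O, C)."""
    out = np.tensordot(W.v, x.v, axes=([1], [0]))
    if b is not None:
        out += b.v[:, None, None, None]

    def bwd(g):
        W.accumulate(np.tensordot(g, x.v, axes=((1, 2, 3), (1, 2, 3))))
        if b is not None:
            b.accumulate(g.sum(axis=(1, 2, 3)))
        x.accumulate(np.tensordot(W.v.T, g, axes=([1], [0])))

    parents = (x, W) if b is None else (x, W, b)
    return Var(out, parents, bwd, "conv1")


def upconv2(x: Var, W: Var, b: Var) -> Var:
    """Kernel-2 stride-2 transposed convolution; ``W``: (O, C, 2, 2, 2)."""
    C, X, Y, Z = x.v.shape
    O = W.v.shape[0]
    t = np.tensordot(W.v, x.v, axes=([1], [0]))                # (O,2,2,2,X,Y,Z)
    out = np.empty((O, 2 * X, 2 * Y, 2 * Z), dtype=F)
    for i in range(2):
        for j in range(2):
            for k in range(2):
                out[:, i::2, j::2, k::2] = t[:, i, j, k]
    out += b.v[:, None, None, None]

    def bwd(g):
        gW = np.empty_like(W.v)
        gx = np.zeros_like(x.v)
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    gs = g[:, i::2, j::2, k::2]                # (O,X,Y,Z)
                    gW[:, :, i, j, k] = np.tensordot(gs, x.v, axes=((1, 2, 3), (1, 2, 3)))
                    gx += np.tensordot(W.v[:, :, i, j, k].T, gs, axes=([1], [0]))
        W.accumulate(gW)
        b.accumulate(g.sum(axis=(1, 2, 3)))
        x.accumulate(gx)

    return Var(out, (x, W, b), bwd, "upconv2")


def _pool_view(a):
    C, X, Y, Z = a.shape
    r = a.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2)
    return r.transpose(0, 1, 3, 5, 2, 4, 6).reshape(C, X // 2, Y // 2, Z // 2, 8)


def _unpool(g8, shape):
    C, X, Y, Z = shape
    r = g8.reshape(C, X // 2, Y // 2, Z // 2, 2, 2, 2)
    return r.transpose(0, 1, 4, 2, 5, 3, 6).reshape(C, X, Y, Z)


def maxpool2(x: Var) -> Var:
    pv = _pool_view(x.v)
    idx = np.argmax(pv, axis=-1)
    out = np.take_along_axis(pv, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        g8 = np.zeros_like(pv)
        np.put_along_axis(g8, idx[..., None], g[..., None], axis=-1)
        x.accumulate(_unpool(g8, x.v.shape))

    return Var(out, (x,), bwd, "maxpool2")


def avgpool2(x: Var) -> Var:
    pv = _pool_view(x.v)
    out = pv.mean(axis=-1)

    def bwd(g):
        g8 = np.broadcast_to(g[..., None] / 8.0, pv.shape)
        x.accumulate(_unpool(np.ascontiguousarray(g8), x.v.shape))

    return Var(out, (x,), bwd, "avgpool2")


def relu(x: Var) -> Var:
    mask = x.v > 0
    out = x.v * mask

    def bwd(g):
        x.accumulate(g * mask)

    return Var(out, (x,), bwd, "relu")


def sigmoid(x: Var) -> Var:
    out = 1.0 / (1.0 + np.exp(-np.clip(x.v, -60.0, 60.0)))

    def bwd(g):
        x.accumulate(g * out * (1.0 - out))

    return Var(out, (x,), bwd, "sigmoid")


def add(a: Var, b: Var) -> Var:
    out = a.v + b.v

    def bwd(g):
        a.accumulate(g)
        b.accumulate(g)

    return Var(out, (a, b), bwd, "add")


def mul(a: Var, b: Var) -> Var:
    """Elementwise product with channel broadcasting (gating)."""
    out = a.v * b.v

    def bwd(g):
        ga = g * b.v
        gb = g * a.v
        if a.v.shape != out.shape:
            ga = ga.sum(axis=0, keepdims=True) if a.v.shape[0] == 1 else ga
        if b.v.shape != out.shape:
            gb = gb.sum(axis=0, keepdims=True) if b.v.shape[0] == 1 else gb
        a.accumulate(ga)
        b.accumulate(gb)

    return Var(out, (a, b), bwd, "mul")


def concat(a: Var, b: Var) -> Var:
    ca = a.v.shape[0]
    out = np.concatenate([a.v, b.v], axis=0)

    def bwd(g):
        a.accumulate(g[:ca])
        b.accumulate(g[ca:])

    return Var(out, (a, b), bwd, "concat")


def masked_mse(pred: Var, target: np.ndarray, mask: np.ndarray) -> Var:
    """Mean over masked voxels of the squared residual summed over channels."""
    m = np.asarray(mask, dtype=F)
    if m.sum() == 0:
        raise ValueError("mask selects no voxels")
    diff = (pred.v - np.asarray(target, dtype=F)) * m[None]
    n = m.sum()
    out = np.array((diff**2).sum() / n, dtype=F)

    def bwd(g):
        pred.accumulate(g * 2.0 * diff / n)

    return Var(out, (pred,), bwd, "masked_mse")


# ---------------------------------------------------------------------------
# Parameters and optimizer

class Param(Var):
    """A trainable leaf tensor."""

    def __init__(self, value, name=""):
        super().__init__(value, (), None, name)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, s in zip(self.params, self.m, self.s):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            s *= self.b2
            s += (1 - self.b2) * g * g
            p.v -= self.lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
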