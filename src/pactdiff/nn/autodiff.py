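"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A ``Tensor`` wraps an ndarray and records the operations producing it; a
single call to :meth:`Tensor.backward` walks the graph in reverse
topological order and accumulates gradients.  The op set is exactly what
the restoration network needs: broadcast arithmetic, matmul, pointwise
nonlinearities, reductions, shape manipulation, stable softmax, im2col
convolution, average pooling and nearest-neighbor upsampling.  Gradients of
every op are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "selective_scan"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- pointwise nonlinearities -----------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        # tanh form avoids overflow of exp(-x) for large negative inputs
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def silu(self):
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        out_data = self.data * sig

        def backward(g):
            self._accum(g * (sig + self.data * sig * (1.0 - sig)))

        return self._make(out_data, (self,), backward)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            self._accum(g * sig)

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    # -- reductions and shape ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    # -- convolution / pooling ---------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None, padding: int = 0):
        """2D cross-correlation, stride 1.  x: (B,C,H,W), weight: (O,C,kh,kw)."""
        x = self.data
        w = weight.data
        B, C, H, W = x.shape
        O, Cw, kh, kw = w.shape
        if Cw != C:
            raise ValueError(f"weight expects {Cw} channels, input has {C}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
        view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
        wmat = w.reshape(O, C * kh * kw)
        out = cols @ wmat.T
        if bias is not None:
            out = out + bias.data[None, :]
        out_data = out.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
        out_data = np.ascontiguousarray(out_data)

        def backward(g):
            g2 = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
            if weight.requires_grad:
                gw = (g2.T @ cols).reshape(O, C, kh, kw)
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g2.sum(axis=0))
            if self.requires_grad:
                gcols = (g2 @ wmat).reshape(B, Ho, Wo, C, kh, kw)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + Ho, j : j + Wo] += gcols[
                            :, :, :, :, i, j
                        ].transpose(0, 3, 1, 2)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                self._accum(gxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, parents, backward)

    def avg_pool2d(self, r: int):
        """Non-overlapping r x r average pooling; spatial dims must divide r."""
        B, C, H, W = self.data.shape
        if H % r or W % r:
            raise ValueError(f"spatial dims ({H},{W}) not divisible by r={r}")
        out_data = self.data.reshape(B, C, H // r, r, W // r, r).mean(axis=(3, 5))

        def backward(g):
            gx = np.repeat(np.repeat(g, r, axis=2), r, axis=3) / (r * r)
            self._accum(gx)

        return self._make(out_data, (self,), backward)

    def upsample_nearest(self, r: int):
        out_data = np.repeat(np.repeat(self.data, r, axis=2), r, axis=3)

        def backward(g):
            B, C, H, W = self.data.shape
            gx = g.reshape(B, C, H, r, W, r).sum(axis=(3, 5))
            self._accum(gx)

        return self._make(out_data, (self,), backward)


def selective_scan(u: Tensor, delta: Tensor, A: Tensor, Bs: Tensor, Cs: Tensor) -> Tensor:
    """Fused diagonal selective-SSM scan with an analytic backward pass.

    Shapes: u, delta (B, L, D); A (D, N) strictly negative; Bs, Cs (B, L, N).
    Per step (exact zero-order hold on the diagonal dynamics):

        dA   = exp(delta * A)
        phi  = (dA - 1) / A                    (per-entry Bbar factor)
        h_l  = dA_l * h_{l-1} + phi_l * Bs_l * u_l
        y_l  = sum_n h_l * Cs_l

    The backward pass reverses the recurrence analytically instead of
    recording L graph nodes, which keeps long scans cheap.
    """
    u, delta, A, Bs, Cs = (_as_tensor(t) for t in (u, delta, A, Bs, Cs))
    B, L, D = u.shape
    N = A.shape[1]
    ud, dd, Ad, Bd, Cd = u.data, delta.data, A.data, Bs.data, Cs.data
    dA = np.exp(dd[..., None] * Ad)  # (B, L, D, N)
    phi = (dA - 1.0) / Ad
    bu = phi * Bd[:, :, None, :] * ud[..., None]
    h = np.empty((B, L, D, N), dtype=ud.dtype)
    prev = np.zeros((B, D, N), dtype=ud.dtype)
    for l in range(L):
        prev = dA[:, l] * prev + bu[:, l]
        h[:, l] = prev
    y = (h * Cd[:, :, None, :]).sum(axis=3)  # (B, L, D)

    def backward(gy):
        gC = (gy[..., None] * h).sum(axis=2) if Cs.requires_grad else None
        gh = gy[..., None] * Cd[:, :, None, :]  # direct dL/dh term, (B,L,D,N)
        G = np.empty_like(gh)
        acc = np.zeros((B, D, N), dtype=gh.dtype)
        for l in range(L - 1, -1, -1):
            acc = gh[:, l] + (dA[:, l + 1] * acc if l + 1 < L else 0.0)
            G[:, l] = acc
        h_prev = np.concatenate(
            [np.zeros((B, 1, D, N), dtype=h.dtype), h[:, :-1]], axis=1
        )
        g_dA = G * h_prev
        g_bu = G
        g_phi = g_bu * Bd[:, :, None, :] * ud[..., None]
        g_dA = g_dA + g_phi / Ad  # phi = (dA - 1)/A
        if u.requires_grad:
            u._accum((g_bu * phi * Bd[:, :, None, :]).sum(axis=3))
        if Bs.requires_grad:
            Bs._accum((g_bu * phi * ud[..., None]).sum(axis=2))
        if Cs.requires_grad and gC is not None:
            Cs._accum(gC)
        if delta.requires_grad:
            delta._accum((g_dA * dA * Ad).sum(axis=3))
        if A.requires_grad:
            dphi_dA = dd[..., None] * dA / Ad - (dA - 1.0) / Ad**2
            gA = (g_dA - g_phi / Ad) * dA * dd[..., None] + g_phi * dphi_dA
            A._accum(gA.sum(axis=(0, 1)))

    out = Tensor(y)
    parents = (u, delta, A, Bs, Cs)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = backward
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, k, axis=axis))

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out
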