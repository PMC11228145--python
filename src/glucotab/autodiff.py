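"""Compact reverse-mode tensor autodiff on NumPy arrays.

Supports exactly the operations the attentive tabular network needs:
broadcast arithmetic, matmul, GLU nonlinearities, axis reductions,
row/column slicing and concatenation, and the simplex projections used for
attention (plain and capped sparsemax, with their exact Jacobian-vector
products on the free support).  Parameters are ``Tensor`` objects with
``requires_grad=True``; :meth:`Tensor.backward` runs topological-order
accumulation.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph machinery ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float, copy=True)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(g, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bwd
        return out

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self ** -1.0)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -50, 50)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * s * (1 - s))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / self.data)
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    # -- reductions / reshaping ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def rows(self, start: int, stop: int) -> "Tensor":
        out = Tensor(self.data[start:stop], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[start:stop] = g
                self._accumulate(full)

        out._backward = bwd
        return out

    def cols(self, start: int, stop: int) -> "Tensor":
        out = Tensor(self.data[:, start:stop], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, start:stop] = g
                self._accumulate(full)

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(np.asarray(data, dtype=float), requires_grad=True)


def concat_rows(parts: list[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=0), parents=tuple(parts))
    sizes = [len(p.data) for p in parts]

    def bwd(g):
        start = 0
        for p, s in zip(parts, sizes):
            if p.requires_grad:
                p._accumulate(g[start:start + s])
            start += s

    out._backward = bwd
    return out


def concat_cols(parts: list[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=1), parents=tuple(parts))
    sizes = [p.data.shape[1] for p in parts]

    def bwd(g):
        start = 0
        for p, s in zip(parts, sizes):
            if p.requires_grad:
                p._accumulate(g[:, start:start + s])
            start += s

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Simplex projections
# ---------------------------------------------------------------------------

def sparsemax_np(z: np.ndarray) -> np.ndarray:
    """Row-wise Euclidean projection onto the probability simplex
    (sorted-threshold algorithm); exact zeros allowed."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    srt = np.sort(z, axis=1)[:, ::-1]
    cum = np.cumsum(srt, axis=1) - 1.0
    k = np.arange(1, z.shape[1] + 1)
    support = srt * k > cum
    k_star = support.sum(axis=1)
    tau = cum[np.arange(len(z)), k_star - 1] / k_star
    return np.maximum(z - tau[:, None], 0.0)


def capped_sparsemax_np(
    z: np.ndarray, cap: np.ndarray, tol: float = 1e-12, iters: int = 80
) -> np.ndarray:
    """Row-wise projection onto {0 <= p <= cap, sum p = 1} by bisection on
    the threshold tau (sum of clip(z - tau, 0, cap) is monotone in tau).

    Rows whose caps sum to < 1 are infeasible; they fall back to the caps
    normalised to sum 1 (uniform if all caps vanish).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    cap = np.broadcast_to(np.asarray(cap, dtype=float), z.shape)
    capsum = cap.sum(axis=1)
    feasible = capsum >= 1.0 - 1e-12

    lo = (z - cap).min(axis=1) - 1.0
    hi = z.max(axis=1)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        s = np.clip(z - mid[:, None], 0.0, cap).sum(axis=1)
        take_hi = s > 1.0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
        if float(np.abs(s - 1.0).max(initial=0.0)) < tol and _ > 40:
            break
    p = np.clip(z - (0.5 * (lo + hi))[:, None], 0.0, cap)

    if not feasible.all():
        bad = ~feasible
        denom = np.where(capsum[bad] > 0, capsum[bad], 1.0)[:, None]
        fallback = np.where(
            capsum[bad, None] > 0, cap[bad] / denom, 1.0 / z.shape[1]
        )
        p[bad] = fallback
    return p


def capped_sparsemax(t: Tensor, cap: np.ndarray) -> Tensor:
    """Autodiff wrapper; the JVP spreads the residual over the free support
    {0 < p < cap} (coordinates pinned at 0 or at their cap get no gradient;
    the caps themselves are treated as constants)."""
    p = capped_sparsemax_np(t.data, cap)
    out = Tensor(p, parents=(t,))
    free = (p > 0) & (p < np.broadcast_to(cap, p.shape) - 1e-14)

    def bwd(g):
        if not t.requires_grad:
            return
        nfree = free.sum(axis=1, keepdims=True)
        nfree = np.where(nfree == 0, 1, nfree)
        mean_free = (g * free).sum(axis=1, keepdims=True) / nfree
        t._accumulate((g - mean_free) * free)

    out._backward = bwd
    return out


class Adam:
    """Adam over a list of parameter tensors, with optional step lr decay."""

    def __init__(self, params: list[Tensor], lr: float = 0.02,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
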