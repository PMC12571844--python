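"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The matching network is small (a few dense layers, a width-3 token
convolution, attention pooling and a Bi-GRU) and runs on CPU, so a compact
tape-based engine over batched ``float32`` arrays is all that is needed.
Every primitive has a closed-form vector-Jacobian product and is covered by
finite-difference gradient checks in the test suite.

Conventions
-----------
* :class:`Tensor` wraps an ``ndarray``; ``requires_grad`` marks leaves that
  accumulate gradients during :meth:`Tensor.backward`.
* Broadcasting in ``+`` and ``*`` is supported; gradients are summed back
  over broadcast axes.
* All floating data is kept in a single dtype (default ``float32``); the
  straight-line oracle implementations in the test-suite use ``float64``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _as_array(x, dtype=DTYPE) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != dtype and np.issubdtype(a.dtype, np.floating):
        a = a.astype(dtype)
    elif not np.issubdtype(a.dtype, np.floating):
        a = a.astype(dtype)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjp = _vjp  # callable(grad_out) -> tuple of parent grads (or None)

    # -- construction -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd core ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads = {id(self): _as_array(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None:
                    continue
                key = id(p)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjp) -> Tensor:
    return Tensor(data, _parents=parents, _vjp=vjp)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data
    ash, bsh = a.data.shape, b.data.shape
    return _node(out, (a, b), lambda g: (_unbroadcast(g, ash), _unbroadcast(g, bsh)))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data
    ash, bsh = a.data.shape, b.data.shape
    ad, bd = a.data, b.data
    return _node(out, (a, b),
                 lambda g: (_unbroadcast(g * bd, ash), _unbroadcast(g * ad, bsh)))


def matmul(a, b) -> Tensor:
    """Matrix product; stacked leading axes on ``a`` are flattened so both
    the product and its gradients run as single GEMMs."""
    a, b = as_tensor(a), as_tensor(b)
    ad, bd = a.data, b.data
    if ad.ndim > 2 and bd.ndim == 2:
        lead = ad.shape[:-1]
        a2 = ad.reshape(-1, ad.shape[-1])
        out = (a2 @ bd).reshape(*lead, bd.shape[1])

        def vjp(g):
            g2 = g.reshape(-1, bd.shape[1])
            return (g2 @ bd.T).reshape(ad.shape), a2.T @ g2

        return _node(out, (a, b), vjp)

    out = ad @ bd

    def vjp(g):
        ga = g @ np.swapaxes(bd, -1, -2)
        gb = np.swapaxes(ad, -1, -2) @ g
        return _unbroadcast(ga, ad.shape), _unbroadcast(gb, bd.shape)

    return _node(out, (a, b), vjp)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return _node(a.data * mask, (a,), lambda g: (g * mask,))


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = np.tanh(a.data)
    return _node(out, (a,), lambda g: (g * (1.0 - out * out),))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _node(out, (a,), lambda g: (g * out * (1.0 - out),))


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(out, tuple(tensors), vjp)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.data.shape
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(old),))


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)
    sh = a.data.shape

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, sh).copy(),)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, sh).copy(),)

    return _node(out, (a,), vjp)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def _scatter_add_rows(ids: np.ndarray, g: np.ndarray, nrows: int) -> np.ndarray:
    """Accumulate rows of ``g`` into an (nrows, d) zero array at ``ids``
    (duplicates sum).  Sparse matmul is much faster than ``np.add.at``."""
    from scipy import sparse
    flat_ids = ids.reshape(-1)
    g2 = np.ascontiguousarray(g.reshape(len(flat_ids), -1))
    S = sparse.csr_matrix(
        (np.ones(len(flat_ids), dtype=g2.dtype), flat_ids,
         np.arange(len(flat_ids) + 1)), shape=(len(flat_ids), nrows))
    return np.asarray(S.T @ g2)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather; the gradient scatter-adds into the table."""
    ids = np.asarray(ids)
    out = table.data[ids]
    nrows = table.data.shape[0]

    def vjp(g):
        return (_scatter_add_rows(ids, g, nrows),)

    return _node(out, (table,), vjp)


def masked_softmax(scores, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over positions where ``mask`` is truthy.

    Fully masked slices yield all-zero weights (callers decide what an empty
    attention window means; here it never produces NaN).
    """
    scores = as_tensor(scores)
    m = np.asarray(mask, dtype=bool)
    s = np.where(m, scores.data, -np.inf)
    smax = np.max(s, axis=axis, keepdims=True)
    smax = np.where(np.isfinite(smax), smax, 0.0)
    e = np.exp(s - smax)
    e = np.where(m, e, 0.0)
    denom = e.sum(axis=axis, keepdims=True)
    safe = np.where(denom > 0, denom, 1.0)
    out = e / safe

    def vjp(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return _node(out, (scores,), vjp)


def getitem(a, idx) -> Tensor:
    """Basic (slice/integer-array) indexing with scatter-add gradient."""
    a = as_tensor(a)
    out = a.data[idx]
    sh = a.data.shape
    plain = isinstance(idx, (int, slice)) or (
        isinstance(idx, tuple) and all(isinstance(i, (int, slice)) for i in idx))
    row_gather = (isinstance(idx, np.ndarray) and idx.ndim == 1
                  and np.issubdtype(idx.dtype, np.integer))

    def vjp(g):
        if row_gather:
            return (_scatter_add_rows(idx, g, sh[0]).reshape(sh),)
        ga = np.zeros(sh, dtype=g.dtype)
        if plain:            # unique destinations: plain assignment-add
            ga[idx] += g
        else:
            np.add.at(ga, idx, g)
        return (ga,)

    return _node(np.ascontiguousarray(out), (a,), vjp)


def shift_windows(E, M: int) -> Tensor:
    """(N, L, d) -> (N, L, (2M+1)d): per position the concatenation of the
    embeddings at offsets -M..M, reading zeros past either boundary (the
    im2col of a width-(2M+1) 'same' token convolution)."""
    E = as_tensor(E)
    N, L, d = E.data.shape
    win = 2 * M + 1
    out = np.zeros((N, L, win * d), dtype=E.data.dtype)
    for j, k in enumerate(range(-M, M + 1)):
        blk = out[:, :, j * d:(j + 1) * d]
        if k < 0:
            blk[:, -k:] = E.data[:, :L + k]
        elif k > 0:
            blk[:, :L - k] = E.data[:, k:]
        else:
            blk[:] = E.data

    def vjp(g):
        ga = np.zeros((N, L, d), dtype=g.dtype)
        for j, k in enumerate(range(-M, M + 1)):
            blk = g[:, :, j * d:(j + 1) * d]
            if k < 0:
                ga[:, :L + k] += blk[:, -k:]
            elif k > 0:
                ga[:, k:] += blk[:, :L - k]
            else:
                ga += blk
        return (ga,)

    return _node(out, (E,), vjp)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def vjp(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in parts)

    return _node(out, tuple(tensors), vjp)


def scatter_rows(src, row_idx: np.ndarray, col_idx: np.ndarray,
                 shape: tuple) -> Tensor:
    """Place row ``n`` of ``src`` at ``out[row_idx[n], col_idx[n]]`` in a
    zero tensor of ``shape`` (B, K, d).  Index pairs must be unique."""
    src = as_tensor(src)
    out = np.zeros(shape, dtype=src.data.dtype)
    out[row_idx, col_idx] = src.data
    return _node(out, (src,), lambda g: (g[row_idx, col_idx],))


def masked_max(a, mask: np.ndarray, axis: int) -> Tensor:
    """Max over unmasked positions; gradient flows to the (first) argmax."""
    a = as_tensor(a)
    m = np.asarray(mask, dtype=bool)
    s = np.where(m, a.data, -np.inf)
    out = s.max(axis=axis)
    arg = np.expand_dims(s.argmax(axis=axis), axis)

    def vjp(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, arg, np.expand_dims(g, axis), axis=axis)
        return (ga,)

    return _node(out, (a,), vjp)


def dropout(a, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: scales kept units by 1/(1-rate) at train time."""
    a = as_tensor(a)
    if not training or rate <= 0.0:
        return a
    keep = (rng.random(a.data.shape) >= rate).astype(a.data.dtype) / (1.0 - rate)
    return mul(a, Tensor(keep))


def bce_with_logits(logits, labels) -> Tensor:
    """Mean binary cross-entropy on logits (numerically stable)."""
    logits = as_tensor(logits)
    y = _as_array(labels, dtype=logits.data.dtype)
    z = logits.data
    # log(1+e^{-|z|}) + max(z,0) - z*y
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = np.array(loss.mean(), dtype=z.dtype)
    n = z.size
    p = 1.0 / (1.0 + np.exp(-z))

    def vjp(g):
        return (g * (p - y) / n,)

    return _node(out, (logits,), vjp)


# ---------------------------------------------------------------------------
# parameters and optimisation
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    """A named leaf tensor updated by the optimiser."""

    __slots__ = ("name",)

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True)
        self.name = name


class Adam:
    """Adam with optional L2 weight decay added to the raw gradient."""

    def __init__(self, params: list[Parameter], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0, decay_filter=None):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.decay_filter = decay_filter or (lambda p: True)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and self.decay_filter(p):
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
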