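"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the molecular GNN needs: dense affine
maps, rectifier/logistic nonlinearities, row gather (embedding lookup),
segment sum/mean (neighborhood aggregation and graph pooling), row-wise
L2 normalization, fused numerically-stable binary and categorical
cross-entropies, and inverted dropout. Gradients are accumulated by
reverse topological traversal; every op is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "matmul",
    "relu",
    "concat",
    "gather",
    "segment_sum",
    "segment_mean",
    "l2_normalize_rows",
    "row_dot",
    "dropout",
    "scale",
    "add_scalars",
    "batch_norm_rows",
    "bce_with_logits",
    "cross_entropy",
    "sigmoid",
    "Adam",
    "glorot",
]


class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad=False, name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def detach(self):
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"


def _needs(*tensors):
    return any(t.requires_grad or t._parents for t in tensors)


def _wrap(data, parents, backward):
    out = Tensor(data)
    if _needs(*parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g, shape):
    """Sum gradient over axes that were broadcast to reach ``g.shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _wrap(data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _wrap(data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        a._accumulate(g * mask)

    return _wrap(data, (a,), backward)


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    data = np.concatenate([a.data, b.data], axis=axis)
    na = a.data.shape[axis]

    def backward(g):
        ga, gb = np.split(g, [na], axis=axis)
        a._accumulate(ga)
        b._accumulate(gb)

    return _wrap(data, (a, b), backward)


def gather(table: Tensor, idx) -> Tensor:
    """Row lookup ``table[idx]`` (embedding lookup); scatter-add backward."""
    idx = np.asarray(idx, dtype=np.intp)
    data = table.data[idx]

    def backward(g):
        acc = np.zeros_like(table.data)
        np.add.at(acc, idx, g)
        table._accumulate(acc)

    return _wrap(data, (table,), backward)


def segment_sum(values: Tensor, seg_ids, n_segments: int) -> Tensor:
    """Sum rows of ``values`` into ``n_segments`` buckets given by seg_ids."""
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    data = np.zeros((n_segments,) + values.data.shape[1:])
    np.add.at(data, seg_ids, values.data)

    def backward(g):
        values._accumulate(g[seg_ids])

    return _wrap(data, (values,), backward)


def segment_mean(values: Tensor, seg_ids, n_segments: int) -> Tensor:
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    counts = np.bincount(seg_ids, minlength=n_segments).astype(np.float64)
    if np.any(counts == 0):
        raise ValueError("segment_mean: empty segment")
    data = np.zeros((n_segments,) + values.data.shape[1:])
    np.add.at(data, seg_ids, values.data)
    data /= counts[:, None] if data.ndim > 1 else counts

    def backward(g):
        w = (1.0 / counts)[seg_ids]
        values._accumulate(g[seg_ids] * (w[:, None] if g.ndim > 1 else w))

    return _wrap(data, (values,), backward)


def l2_normalize_rows(a: Tensor, warn=None) -> Tensor:
    """Rescale each nonzero row to unit Euclidean norm; zero rows pass through.

    ``warn`` is called once if any all-zero row is encountered.
    """
    norms = np.linalg.norm(a.data, axis=1)
    zero = norms == 0.0
    if zero.any() and warn is not None:
        warn(int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    data = a.data / safe[:, None]

    def backward(g):
        # d/dx (x/|x|) = (I - y y^T)/|x| with y the unit row
        y = data
        proj = (g * y).sum(axis=1, keepdims=True)
        ga = (g - y * proj) / safe[:, None]
        ga[zero] = g[zero]
        a._accumulate(ga)

    return _wrap(data, (a,), backward)


def row_dot(a: Tensor, b: Tensor) -> Tensor:
    data = (a.data * b.data).sum(axis=1)

    def backward(g):
        a._accumulate(g[:, None] * b.data)
        b._accumulate(g[:, None] * a.data)

    return _wrap(data, (a, b), backward)


def dropout(a: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when p == 0."""
    if p <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= p) / (1.0 - p)
    data = a.data * mask

    def backward(g):
        a._accumulate(g * mask)

    return _wrap(data, (a,), backward)


def scale(a: Tensor, s: float) -> Tensor:
    data = a.data * s

    def backward(g):
        a._accumulate(g * s)

    return _wrap(data, (a,), backward)


def add_scalars(terms) -> Tensor:
    """Sum of scalar tensors (joint loss assembly)."""
    terms = list(terms)
    data = np.sum([t.data for t in terms], axis=0)

    def backward(g):
        for t in terms:
            t._accumulate(g)

    return _wrap(data, tuple(terms), backward)


def batch_norm_rows(a: Tensor, gamma: Tensor, beta: Tensor, running_mean=None,
                    running_var=None, eps: float = 1e-5) -> Tensor:
    """Column-wise batch normalization over the rows of ``a``.

    Training mode (running stats not given): batch statistics, exact BN
    gradient. Evaluation mode: the provided running statistics are constants.
    """
    x = a.data
    if running_mean is None:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        data = gamma.data * xhat + beta.data

        def backward(g):
            n = x.shape[0]
            dxhat = g * gamma.data
            dx = (inv / n) * (
                n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
            a._accumulate(dx)
            gamma._accumulate((g * xhat).sum(axis=0))
            beta._accumulate(g.sum(axis=0))

        return _wrap(data, (a, gamma, beta), backward)

    inv = 1.0 / np.sqrt(running_var + eps)
    xhat = (x - running_mean) * inv
    data = gamma.data * xhat + beta.data

    def backward(g):
        a._accumulate(g * gamma.data * inv)
        gamma._accumulate((g * xhat).sum(axis=0))
        beta._accumulate(g.sum(axis=0))

    return _wrap(data, (a, gamma, beta), backward)


def sigmoid(a: Tensor) -> Tensor:
    data = _stable_sigmoid(a.data)

    def backward(g):
        a._accumulate(g * data * (1.0 - data))

    return _wrap(data, (a,), backward)


def _stable_sigmoid(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: Tensor, targets) -> Tensor:
    """Mean binary cross-entropy, fused with the logistic for stability.

    loss_i = max(z,0) - z*t + log(1 + exp(-|z|))
    """
    t = np.asarray(targets, dtype=np.float64)
    z = logits.data
    per = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    data = per.mean()

    def backward(g):
        logits._accumulate(g * (_stable_sigmoid(z) - t) / z.size)

    return _wrap(data, (logits,), backward)


def cross_entropy(logits: Tensor, targets) -> Tensor:
    """Mean categorical cross-entropy over rows of logits (log-sum-exp fused)."""
    t = np.asarray(targets, dtype=np.intp)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    data = (lse - z[np.arange(len(t)), t]).mean()

    def backward(g):
        p = np.exp(z - zmax)
        p /= p.sum(axis=1, keepdims=True)
        p[np.arange(len(t)), t] -= 1.0
        logits._accumulate(g * p / len(t))

    return _wrap(data, (logits,), backward)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Adam:
    """Adaptive-moment optimizer with the conventional defaults."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
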