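"""Minimal numpy neural-network layers with manual backpropagation.

Implements exactly the building blocks the tabular attention classifier
needs: linear layers, (ghost) batch normalization, GLU blocks, dropout,
the 1.5-entmax mapping, weighted cross-entropy, and Adam with decoupled
weight decay.  Layers return an explicit cache from ``forward`` and
accumulate parameter gradients in ``backward``, so layer objects can be
shared between two invocations in one computation graph (the feature
transformer's shared GLU blocks are used in both the attention pass and
the classification pass).

All computation is float64 unless callers pass float32; determinism is
inherited from the seeded ``numpy.random.Generator`` used for
initialization and dropout.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Parameter",
    "Linear",
    "BatchNorm",
    "GLUBlock",
    "Dropout",
    "FeatureTransformer",
    "entmax15",
    "entmax15_backward",
    "weighted_cross_entropy",
    "softmax",
    "AdamW",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        # decay=False exempts biases and BN parameters from weight decay
        self.decay = decay


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He initialization
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out), decay=False)

    def forward(self, x: np.ndarray):
        return x @ self.W.value + self.b.value, x

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        x = cache
        self.W.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def parameters(self):
        return [self.W, self.b]


class BatchNorm(Layer):
    """Batch normalization with optional ghost (virtual) batches.

    In training mode the batch is split into consecutive groups of
    ``virtual_batch_size`` rows (the final remainder group is normalized on
    its own) and each group is normalized with its own statistics — the
    ghost-batch regularizer.  Running statistics feed evaluation mode.
    """

    def __init__(
        self,
        dim: int,
        virtual_batch_size: int | None = None,
        momentum: float = 0.1,
        eps: float = 1e-5,
    ):
        self.gamma = Parameter(np.ones(dim), decay=False)
        self.beta = Parameter(np.zeros(dim), decay=False)
        self.vbs = virtual_batch_size
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self._calib_n: int | None = None

    def _groups(self, n: int) -> list[slice]:
        if self.vbs is None or self.vbs >= n:
            return [slice(0, n)]
        return [slice(lo, min(lo + self.vbs, n)) for lo in range(0, n, self.vbs)]

    def forward(self, x: np.ndarray, train: bool):
        if not train:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
            return self.gamma.value * xhat + self.beta.value, ("eval", xhat)
        y = np.empty_like(x)
        caches = []
        groups = self._groups(x.shape[0])
        for sl in groups:
            xg = x[sl]
            mean = xg.mean(axis=0)
            var = xg.var(axis=0)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (xg - mean) * inv
            y[sl] = self.gamma.value * xhat + self.beta.value
            caches.append((sl, xhat, inv))
            if self._calib_n is not None:
                # calibration pass: equally-weighted average of group stats
                self._calib_n += 1
                self.running_mean += (mean - self.running_mean) / self._calib_n
                self.running_var += (var - self.running_var) / self._calib_n
            else:
                self.running_mean = (
                    (1 - self.momentum) * self.running_mean + self.momentum * mean
                )
                self.running_var = (
                    (1 - self.momentum) * self.running_var + self.momentum * var
                )
        return y, ("train", caches)

    def start_calibration(self) -> None:
        """Begin recomputing running statistics from scratch (precise BN).

        While active, train-mode forward passes replace the exponential
        moving average with an equally-weighted mean over all ghost groups
        seen, so statistics reflect the *final* weights rather than a
        moving average over a drifting training trajectory.
        """
        self._calib_n = 0
        self.running_mean = np.zeros_like(self.running_mean)
        self.running_var = np.zeros_like(self.running_var)

    def finish_calibration(self) -> None:
        if not self._calib_n:
            self.running_var = np.ones_like(self.running_var)
        self._calib_n = None

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        mode, payload = cache
        if mode == "eval":
            xhat = payload
            self.gamma.grad += (dy * xhat).sum(axis=0)
            self.beta.grad += dy.sum(axis=0)
            return dy * self.gamma.value / np.sqrt(self.running_var + self.eps)
        dx = np.empty_like(dy)
        for sl, xhat, inv in payload:
            dyg = dy[sl]
            m = dyg.shape[0]
            self.gamma.grad += (dyg * xhat).sum(axis=0)
            self.beta.grad += dyg.sum(axis=0)
            dxhat = dyg * self.gamma.value
            dx[sl] = (
                inv / m * (m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
            )
        return dx

    def parameters(self):
        return [self.gamma, self.beta]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class GLUBlock(Layer):
    """Fully-connected -> batch norm -> gated linear unit.

    The fully-connected weights may be *borrowed* (``fc=...``) to share
    them between two feature-transformer invocations; the batch-norm layer
    is always block-own, because the two invocations see activations on
    very different scales (raw vs attention-masked input) and must not mix
    normalization statistics.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        virtual_batch_size: int | None,
        rng: np.random.Generator,
        fc: Linear | None = None,
    ):
        self.fc = fc if fc is not None else Linear(n_in, 2 * n_out, rng)
        self.owns_fc = fc is None
        self.bn = BatchNorm(2 * n_out, virtual_batch_size)
        self.n_out = n_out

    def forward(self, x: np.ndarray, train: bool):
        h, c_fc = self.fc.forward(x)
        h, c_bn = self.bn.forward(h, train)
        a, b = h[:, : self.n_out], h[:, self.n_out :]
        s = _sigmoid(b)
        return a * s, (c_fc, c_bn, a, s)

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        c_fc, c_bn, a, s = cache
        da = dy * s
        db = dy * a * s * (1.0 - s)
        dh = np.concatenate([da, db], axis=1)
        dh = self.bn.backward(c_bn, dh)
        return self.fc.backward(c_fc, dh)

    def parameters(self):
        own = self.fc.parameters() if self.owns_fc else []
        return own + self.bn.parameters()


class Dropout(Layer):
    def __init__(self, p: float):
        self.p = p

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator):
        if not train or self.p <= 0:
            return x, None
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask, mask

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        return dy if cache is None else dy * cache


_SQRT_HALF = np.sqrt(0.5)


class FeatureTransformer(Layer):
    """Stack of shared + invocation-specific GLU blocks with skip connections.

    The first block maps the input dimension to the latent width; every
    later block keeps the width and is combined with its input through a
    residual connection scaled by sqrt(0.5).  ``shared_fcs`` are Linear
    layers *owned by the caller* and reused by both transformer instances
    (weight sharing across the attention and classification passes); the
    batch-norm layers are never shared.
    """

    def __init__(
        self,
        n_in: int,
        width: int,
        shared_fcs: Sequence[Linear],
        n_independent: int,
        virtual_batch_size: int | None,
        rng: np.random.Generator,
    ):
        blocks: list[GLUBlock] = []
        for i, fc in enumerate(shared_fcs):
            blocks.append(
                GLUBlock(n_in if i == 0 else width, width, virtual_batch_size, rng, fc=fc)
            )
        for j in range(n_independent):
            dim = n_in if not blocks and j == 0 else width
            blocks.append(GLUBlock(dim, width, virtual_batch_size, rng))
        self.blocks = blocks

    def forward(self, x: np.ndarray, train: bool):
        caches = []
        out = x
        for i, block in enumerate(self.blocks):
            y, c = block.forward(out, train)
            if i == 0:
                out = y
                caches.append((c, False))
            else:
                out = (out + y) * _SQRT_HALF
                caches.append((c, True))
        return out, caches

    def backward(self, caches, dy: np.ndarray) -> np.ndarray:
        for block, (cache, skip) in zip(reversed(self.blocks), reversed(caches)):
            if skip:
                dy_block = dy * _SQRT_HALF
                dy = dy_block + block.backward(cache, dy_block)
            else:
                dy = block.backward(cache, dy)
        return dy

    def parameters(self):
        # borrowed shared fc weights are excluded by GLUBlock.parameters;
        # the owner registers them exactly once
        return [p for b in self.blocks for p in b.parameters()]


# ---------------------------------------------------------------------------
# 1.5-entmax
# ---------------------------------------------------------------------------

def entmax15(z: np.ndarray, tol: float = 1e-14, max_iter: int = 64) -> np.ndarray:
    """Row-wise 1.5-entmax: the sparse softmax generalization with
    Tsallis alpha = 1.5.

    The maximizer of ``p @ z + H_1.5(p)`` over the simplex has the closed
    form ``p_i = max(0, z_i / 2 - tau)^2`` with the threshold tau chosen so
    the row sums to one; tau is found by bisection.  Low-scoring entries
    get exactly zero probability, which is what makes the attention masks
    sparse.  Adding a constant to ``z`` does not change the output.
    """
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if not np.isfinite(z).all():
        raise ValueError("entmax15 input contains NaN or infinite entries")
    u = z / 2.0
    # tau in [max(u) - 1, max(u)]: at the lower end the max entry alone
    # contributes 1, at the upper end the sum is 0
    lo = u.max(axis=1) - 1.0
    hi = u.max(axis=1)
    for _ in range(max_iter):
        tau = 0.5 * (lo + hi)
        s = np.square(np.clip(u - tau[:, None], 0.0, None)).sum(axis=1)
        lo = np.where(s >= 1.0, tau, lo)
        hi = np.where(s >= 1.0, hi, tau)
        if np.max(hi - lo) < tol:
            break
    tau = 0.5 * (lo + hi)
    p = np.square(np.clip(u - tau[:, None], 0.0, None))
    p /= p.sum(axis=1, keepdims=True)  # exact simplex membership
    return p


def entmax15_backward(p: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Vector-Jacobian product of 1.5-entmax at output ``p``.

    On the support, dp/dz = diag(s) - s s^T / sum(s) with s = sqrt(p).
    """
    s = np.sqrt(p)
    ssum = s.sum(axis=1, keepdims=True)
    return s * dy - s * ((s * dy).sum(axis=1, keepdims=True) / ssum)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted cross-entropy, mean over the batch.

    Each sample is weighted by the weight of its *true* class.  Returns the
    scalar loss and the gradient with respect to the logits.
    """
    n = logits.shape[0]
    p = softmax(logits)
    w = class_weights[labels]
    logp = np.log(p[np.arange(n), labels] + 1e-300)
    loss = float(-(w * logp).mean())
    grad = p * w[:, None]
    grad[np.arange(n), labels] -= w
    return loss, grad / n


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay (decay applied to the raw weights,
    not folded into the gradient; biases and normalization parameters are
    exempt)."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * np.square(p.grad)
            if p.decay and self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
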