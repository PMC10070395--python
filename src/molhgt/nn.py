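"""Neural-network building blocks on top of :mod:`molhgt.autodiff`.

Parameters live in (arbitrarily nested) dicts of :class:`Tensor`; the
helpers here initialize them, iterate them, and run Adam updates.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "glorot_uniform",
    "orthogonal",
    "zeros",
    "iter_params",
    "init_gru",
    "gru_sequence",
    "Adam",
    "dropout",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> Tensor:
    fan_in, fan_out = shape[0], shape[1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> Tensor:
    a = rng.standard_normal(size=(max(shape), max(shape)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # fix the sign ambiguity for reproducibility
    return Tensor(q[: shape[0], : shape[1]].copy(), requires_grad=True)


def zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def iter_params(tree, prefix: str = ""):
    """Yield ``(path, Tensor)`` pairs from a nested dict of tensors."""
    if isinstance(tree, Tensor):
        yield prefix, tree
        return
    for key in sorted(tree):
        path = f"{prefix}/{key}" if prefix else str(key)
        yield from iter_params(tree[key], path)


# ---------------------------------------------------------------------------
# GRU
# ---------------------------------------------------------------------------


def init_gru(rng: np.random.Generator, input_dim: int, hidden_dim: int) -> dict:
    """GRU cell parameters: input maps Glorot, recurrent maps orthogonal."""
    return {
        "W_r": glorot_uniform(rng, (input_dim, hidden_dim)),
        "W_z": glorot_uniform(rng, (input_dim, hidden_dim)),
        "W_n": glorot_uniform(rng, (input_dim, hidden_dim)),
        "U_r": orthogonal(rng, (hidden_dim, hidden_dim)),
        "U_z": orthogonal(rng, (hidden_dim, hidden_dim)),
        "U_n": orthogonal(rng, (hidden_dim, hidden_dim)),
        "b_r": zeros((1, hidden_dim)),
        "b_z": zeros((1, hidden_dim)),
        "b_n": zeros((1, hidden_dim)),
        "b_hn": zeros((1, hidden_dim)),
    }


def gru_step(params: dict, x: Tensor, h: Tensor) -> Tensor:
    """One GRU update; ``x`` and ``h`` are (1, d) rows.

    r = sigmoid(x W_r + h U_r + b_r)
    z = sigmoid(x W_z + h U_z + b_z)
    n = tanh(x W_n + b_n + r * (h U_n + b_hn))
    h' = (1 - z) * n + z * h
    """
    r = (x @ params["W_r"] + h @ params["U_r"] + params["b_r"]).sigmoid()
    z = (x @ params["W_z"] + h @ params["U_z"] + params["b_z"]).sigmoid()
    n = (x @ params["W_n"] + params["b_n"] + r * (h @ params["U_n"] + params["b_hn"])).tanh()
    return (1.0 - z) * n + z * h


def gru_sequence(params: dict, inputs: Tensor) -> Tensor:
    """Run the GRU over the rows of ``inputs`` (N, d); return the final hidden (1, d).

    Input projections are computed for all rows at once; the sequential loop
    carries only the recurrent part. Identical math to repeated
    :func:`gru_step`.
    """
    hidden_dim = params["U_r"].shape[0]
    xr = inputs @ params["W_r"] + params["b_r"]
    xz = inputs @ params["W_z"] + params["b_z"]
    xn = inputs @ params["W_n"] + params["b_n"]
    h = Tensor(np.zeros((1, hidden_dim)))
    for i in range(inputs.shape[0]):
        r = (xr[i : i + 1] + h @ params["U_r"]).sigmoid()
        z = (xz[i : i + 1] + h @ params["U_z"]).sigmoid()
        n = (xn[i : i + 1] + r * (h @ params["U_n"] + params["b_hn"])).tanh()
        h = (1.0 - z) * n + z * h
    return h


# ---------------------------------------------------------------------------
# dropout
# ---------------------------------------------------------------------------


def dropout(t: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return t
    mask = (rng.random(t.shape) >= rate) / (1.0 - rate)
    return t * Tensor(mask)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam over a nested parameter dict, with in-place updates."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 5.0):
        self.entries = list(iter_params(params))
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {path: np.zeros_like(p.data) for path, p in self.entries}
        self.v = {path: np.zeros_like(p.data) for path, p in self.entries}

    def zero_grad(self) -> None:
        for _, p in self.entries:
            p.grad = None

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float((p.grad**2).sum()) for _, p in self.entries if p.grad is not None)
            )
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for _, p in self.entries:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.t += 1
        bias1 = 1.0 - self.beta1**self.t
        bias2 = 1.0 - self.beta2**self.t
        for path, p in self.entries:
            if p.grad is None:
                continue
            m = self.m[path] = self.beta1 * self.m[path] + (1 - self.beta1) * p.grad
            v = self.v[path] = self.beta2 * self.v[path] + (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
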