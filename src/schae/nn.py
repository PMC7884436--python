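"""Minimal numpy neural-network toolkit used by the autoencoder modules.

The networks in this package are small (one or two hidden layers), so each
model implements its own explicit forward/backward pass on top of these
primitives rather than relying on a general autodiff framework.  Gradient
correctness is covered by finite-difference tests.
"""
from __future__ import annotations

import numpy as np

# SELU constants (self-normalising networks)
SELU_LAMBDA = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772


class TrainingDivergedError(RuntimeError):
    """Raised when a training loss becomes non-finite."""


def selu(x: np.ndarray) -> np.ndarray:
    return SELU_LAMBDA * np.where(x > 0, x, SELU_ALPHA * np.expm1(x))


def selu_grad(x: np.ndarray) -> np.ndarray:
    """d selu / dx evaluated at the pre-activation ``x``."""
    return SELU_LAMBDA * np.where(x > 0, 1.0, SELU_ALPHA * np.exp(x))


def lecun_normal(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """LeCun-normal init, the standard pairing for SELU activations."""
    return rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, fan_out))


class AdamW:
    """AdamW: Adam moments with decoupled weight decay.

    ``params`` is a dict name -> array, updated in place by :meth:`step`.
    Weight decay is applied only to parameter names listed in ``decay`` —
    conventionally the weight matrices, never the biases.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
        decay: set[str] | None = None,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay = set(decay) if decay is not None else {k for k in params if k.startswith("W")}
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            if k in self.decay:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Yield shuffled index batches covering ``range(n)`` once."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def check_finite(loss: float, *, epoch: int, seed: int, what: str) -> None:
    if not np.isfinite(loss):
        raise TrainingDivergedError(
            f"{what} training diverged (non-finite loss) at epoch {epoch} with seed {seed}"
        )
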