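"""2D visualization by KL-divergence neighbour embedding.

The compressed matrix is projected to two dimensions by a small neural
network trained so that the neighbourhood probability distribution of the 2D
points matches that of the latent points.  Both distributions come from the
same transform chain:

1. pairwise distances (Pearson distance ``1 - r`` in the latent space,
   Euclidean in 2D, where Pearson correlation is degenerate);
2. per-row log and z-transform of the distances, which makes each cell's
   distance profile comparable (row mean 0, sd 1 off-diagonal);
3. a softmax over negated transformed distances, giving conditional
   probabilities that favour near neighbours, symmetrised into a joint
   distribution ``p_ij = (p_{j|i} + p_{i|j}) / (2n)``.

Training minimises ``KL(P || Q)`` by explicit backpropagation through the
whole chain (softmax, row standardisation, log, pairwise distance, network).
The parameters achieving the lowest KL seen during training are kept, so the
reported divergence never exceeds the initial one.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import pearson_similarity
from .nn import AdamW, check_finite, lecun_normal, selu, selu_grad
from .types import CompressedMatrix, InvalidInputError

logger = logging.getLogger(__name__)

_DIST_FLOOR = 1e-12
DEFAULT_EPOCHS = 100
DEFAULT_HIDDEN = 32


@dataclass
class TransformedDistances:
    """Row-standardised log-distances; diagonal excluded from all statistics."""

    values: np.ndarray


@dataclass
class Embedding2D:
    coords: np.ndarray
    cell_ids: list[str]
    final_kl: float
    kl_history: list[float] = field(default_factory=list)
    checkpoint_kl: list[float] = field(default_factory=list)


def _pairwise_pearson_distance(z: np.ndarray) -> np.ndarray:
    d = 1.0 - (2.0 * pearson_similarity(z) - 1.0)  # back to 1 - r
    np.fill_diagonal(d, 0.0)
    return d


def _pairwise_euclidean(y: np.ndarray) -> np.ndarray:
    sq = np.sum(y * y, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (y @ y.T)
    np.maximum(d2, 0.0, out=d2)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return d


def _log_z_rows(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise standardised log-distances plus the pieces the backward pass needs.

    Returns (T, logd, sd, floored_d).  Zero off-diagonal distances are
    floored at 1e-12 (duplicate cells) with a warning; rows with zero
    log-distance spread map to all-zero rows.
    """
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    dd = d.copy()
    zero_off = (dd <= 0) & off
    if zero_off.any():
        logger.warning("%d zero pairwise distance(s) floored at %g", int(zero_off.sum() // 2), _DIST_FLOOR)
        dd[zero_off] = _DIST_FLOOR
    logd = np.zeros_like(dd)
    logd[off] = np.log(dd[off])
    mean = logd.sum(axis=1) / (n - 1)
    cent = (logd - mean[:, None]) * off
    sd = np.sqrt((cent**2).sum(axis=1) / (n - 1))  # population sd over off-diagonal
    safe_sd = np.where(sd > 0, sd, 1.0)
    t = cent / safe_sd[:, None]
    t[sd == 0, :] = 0.0
    np.fill_diagonal(t, 0.0)
    return t, logd, sd, dd


def transform_distances(z: CompressedMatrix | np.ndarray) -> TransformedDistances:
    """Pearson distances of latent vectors, log-transformed and row-standardised."""
    values = z.values if isinstance(z, CompressedMatrix) else np.asarray(z, float)
    if values.shape[0] < 3:
        raise InvalidInputError("need at least 3 cells")
    t, *_ = _log_z_rows(_pairwise_pearson_distance(values))
    return TransformedDistances(values=t)


def _conditional_from_t(t: np.ndarray) -> np.ndarray:
    """Softmax over ``-t`` per row, excluding the diagonal."""
    n = t.shape[0]
    logits = -t.copy()
    np.fill_diagonal(logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def neighbor_probabilities(d: TransformedDistances | np.ndarray) -> np.ndarray:
    """Joint neighbour distribution P: symmetrised conditionals, entries sum to 1."""
    t = d.values if isinstance(d, TransformedDistances) else np.asarray(d, float)
    c = _conditional_from_t(t)
    n = t.shape[0]
    p = (c + c.T) / (2.0 * n)
    np.fill_diagonal(p, 0.0)
    return p


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """``sum_{i != j} p_ij log(p_ij / q_ij)`` with 0 log 0 = 0."""
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / np.maximum(q[mask], 1e-300))))


def _q_from_coords(y: np.ndarray):
    d = _pairwise_euclidean(y)
    t, logd, sd, dd = _log_z_rows(d)
    c = _conditional_from_t(t)
    n = y.shape[0]
    q = (c + c.T) / (2.0 * n)
    np.fill_diagonal(q, 0.0)
    return q, c, t, sd, dd


def _kl_grad_wrt_coords(y: np.ndarray, p: np.ndarray):
    """KL(P||Q) and its exact gradient with respect to the 2D coordinates.

    Chains through: joint symmetrisation, row softmax, row standardisation
    (layer-norm-style backward over off-diagonal entries), log, and the
    Euclidean pairwise distance.
    """
    n = y.shape[0]
    q, c, t, sd, dd = _q_from_coords(y)
    kl = kl_divergence(p, q)

    # dKL/dq, symmetric; then into the conditionals
    with np.errstate(divide="ignore", invalid="ignore"):
        gq = np.where(p > 0, -p / np.maximum(q, 1e-300), 0.0)
    gc = (gq + gq.T) / (2.0 * n)  # q symmetric in c and c.T

    # softmax backward per row (logits = -t, diagonal excluded)
    dot = np.sum(gc * c, axis=1, keepdims=True)
    glogit = c * (gc - dot)
    gt = -glogit

    # row standardisation backward (population stats over n-1 off-diagonal entries)
    off = ~np.eye(n, dtype=bool)
    gt = gt * off
    m1 = gt.sum(axis=1, keepdims=True) / (n - 1)
    m2 = (gt * t).sum(axis=1, keepdims=True) / (n - 1)
    safe_sd = np.where(sd > 0, sd, np.inf)[:, None]
    glogd = (gt - m1 - t * m2) / safe_sd * off

    # log backward; floored entries have (numerically) enormous 1/d, but the
    # floor is only hit for exact duplicates where the gradient direction
    # vanishes anyway — clip for safety
    with np.errstate(divide="ignore", invalid="ignore"):
        gd = np.where(dd > 0, glogd / np.maximum(dd, _DIST_FLOOR), 0.0)
    np.fill_diagonal(gd, 0.0)

    # Euclidean distance backward: dD_ij/dy_i = (y_i - y_j) / D_ij
    f = gd + gd.T
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dd > _DIST_FLOOR, f / dd, 0.0)
    np.fill_diagonal(ratio, 0.0)
    gy = y * ratio.sum(axis=1, keepdims=True) - ratio @ y
    return kl, gy


def fit_embedding(
    z: CompressedMatrix,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
    hidden: int = DEFAULT_HIDDEN,
    lr: float = 1e-2,
    n_dims: int = 2,
    checkpoint_every: int = 10,
) -> Embedding2D:
    """Train the projection network to minimise KL(P || Q).

    Full-batch AdamW; the best (lowest-KL) parameters seen are retained, so
    ``final_kl`` is the minimum over the trajectory and ``checkpoint_kl``
    (best-so-far at every ``checkpoint_every`` epochs) is non-increasing.
    """
    values = z.values
    n, m = values.shape
    if n < 3:
        raise InvalidInputError("need at least 3 cells to embed")
    p = neighbor_probabilities(transform_distances(values))
    rng = np.random.default_rng(seed)
    params = {
        "W1": lecun_normal(rng, m, hidden),
        "b1": np.zeros(hidden),
        "W2": lecun_normal(rng, hidden, n_dims),
        "b2": np.zeros(n_dims),
    }
    opt = AdamW(params, lr=lr, weight_decay=0.0)

    def forward(pp):
        h_pre = values @ pp["W1"] + pp["b1"]
        return h_pre, selu(h_pre) @ pp["W2"] + pp["b2"]

    best = {k: v.copy() for k, v in params.items()}
    _, y0 = forward(params)
    best_kl = kl_divergence(p, _q_from_coords(y0)[0])
    history = [best_kl]
    checkpoints = [best_kl]
    for epoch in range(epochs):
        h_pre, y = forward(params)
        kl, gy = _kl_grad_wrt_coords(y, p)
        check_finite(kl, epoch=epoch, seed=seed, what="embedding")
        h = selu(h_pre)
        gh = (gy @ params["W2"].T) * selu_grad(h_pre)
        grads = {
            "W2": h.T @ gy, "b2": gy.sum(axis=0),
            "W1": values.T @ gh, "b1": gh.sum(axis=0),
        }
        opt.step(grads)
        history.append(kl)
        if kl < best_kl:
            best_kl = kl
            best = {k: v.copy() for k, v in params.items()}
        if (epoch + 1) % checkpoint_every == 0:
            checkpoints.append(best_kl)
    _, y_best = forward(best)
    final_kl = kl_divergence(p, _q_from_coords(y_best)[0])
    logger.info("embedding: KL %.4f -> %.4f over %d epochs", history[0], final_kl, epochs)
    return Embedding2D(
        coords=y_best,
        cell_ids=list(z.cell_ids),
        final_kl=final_kl,
        kl_history=history,
        checkpoint_kl=checkpoints,
    )
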