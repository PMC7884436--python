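"""Gene filtering with a one-layer non-negative kernel autoencoder.

A linear autoencoder with a 50-node bottleneck is trained to reconstruct the
scaled expression matrix while the encoder weights are constrained to be
non-negative, so each latent variable is an additive (parts-based) combination
of genes.  Under this constraint the encoder shrinks the weights of
uninformative genes toward zero and spreads informative genes unevenly across
latent nodes, so the variance of a gene's encoder-weight row is an importance
score.  The top-scoring genes (5000 by default) are retained for compression.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import AdamW, check_finite, minibatches
from .types import GeneSelection, InvalidInputError, ScaledMatrix

logger = logging.getLogger(__name__)

DEFAULT_LATENT_SIZE = 50
DEFAULT_N_KEEP = 5000


@dataclass
class NNAutoencoderModel:
    """Trained one-layer autoencoder with non-negative encoder weights.

    ``W_E`` is genes x latent and satisfies ``W_E >= 0`` elementwise; the
    constraint is re-applied by projection after every optimizer step.
    """

    W_E: np.ndarray
    b_E: np.ndarray
    W_D: np.ndarray
    b_D: np.ndarray
    latent_size: int
    loss_history: list[float] = field(default_factory=list)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return (x @ self.W_E + self.b_E) @ self.W_D + self.b_D


def train_nn_autoencoder(
    x: ScaledMatrix,
    latent_size: int = DEFAULT_LATENT_SIZE,
    epochs: int = 50,
    seed: int = 0,
    lr: float = 5e-3,
    batch_size: int | None = None,
    weight_decay: float = 1e-2,
) -> NNAutoencoderModel:
    """Train the non-negative autoencoder on a scaled matrix.

    Mean-squared-error reconstruction loss, AdamW optimizer; encoder weights
    are clamped at zero after every step so non-negativity holds throughout
    training, not only at the end.

    The default epoch budget is deliberately short: correlated, group-bearing
    genes are learned first, so their encoder rows develop spread while rows
    of unstructured genes are still near their initialisation.  Training the
    filter to convergence would let the model fit noise genes too and erode
    the contrast the variance score relies on.
    """
    v = x.values
    n, g = v.shape
    if n < 2 or g < 2:
        raise InvalidInputError("need at least 2 cells and 2 genes to train")
    if batch_size is None:
        batch_size = min(n, 128)
    rng = np.random.default_rng(seed)

    # non-negative start for W_E so the projection never wipes the init
    params = {
        "W_E": rng.uniform(0.0, np.sqrt(2.0 / g), size=(g, latent_size)),
        "b_E": np.zeros(latent_size),
        "W_D": rng.normal(0.0, np.sqrt(1.0 / latent_size), size=(latent_size, g)),
        "b_D": np.zeros(g),
    }
    opt = AdamW(params, lr=lr, weight_decay=weight_decay, decay={"W_E", "W_D"})

    def full_loss() -> float:
        h = v @ params["W_E"] + params["b_E"]
        r = h @ params["W_D"] + params["b_D"]
        return float(np.mean((r - v) ** 2))

    history = [full_loss()]
    for epoch in range(epochs):
        for idx in minibatches(n, batch_size, rng):
            xb = v[idx]
            h = xb @ params["W_E"] + params["b_E"]
            r = h @ params["W_D"] + params["b_D"]
            err = 2.0 * (r - xb) / xb.size  # d mean((r-x)^2) / dr
            grads = {
                "W_D": h.T @ err,
                "b_D": err.sum(axis=0),
            }
            dh = err @ params["W_D"].T
            grads["W_E"] = xb.T @ dh
            grads["b_E"] = dh.sum(axis=0)
            opt.step(grads)
            np.maximum(params["W_E"], 0.0, out=params["W_E"])  # projection step
        loss = full_loss()
        check_finite(loss, epoch=epoch, seed=seed, what="non-negative autoencoder")
        history.append(loss)
    logger.info(
        "non-negative autoencoder: loss %.5f -> %.5f over %d epochs",
        history[0], history[-1], epochs,
    )
    return NNAutoencoderModel(
        W_E=params["W_E"], b_E=params["b_E"], W_D=params["W_D"], b_D=params["b_D"],
        latent_size=latent_size, loss_history=history,
    )


def score_genes(model: NNAutoencoderModel) -> np.ndarray:
    """Per-gene importance: population variance of the gene's encoder-weight row."""
    return model.W_E.var(axis=1)  # ddof=0: population variance across latent nodes


def rank_genes(scores: np.ndarray, n_keep: int = DEFAULT_N_KEEP) -> GeneSelection:
    """Pick the ``n_keep`` highest-scoring genes; ties break toward the lower index."""
    g = scores.shape[0]
    k = min(n_keep, g)
    # stable sort on -score => equal scores keep ascending index order
    order = np.argsort(-scores, kind="stable")
    kept = np.sort(order[:k])
    return GeneSelection(scores=scores, kept_indices=kept, n_keep=k)


def select_genes(x: ScaledMatrix, sel: GeneSelection) -> ScaledMatrix:
    """Column-subset ``x`` to the retained genes, preserving cell order."""
    if sel.kept_indices.size == 0:
        raise InvalidInputError("empty gene selection")
    if sel.kept_indices.max() >= x.n_genes or sel.kept_indices.min() < 0:
        raise InvalidInputError("gene selection indices out of range")
    return ScaledMatrix(
        x.values[:, sel.kept_indices],
        list(x.cell_ids),
        [x.gene_ids[i] for i in sel.kept_indices],
        log_applied=x.log_applied,
    )


def filter_genes(
    x: ScaledMatrix,
    n_keep: int = DEFAULT_N_KEEP,
    latent_size: int = DEFAULT_LATENT_SIZE,
    epochs: int = 50,
    seed: int = 0,
) -> tuple[ScaledMatrix, GeneSelection]:
    """Convenience wrapper: train, score, rank and subset in one call."""
    if n_keep >= x.n_genes:
        sel = GeneSelection(
            scores=np.zeros(x.n_genes), kept_indices=np.arange(x.n_genes), n_keep=x.n_genes
        )
        return x, sel
    model = train_nn_autoencoder(x, latent_size=latent_size, epochs=epochs, seed=seed)
    sel = rank_genes(score_genes(model), n_keep=n_keep)
    return select_genes(x, sel), sel
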