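"""Transductive cell-type classification.

Train and test matrices are restricted to their common genes, row-concatenated
and pushed through the same unsupervised pipeline as clustering (per-cell
scaling, non-negative-autoencoder gene filtering, variational compression).
Because both data sets share one embedding, batch effects and platform
scaling largely cancel, and a plain k-nearest-neighbour vote in the latent
space (Pearson similarity, k = 10 by default) transfers the training labels
to the test cells.  Labels are never used during compression.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clustering import pearson_similarity
from .feature_select import filter_genes
from .latent_model import compress
from .preprocess import preprocess
from .types import ExpressionMatrix, InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_K = 10


@dataclass
class LabeledDataset:
    """An expression matrix with one categorical label per cell."""

    matrix: ExpressionMatrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.matrix.n_cells:
            raise InvalidInputError(
                f"label vector length {self.labels.shape[0]} != n_cells {self.matrix.n_cells}"
            )


def align_common_genes(
    train: ExpressionMatrix, test: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, in a canonical order.

    The order is the training matrix's gene order, filtered to the
    intersection (exact string match).
    """
    test_set = set(test.gene_ids)
    common = [g for g in train.gene_ids if g in test_set]
    if not common:
        raise InvalidInputError(
            "no genes in common between train and test; "
            f"train has e.g. {train.gene_ids[:3]}, test has e.g. {test.gene_ids[:3]}"
        )
    tr_pos = {g: i for i, g in enumerate(train.gene_ids)}
    te_pos = {g: i for i, g in enumerate(test.gene_ids)}
    tr_idx = [tr_pos[g] for g in common]
    te_idx = [te_pos[g] for g in common]
    return (
        ExpressionMatrix(train.values[:, tr_idx], list(train.cell_ids), list(common)),
        ExpressionMatrix(test.values[:, te_idx], list(test.cell_ids), list(common)),
    )


def _knn_vote(
    sim: np.ndarray, train_labels: np.ndarray, k: int, weighted: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Majority (or similarity-weighted) vote over the k most similar columns."""
    classes, enc = np.unique(train_labels, return_inverse=True)
    n_test = sim.shape[0]
    pred = np.empty(n_test, dtype=np.int64)
    frac = np.empty(n_test)
    nbr = np.argpartition(-sim, k - 1, axis=1)[:, :k] if k < sim.shape[1] else \
        np.tile(np.arange(sim.shape[1]), (n_test, 1))
    for i in range(n_test):
        neigh = nbr[i]
        wts = sim[i, neigh] if weighted else np.ones(neigh.size)
        cnt = np.bincount(enc[neigh], weights=wts, minlength=classes.size)
        top = cnt.max()
        winners = np.where(np.isclose(cnt, top))[0]
        if winners.size == 1:
            pred[i] = winners[0]
        else:  # tie: single most similar neighbour decides
            pred[i] = enc[neigh[np.argmax(sim[i, neigh])]]
        frac[i] = cnt[pred[i]] / cnt.sum()
    return classes[pred], frac


def classify_cells(
    train: LabeledDataset,
    test: ExpressionMatrix,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_keep: int = 5000,
    weighted: bool = False,
    return_vote_fraction: bool = False,
    **vae_kwargs,
):
    """Label test cells by k-nn in a joint latent embedding.

    Steps: align common genes, concatenate rows, preprocess (log rule and
    per-cell scaling), filter genes, compress with the stacked VAE, then
    vote among the ``k`` most Pearson-similar training cells.  Ties go to
    the single most similar neighbour.
    """
    n_train = train.matrix.n_cells
    if k > n_train:
        raise InvalidInputError(f"k={k} exceeds the number of training cells {n_train}")
    tr, te = align_common_genes(train.matrix, test)

    cell_ids = [f"train:{c}" for c in tr.cell_ids] + [f"test:{c}" for c in te.cell_ids]
    merged = ExpressionMatrix(
        np.vstack([tr.values, te.values]), cell_ids, list(tr.gene_ids)
    )
    x = preprocess(merged)
    x, _ = filter_genes(x, n_keep=n_keep, seed=seed)
    z, _ = compress(x, seed=seed, **vae_kwargs)
    z_tr = z.values[:n_train]
    z_te = z.values[n_train:]
    sim = pearson_similarity(z_te, z_tr)
    pred, frac = _knn_vote(sim, train.labels, k, weighted)
    logger.info("classified %d test cells against %d training cells (k=%d)", len(pred), n_train, k)
    if return_vote_fraction:
        return pred, frac
    return pred
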