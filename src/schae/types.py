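"""Core data containers shared across the pipeline.

All matrices are cells x genes (rows are cells), mirroring the orientation
of the raw expression matrix the pipeline ingests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "ScaledMatrix",
    "CompressedMatrix",
    "GeneSelection",
    "ClusteringResult",
    "PseudotimeResult",
]


class InvalidInputError(ValueError):
    """Raised when an input matrix violates the container invariants."""


def _check_ids(ids: list[str], what: str, n: int) -> list[str]:
    ids = [str(i) for i in ids]
    if len(ids) != n:
        raise InvalidInputError(f"{what}: expected {n} ids, got {len(ids)}")
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise InvalidInputError(f"duplicate {what}: {sorted(set(dups))[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with string identifiers.

    Rows are cells, columns are genes.  Entries must be finite and
    non-negative (raw counts or already-normalised values).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise InvalidInputError(
                f"expression matrix must be a non-empty 2-D array, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("expression matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise InvalidInputError("expression matrix contains negative entries")
        n, g = self.values.shape
        self.cell_ids = _check_ids(self.cell_ids, "cell ids", n)
        self.gene_ids = _check_ids(self.gene_ids, "gene ids", g)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, values: np.ndarray, prefix: str = "cell") -> "ExpressionMatrix":
        """Wrap a bare array with generated ``cell_i`` / ``gene_j`` ids."""
        values = np.asarray(values, dtype=np.float64)
        return cls(
            values,
            [f"{prefix}_{i}" for i in range(values.shape[0])],
            [f"gene_{j}" for j in range(values.shape[1])],
        )


@dataclass
class ScaledMatrix:
    """Per-cell min-max scaled matrix; every entry lies in [0, 1].

    ``log_applied`` records whether the conditional log2 transform ran
    before scaling.  Constant (degenerate) cells are all-zero rows.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    log_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise InvalidInputError("scaled matrix entries must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class CompressedMatrix:
    """Latent representation of cells (n_cells x m) from the variational autoencoder."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("compressed matrix contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneSelection:
    """Per-gene importance scores and the retained top-scoring index set.

    ``scores`` are the variances of each gene's non-negative encoder-weight
    row; ``kept_indices`` are the ``n_keep`` highest-scoring genes (ties
    broken toward the lower index), stored in ascending index order.
    """

    scores: np.ndarray
    kept_indices: np.ndarray
    n_keep: int


@dataclass
class ClusteringResult:
    """Consensus cell partition plus the per-replicate partitions behind it."""

    labels: np.ndarray
    k: int
    replicate_labels: list[np.ndarray] = field(default_factory=list)
    method_metadata: dict = field(default_factory=dict)


@dataclass
class PseudotimeResult:
    """Per-cell pseudotime anchored at ``start_cell`` plus the spanning tree."""

    times: np.ndarray
    start_cell: str
    tree_edges: list[tuple[int, int, float]]
    cell_ids: list[str]
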