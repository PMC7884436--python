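"""Non-branching pseudotime from a minimum spanning tree.

Cells are connected in a complete graph weighted by Pearson distance
``1 - r`` between their latent vectors; the minimum spanning tree of that
graph is the inferred trajectory backbone, and the pseudotime of a cell is
the total edge weight along its unique tree path from a user-designated
start cell.  Every cell receives a finite time because a spanning tree is
connected by construction.
"""
from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree

from .clustering import pearson_similarity
from .types import CompressedMatrix, InvalidInputError, PseudotimeResult

logger = logging.getLogger(__name__)


def pearson_distance_matrix(z: np.ndarray) -> np.ndarray:
    """Dense ``1 - r`` distances between rows, zero diagonal."""
    d = 1.0 - (2.0 * pearson_similarity(z) - 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def infer_pseudotime(z: CompressedMatrix, start_cell: str) -> PseudotimeResult:
    """MST-path pseudotime anchored at ``start_cell``.

    The spanning tree is computed on the complete Pearson-distance graph;
    times are tree-path distances from the start cell (additive along tree
    paths, zero at the start).
    """
    if z.n_cells < 2:
        raise InvalidInputError("need at least 2 cells for pseudotime")
    try:
        start = z.cell_ids.index(str(start_cell))
    except ValueError:
        raise InvalidInputError(
            f"start cell {start_cell!r} not found among {z.n_cells} cells"
        ) from None
    d = pearson_distance_matrix(z.values)
    # scipy's MST drops explicit zeros; keep duplicate-cell edges alive with
    # a tiny epsilon that cannot change which tree is minimal
    eps = 1e-15
    dd = d + eps
    np.fill_diagonal(dd, 0.0)
    tree = minimum_spanning_tree(sp.csr_matrix(dd))
    tree_sym = tree + tree.T
    times = dijkstra(tree_sym, directed=False, indices=start)
    times = np.maximum(times - eps * _hops(tree_sym, start), 0.0)
    coo = tree.tocoo()
    edges = [(int(i), int(j), float(max(v - eps, 0.0))) for i, j, v in zip(coo.row, coo.col, coo.data)]
    if not np.all(np.isfinite(times)):
        raise InvalidInputError("spanning tree is disconnected; this should not happen")
    return PseudotimeResult(
        times=times, start_cell=str(start_cell), tree_edges=edges, cell_ids=list(z.cell_ids)
    )


def _hops(tree_sym: sp.spmatrix, start: int) -> np.ndarray:
    """Number of tree edges on the path from ``start`` to every cell."""
    unit = tree_sym.copy()
    unit.data = np.ones_like(unit.data)
    return dijkstra(unit, directed=False, indices=start)


def fit_stage_r2(times: np.ndarray, stages: np.ndarray) -> float:
    """Coefficient of determination of stage rank regressed on pseudotime.

    Stages are ordinal labels; they are mapped to ranks by sorted unique
    value.  Returns ``r^2`` of the simple linear fit (closed form), in
    [0, 1].  Constant times carry no ordering information and return 0 with
    a warning.
    """
    times = np.asarray(times, dtype=float)
    stages = np.asarray(stages)
    if times.shape[0] != stages.shape[0]:
        raise InvalidInputError("times and stages must have equal length")
    uniq = np.unique(stages)
    if uniq.size < 2:
        raise InvalidInputError("need at least 2 distinct stages")
    rank = {s: i for i, s in enumerate(uniq)}
    y = np.array([rank[s] for s in stages], dtype=float)
    if np.all(times == times[0]):
        logger.warning("constant pseudotimes: stage R^2 undefined, returning 0")
        return 0.0
    r = np.corrcoef(times, y)[0, 1]
    return float(r * r)
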