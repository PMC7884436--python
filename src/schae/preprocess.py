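"""Conditional log transform and per-cell min-max scaling.

The pipeline rescales every cell to [0, 1] so that highly expressed genes do
not dominate the autoencoders.  Before scaling, a base-2 log transform is
applied once, globally, if the dynamic range of the matrix exceeds 100 —
raw counts get log-compressed, already-log-scaled inputs pass through.
"""
from __future__ import annotations

import logging

import numpy as np

from .types import ExpressionMatrix, InvalidInputError, ScaledMatrix

logger = logging.getLogger(__name__)

#: dynamic-range threshold above which the log2 transform is applied
LOG_RANGE_THRESHOLD = 100.0


def maybe_log_transform(m: ExpressionMatrix) -> tuple[ExpressionMatrix, bool]:
    """Apply ``log2(x + 1)`` to every entry iff the matrix range exceeds 100.

    The range is ``max(M) - min(M)`` over the whole matrix, checked once
    before any other step.  The pseudocount of 1 maps zeros to zero.

    Returns the (possibly transformed) matrix and a flag saying whether the
    transform ran.
    """
    if m.values.size == 0:
        raise InvalidInputError("empty matrix")
    rng = float(m.values.max() - m.values.min())
    if rng > LOG_RANGE_THRESHOLD:
        logger.info("matrix range %.3g > %g: applying log2(x+1)", rng, LOG_RANGE_THRESHOLD)
        return (
            ExpressionMatrix(np.log2(m.values + 1.0), list(m.cell_ids), list(m.gene_ids)),
            True,
        )
    return m, False


def minmax_rows(m: ExpressionMatrix, log_applied: bool = False) -> ScaledMatrix:
    """Rescale each cell (row) to [0, 1] by its own min and max.

    Constant rows (max == min) have no scale and are mapped to all zeros;
    they are reported in the log rather than aborting the run.
    """
    v = m.values
    lo = v.min(axis=1, keepdims=True)
    hi = v.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0
    if flat.any():
        logger.warning(
            "%d constant cell(s) mapped to all-zero rows: %s",
            int(flat.sum()),
            [m.cell_ids[i] for i in np.where(flat)[0][:5]],
        )
    span = np.where(span == 0, 1.0, span)
    x = (v - lo) / span
    x[flat, :] = 0.0
    return ScaledMatrix(x, list(m.cell_ids), list(m.gene_ids), log_applied=log_applied)


def preprocess(m: ExpressionMatrix) -> ScaledMatrix:
    """Full preprocessing: conditional log transform, then per-cell scaling."""
    m2, logged = maybe_log_transform(m)
    return minmax_rows(m2, log_applied=logged)
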