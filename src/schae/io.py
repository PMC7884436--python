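"""Reading and writing expression matrices and pipeline outputs.

Dense CSV/TSV (header row = gene ids, first column = cell ids) and Matrix
Market triplet files with companion gene/barcode text files are supported.
An orientation flag transposes matrices stored genes-in-rows (the common
10x convention for .mtx).
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import CompressedMatrix, ExpressionMatrix, InvalidInputError

logger = logging.getLogger(__name__)


def read_matrix(
    path: str | Path,
    fmt: str | None = None,
    cells_in_rows: bool = True,
    genes_file: str | Path | None = None,
    barcodes_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV, TSV or Matrix Market.

    ``fmt`` is inferred from the suffix when omitted.  For ``.mtx`` input,
    ``genes_file`` and ``barcodes_file`` name one-id-per-line text files;
    by default the matrix is assumed genes-in-rows and transposed
    (``cells_in_rows=False`` is implied for mtx unless stated).
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"input file not found: {path}")
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".mtx": "mtx"}.get(suffix)
        if fmt is None:
            raise InvalidInputError(f"cannot infer format from suffix {suffix!r}")
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        # pandas silently renames duplicate header entries; check the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dups = {h for h in header if header.count(h) > 1}
        if dups:
            raise InvalidInputError(f"duplicate column ids in {path}: {sorted(dups)[:5]}")
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=np.float64)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
        if not cells_in_rows:
            values, row_ids, col_ids = values.T, col_ids, row_ids
        return ExpressionMatrix(values, row_ids, col_ids)
    if fmt == "mtx":
        if genes_file is None or barcodes_file is None:
            raise InvalidInputError("mtx input needs genes_file and barcodes_file")
        m = scipy.io.mmread(path)
        values = m.toarray() if sp.issparse(m) else np.asarray(m)
        genes = _read_ids(genes_file)
        cells = _read_ids(barcodes_file)
        if values.shape == (len(genes), len(cells)):
            values = values.T  # genes-in-rows on disk, cells-in-rows in memory
        elif values.shape != (len(cells), len(genes)):
            raise InvalidInputError(
                f"mtx shape {values.shape} matches neither (genes={len(genes)}, "
                f"cells={len(cells)}) orientation"
            )
        return ExpressionMatrix(np.asarray(values, dtype=np.float64), cells, genes)
    raise InvalidInputError(f"unknown format {fmt!r}")


def _read_ids(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


def write_matrix(m: ExpressionMatrix, path: str | Path, fmt: str = "tsv") -> None:
    df = pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids)
    df.to_csv(path, sep="," if fmt == "csv" else "\t")


def write_labels(cell_ids: list[str], labels: np.ndarray, path: str | Path,
                 column: str = "cluster") -> None:
    pd.DataFrame({"cell_id": cell_ids, column: labels}).to_csv(path, sep="\t", index=False)


def write_compressed(z: CompressedMatrix, path: str | Path) -> None:
    df = pd.DataFrame(z.values, index=z.cell_ids,
                      columns=[f"latent_{i}" for i in range(z.m)])
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t")


def read_compressed(path: str | Path) -> CompressedMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CompressedMatrix(df.to_numpy(dtype=np.float64), [str(i) for i in df.index])


def write_coords(cell_ids: list[str], coords: np.ndarray, path: str | Path) -> None:
    cols = {"cell_id": cell_ids}
    for d in range(coords.shape[1]):
        cols[f"dim{d + 1}"] = coords[:, d]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_scores(gene_ids: list[str], scores: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"gene_id": gene_ids, "score": scores}).to_csv(path, sep="\t", index=False)


def read_label_file(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a two-column TSV (cell_id, label); returns ids and labels."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InvalidInputError("label file needs two columns: cell_id, label")
    return [str(c) for c in df.iloc[:, 0]], df.iloc[:, 1].to_numpy()
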