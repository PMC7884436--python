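"""Run configuration and the end-to-end pipeline driver.

One preprocessing + gene-filtering + compression pass is shared by all
requested downstream tasks (clustering, visualization, classification,
pseudotime); a JSON manifest recording the configuration, seed, package
versions and timings is written next to the outputs so any run can be
reproduced exactly.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy
import sklearn

from .classify import LabeledDataset, classify_cells
from .clustering import cluster_pipeline
from .embedding2d import fit_embedding
from .feature_select import filter_genes
from .io import (
    read_label_file,
    read_matrix,
    write_compressed,
    write_coords,
    write_labels,
    write_scores,
)
from .latent_model import compress
from .preprocess import preprocess
from .pseudotime import infer_pseudotime
from .types import ExpressionMatrix, InvalidInputError

logger = logging.getLogger(__name__)

VALID_TASKS = ("cluster", "visualize", "classify", "pseudotime")


def _package_version() -> str:
    from . import __version__

    return __version__


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their documented defaults."""

    n_genes: int = 5000
    latent_dim: int = 15
    warmup_epochs: int = 40
    epochs: int = 200
    n_realizations: int = 5
    n_replicates: int = 10
    k: int | None = None
    k_nn: int | None = None
    j_lo: int = 2
    j_hi: int = 15
    vote_threshold: int = 50_000
    embed_epochs: int = 100
    embed_dims: int = 2
    classify_k: int = 10
    start_cell: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(
    matrix: ExpressionMatrix,
    tasks: set[str] | list[str],
    out_dir: str | Path,
    config: RunConfig | None = None,
    train_labels_path: str | Path | None = None,
    test_matrix: ExpressionMatrix | None = None,
) -> dict[str, Path]:
    """Execute the shared compression once, then each requested task.

    Returns a dict mapping output names to file paths.  Identical
    configuration and seed give byte-identical outputs.
    """
    config = config or RunConfig()
    tasks = set(tasks)
    bad = tasks - set(VALID_TASKS)
    if bad:
        raise InvalidInputError(f"unknown tasks: {sorted(bad)}; valid: {VALID_TASKS}")
    if "pseudotime" in tasks and config.start_cell is None:
        raise InvalidInputError("pseudotime requires start_cell in the configuration")
    if "classify" in tasks and (train_labels_path is None or test_matrix is None):
        raise InvalidInputError("classify requires training labels and a test matrix")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    x = preprocess(matrix)
    x, sel = filter_genes(x, n_keep=config.n_genes, seed=config.seed)
    z, _model = compress(
        x,
        m=config.latent_dim,
        seed=config.seed,
        warmup_epochs=config.warmup_epochs,
        epochs=config.epochs,
        n_realizations=config.n_realizations,
    )
    timings["compress"] = time.perf_counter() - t0
    outputs["compressed"] = out_dir / "compressed.tsv"
    write_compressed(z, outputs["compressed"])
    outputs["gene_scores"] = out_dir / "gene_scores.tsv"
    write_scores([matrix.gene_ids[i] for i in sel.kept_indices],
                 sel.scores[sel.kept_indices] if sel.scores.size else sel.scores,
                 outputs["gene_scores"])

    if "cluster" in tasks:
        t0 = time.perf_counter()
        res = cluster_pipeline(
            x,
            n_replicates=config.n_replicates,
            k=config.k,
            seed=config.seed,
            k_nn=config.k_nn,
            j_range=range(config.j_lo, config.j_hi + 1),
            vote_threshold=config.vote_threshold,
            m=config.latent_dim,
            warmup_epochs=config.warmup_epochs,
            epochs=config.epochs,
            n_realizations=config.n_realizations,
        )
        timings["cluster"] = time.perf_counter() - t0
        outputs["clusters"] = out_dir / "clusters.tsv"
        write_labels(matrix.cell_ids, res.labels, outputs["clusters"])
        logger.info("clustering done: k=%d", res.k)

    if "visualize" in tasks:
        t0 = time.perf_counter()
        emb = fit_embedding(
            z, epochs=config.embed_epochs, seed=config.seed, n_dims=config.embed_dims
        )
        timings["visualize"] = time.perf_counter() - t0
        outputs["embedding"] = out_dir / "embedding.tsv"
        write_coords(z.cell_ids, emb.coords, outputs["embedding"])

    if "pseudotime" in tasks:
        t0 = time.perf_counter()
        pt = infer_pseudotime(z, config.start_cell)
        timings["pseudotime"] = time.perf_counter() - t0
        outputs["pseudotime"] = out_dir / "pseudotime.tsv"
        write_labels(z.cell_ids, pt.times, outputs["pseudotime"], column="pseudotime")

    if "classify" in tasks:
        t0 = time.perf_counter()
        ids, labels = read_label_file(train_labels_path)
        if ids != list(matrix.cell_ids):
            order = {c: i for i, c in enumerate(ids)}
            missing = [c for c in matrix.cell_ids if c not in order]
            if missing:
                raise InvalidInputError(f"labels missing for cells e.g. {missing[:5]}")
            labels = labels[[order[c] for c in matrix.cell_ids]]
        pred, frac = classify_cells(
            LabeledDataset(matrix, labels),
            test_matrix,
            k=config.classify_k,
            seed=config.seed,
            n_keep=config.n_genes,
            return_vote_fraction=True,
            m=config.latent_dim,
            warmup_epochs=config.warmup_epochs,
            epochs=config.epochs,
        )
        timings["classify"] = time.perf_counter() - t0
        outputs["predictions"] = out_dir / "predictions.tsv"
        import pandas as pd

        pd.DataFrame(
            {"cell_id": test_matrix.cell_ids, "predicted_label": pred, "vote_fraction": frac}
        ).to_csv(outputs["predictions"], sep="\t", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "tasks": sorted(tasks),
        "n_cells": matrix.n_cells,
        "n_genes": matrix.n_genes,
        "versions": {
            "schae": _package_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "python": platform.python_version(),
        },
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    outputs["manifest"] = manifest_path
    return outputs
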