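"""Synthetic scRNA-seq count generator with known ground truth.

Emulates the generative family of grouped negative-binomial counts with
technical dropout (as produced by Splatter-style simulators): gamma-distributed
gene base means, log-normal library sizes, group-specific differential
expression on a designated gene subset, gamma-Poisson (negative binomial)
sampling, and extra Bernoulli dropout tuned so the realized sparsity hits a
target.  A trajectory mode replaces discrete groups with genes switching on
sigmoidally at random pseudotimes; a batch mode adds multiplicative shifts on
a random gene subset.

Ground truth (labels, times, differential-expression sets) is returned
alongside the matrix so downstream accuracy can be measured exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ExpressionMatrix, InvalidInputError

__all__ = ["SimulationSpec", "SimulationTruth", "simulate_counts", "simulate_batches"]


@dataclass
class SimulationSpec:
    """Parameters of one simulated data set.

    Defaults give the small three-group fixture used throughout the test
    suite: 600 cells, 2000 genes, 10% of genes differentially expressed per
    group at threefold change, NB dispersion 0.25, 30% realized sparsity.
    """

    n_cells: int = 600
    n_genes: int = 2000
    n_groups: int = 3
    group_proportions: list[float] | None = None
    de_fraction: float = 0.1
    fold_change: float = 3.0
    dispersion: float = 0.25
    dropout_target: float = 0.3
    lib_size_mean: float = 20000.0
    lib_size_sigma: float = 0.2
    trajectory: bool = False
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_proportions is None:
            self.group_proportions = [1.0 / self.n_groups] * self.n_groups
        p = np.asarray(self.group_proportions, dtype=float)
        if len(p) != self.n_groups or abs(p.sum() - 1.0) > 1e-8 or np.any(p < 0):
            raise InvalidInputError("group_proportions must be a simplex vector of length n_groups")
        if not (0.0 <= self.dropout_target < 1.0):
            raise InvalidInputError("dropout_target must lie in [0, 1)")
        if self.fold_change <= 1.0:
            raise InvalidInputError("fold_change must exceed 1")
        if self.dispersion < 0:
            raise InvalidInputError("dispersion must be positive")


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated matrix."""

    labels: np.ndarray | None = None
    times: np.ndarray | None = None
    de_gene_sets: dict[int, np.ndarray] = field(default_factory=dict)
    group_means: np.ndarray | None = None  # n_groups x n_genes expected profiles
    batch_genes: np.ndarray | None = None
    realized_sparsity: float = 0.0


def _base_means(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    # moderately skewed gene abundances; deep enough mean coverage that the
    # negative-binomial baseline stays below the lowest sparsity target (28%)
    return rng.gamma(shape=1.5, scale=1.0 / 1.5, size=spec.n_genes) + 0.05


def _nb_sample(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw: NB with Var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mean).astype(np.float64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(np.float64)


def _apply_dropout(
    counts: np.ndarray, target: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    zero_frac = float(np.mean(counts == 0))
    if target <= zero_frac:
        if target > 0 and zero_frac - target > 0.05:
            raise InvalidInputError(
                f"infeasible dropout_target {target:.2f}: sampling noise alone "
                f"already leaves {zero_frac:.2f} zeros"
            )
        return counts, zero_frac
    p_extra = (target - zero_frac) / (1.0 - zero_frac)
    mask = rng.random(counts.shape) < p_extra
    out = np.where(mask, 0.0, counts)
    return out, float(np.mean(out == 0))


def simulate_counts(spec: SimulationSpec) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Draw one matrix (and its ground truth) from ``spec``.

    Group mode returns per-cell integer labels; trajectory mode returns the
    true pseudotimes of cells ordered along a non-branching path.  The draw
    is fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.trajectory:
        return _simulate_trajectory(spec, rng)
    return _simulate_groups(spec, rng)


def _group_mean_profiles(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    base = _base_means(spec, rng)
    n_de = int(round(spec.de_fraction * spec.n_genes))
    means = np.tile(base, (spec.n_groups, 1))
    de_sets: dict[int, np.ndarray] = {}
    for g in range(spec.n_groups):
        de = rng.choice(spec.n_genes, size=n_de, replace=False)
        # up- or down-regulate each marker; same magnitude either way
        direction = rng.choice([-1.0, 1.0], size=n_de)
        means[g, de] = means[g, de] * spec.fold_change**direction
        de_sets[g] = np.sort(de)
    return means, de_sets


def _simulate_groups(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[ExpressionMatrix, SimulationTruth]:
    means, de_sets = _group_mean_profiles(spec, rng)
    labels = rng.choice(spec.n_groups, size=spec.n_cells, p=spec.group_proportions)
    lib = spec.lib_size_mean * np.exp(rng.normal(0.0, spec.lib_size_sigma, size=spec.n_cells))
    profiles = means[labels]  # n_cells x n_genes expected relative expression
    expected = profiles / profiles.sum(axis=1, keepdims=True) * lib[:, None]
    if spec.noiseless:
        counts = expected
        realized = float(np.mean(counts == 0))
    else:
        counts = _nb_sample(expected, spec.dispersion, rng)
        counts, realized = _apply_dropout(counts, spec.dropout_target, rng)
    mat = ExpressionMatrix.from_array(counts)
    truth = SimulationTruth(
        labels=labels, de_gene_sets=de_sets, group_means=means, realized_sparsity=realized
    )
    return mat, truth


def _simulate_trajectory(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Non-branching path: markers switch on (or off) sigmoidally in time."""
    base = _base_means(spec, rng)
    n_de = max(2, int(round(spec.de_fraction * spec.n_genes)))
    de = np.sort(rng.choice(spec.n_genes, size=n_de, replace=False))
    midpoints = rng.uniform(0.0, 1.0, size=n_de)
    direction = rng.choice([-1.0, 1.0], size=n_de)
    t = np.sort(rng.uniform(0.0, 1.0, size=spec.n_cells))
    # log-fold-change ramps through a sigmoid centred at each gene's midpoint
    act = 1.0 / (1.0 + np.exp(-(t[:, None] - midpoints[None, :]) / 0.1))
    logfc = direction[None, :] * np.log(spec.fold_change) * act
    profiles = np.tile(base, (spec.n_cells, 1))
    profiles[:, de] = profiles[:, de] * np.exp(logfc)
    lib = spec.lib_size_mean * np.exp(rng.normal(0.0, spec.lib_size_sigma, size=spec.n_cells))
    expected = profiles / profiles.sum(axis=1, keepdims=True) * lib[:, None]
    if spec.noiseless:
        counts = expected
        realized = float(np.mean(counts == 0))
    else:
        counts = _nb_sample(expected, spec.dispersion, rng)
        counts, realized = _apply_dropout(counts, spec.dropout_target, rng)
    mat = ExpressionMatrix.from_array(counts)
    truth = SimulationTruth(times=t, de_gene_sets={0: de}, realized_sparsity=realized)
    return mat, truth


def simulate_batches(
    spec: SimulationSpec,
    n_batches: int = 2,
    batch_gene_fraction: float = 0.1,
    batch_fold: float = 3.0,
) -> list[tuple[ExpressionMatrix, SimulationTruth]]:
    """Draw ``n_batches`` data sets sharing one group structure.

    Each batch applies a batch-specific multiplicative shift (``batch_fold``,
    random direction per gene) to its own random ``batch_gene_fraction``
    subset of genes, emulating data sets of the same tissue measured on
    different platforms.  The first batch is left unshifted.
    """
    if n_batches < 2:
        raise InvalidInputError("need at least 2 batches")
    rng = np.random.default_rng(spec.seed)
    means, de_sets = _group_mean_profiles(spec, rng)
    out = []
    n_shift = int(round(batch_gene_fraction * spec.n_genes))
    for b in range(n_batches):
        batch_means = means.copy()
        shifted = None
        if b > 0 and n_shift > 0 and batch_fold > 1.0:
            shifted = np.sort(rng.choice(spec.n_genes, size=n_shift, replace=False))
            direction = rng.choice([-1.0, 1.0], size=n_shift)
            batch_means[:, shifted] = batch_means[:, shifted] * batch_fold ** direction[None, :]
        labels = rng.choice(spec.n_groups, size=spec.n_cells, p=spec.group_proportions)
        lib = spec.lib_size_mean * np.exp(rng.normal(0.0, spec.lib_size_sigma, size=spec.n_cells))
        profiles = batch_means[labels]
        expected = profiles / profiles.sum(axis=1, keepdims=True) * lib[:, None]
        counts = _nb_sample(expected, spec.dispersion, rng)
        counts, realized = _apply_dropout(counts, spec.dropout_target, rng)
        mat = ExpressionMatrix.from_array(counts, prefix=f"b{b}_cell")
        out.append(
            (
                mat,
                SimulationTruth(
                    labels=labels,
                    de_gene_sets=de_sets,
                    group_means=batch_means,
                    batch_genes=shifted,
                    realized_sparsity=realized,
                ),
            )
        )
    return out
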