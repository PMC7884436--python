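"""Cell segregation: k-nn spectral clustering with consensus and voting.

Cells are clustered in the compressed latent space.  Similarity between two
cells is derived from the Pearson correlation of their latent vectors,
``s = (1 + r) / 2``, kept only for each cell's k nearest neighbours so the
affinity graph stays sparse.  Spectral clustering then partitions the graph:
eigenvectors of the symmetric normalised Laplacian ``L_sym = I - D^-1/2 A
D^-1/2`` for the k smallest eigenvalues are row-normalised and split by
k-means.

The number of clusters is estimated from two indices computed over a scan of
candidate counts j on a subsample: the between-over-total sum-of-squares
ratio, and the relative change of the within sum of squares from j to j+1;
the partitions scanned come from the spectral embedding whose dimension
grows with j, and the sums of squares are measured on the latent vectors.

To avoid local minima, the projection-plus-clustering process is repeated
over several independently trained compression models and the replicate
partitions are merged by weighted meta-clustering (wMetaC): co-clustering
frequencies s_ij give cell-pair weights w_ij = s_ij (1 - s_ij), clusters
from all replicates are compared by cell-weighted Jaccard overlap,
hierarchically merged, and each cell votes with its replicate memberships.

For very large data sets an optional voting procedure clusters only a core
subset and assigns the remaining cells by k-nearest-neighbour majority vote.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.linalg import eigsh
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .latent_model import encode, train_stacked_vae
from .types import ClusteringResult, CompressedMatrix, InvalidInputError, ScaledMatrix

logger = logging.getLogger(__name__)

#: above this eigenproblem size the sparse (ARPACK) path is used
_DENSE_EIG_LIMIT = 2000
DEFAULT_N_REPLICATES = 10
DEFAULT_VOTE_THRESHOLD = 50_000
DEFAULT_SUBSAMPLE = 2000


def default_k_nn(n: int) -> int:
    return int(min(n - 1, np.ceil(np.sqrt(n))))


@dataclass
class AffinityGraph:
    """Sparse symmetric nonnegative cell-cell affinity with zero diagonal."""

    matrix: sp.csr_matrix
    k_nn: int

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ClusterIndexScan:
    """Diagnostics of the cluster-count scan.

    ``index1[j]`` is SS_between / SS_total at j clusters; ``index2[j]`` is
    the relative change of SS_within from j to j+1 clusters.  The sums of
    squares are measured on the subsampled latent vectors.
    """

    j_values: np.ndarray
    index1: np.ndarray
    index2: np.ndarray
    ss_between: np.ndarray
    ss_within: np.ndarray
    ss_total: np.ndarray
    k_index1: int
    k_index2: int


def pearson_similarity(z: np.ndarray, other: np.ndarray | None = None) -> np.ndarray:
    """Pairwise ``(1 + pearson) / 2`` similarity between rows; in [0, 1]."""
    z = np.asarray(z, dtype=np.float64)
    sd = z.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.where(sd == 0)[0][0])
        raise InvalidInputError(
            f"cell at row {bad} has zero variance across latent dimensions; "
            "Pearson similarity is undefined for it"
        )
    zc = (z - z.mean(axis=1, keepdims=True)) / sd[:, None]
    if other is None:
        r = zc @ zc.T / z.shape[1]
    else:
        other = np.asarray(other, dtype=np.float64)
        sd2 = other.std(axis=1)
        if np.any(sd2 == 0):
            bad = int(np.where(sd2 == 0)[0][0])
            raise InvalidInputError(f"cell at row {bad} has zero variance across latent dimensions")
        oc = (other - other.mean(axis=1, keepdims=True)) / sd2[:, None]
        r = zc @ oc.T / z.shape[1]
    return (1.0 + np.clip(r, -1.0, 1.0)) / 2.0


def build_knn_affinity(z: CompressedMatrix | np.ndarray, k_nn: int | None = None) -> AffinityGraph:
    """Sparse affinity: each cell keeps its ``k_nn`` most similar neighbours.

    The kept entries are ``(1 + r) / 2`` Pearson similarities; the matrix is
    symmetrised with an elementwise maximum, so a neighbour relation in
    either direction survives.
    """
    values = z.values if isinstance(z, CompressedMatrix) else np.asarray(z, float)
    n = values.shape[0]
    if k_nn is None:
        k_nn = default_k_nn(n)
    if not (1 <= k_nn < n):
        raise InvalidInputError(f"need 1 <= k_nn < n_cells, got k_nn={k_nn}, n={n}")
    s = pearson_similarity(values)
    np.fill_diagonal(s, -np.inf)  # self never a neighbour
    a = np.zeros_like(s)
    nbr = np.argpartition(-s, k_nn - 1, axis=1)[:, :k_nn]
    rows = np.repeat(np.arange(n), k_nn)
    a[rows, nbr.ravel()] = s[rows, nbr.ravel()]
    a = np.maximum(a, a.T)
    np.maximum(a, 0.0, out=a)
    return AffinityGraph(matrix=sp.csr_matrix(a), k_nn=k_nn)


def _spectral_basis(g: AffinityGraph, n_vec: int, seed: int) -> np.ndarray:
    """Eigenvectors of L_sym for its ``n_vec`` smallest eigenvalues.

    Computed as the largest eigenvectors of the normalised affinity
    ``D^-1/2 A D^-1/2``; columns are ordered by ascending Laplacian
    eigenvalue.  Dense LAPACK below ``_DENSE_EIG_LIMIT`` cells, ARPACK with
    a seed-fixed start vector above.
    """
    a = g.matrix
    n = a.shape[0]
    deg = np.asarray(a.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise InvalidInputError("affinity graph has an isolated cell; increase k_nn")
    dinv = 1.0 / np.sqrt(deg)
    if n <= _DENSE_EIG_LIMIT:
        m = a.toarray() * dinv[:, None] * dinv[None, :]
        try:
            vals, vecs = np.linalg.eigh(m)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise InvalidInputError(f"eigensolver failed ({exc}); try a larger k_nn") from exc
        return vecs[:, ::-1][:, :n_vec]
    m = a.multiply(dinv[:, None]).multiply(dinv[None, :]).tocsr()
    v0 = np.random.default_rng(seed).standard_normal(n)
    # the top eigenvalues of a well-clustered graph are nearly degenerate;
    # extra Ritz vectors and a wide Lanczos subspace keep ARPACK from
    # returning a partial eigenspace
    k_req = min(n - 2, n_vec + 10)
    ncv = min(n, max(4 * k_req + 1, 40))
    try:
        vals, vecs = eigsh(m, k=k_req, which="LA", v0=v0, ncv=ncv)
    except Exception as exc:  # pragma: no cover
        raise InvalidInputError(f"eigensolver failed ({exc}); try a larger k_nn") from exc
    order = np.argsort(-vals)[:n_vec]
    return vecs[:, order]


def _row_normalize(u: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    return u / np.maximum(norms, 1e-12)


def _kmeans_labels(u: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    return km.fit_predict(u)


def knn_spectral_cluster(
    g: AffinityGraph, k: int, seed: int = 0, basis: np.ndarray | None = None
) -> np.ndarray:
    """Partition the affinity graph into ``k`` clusters.

    ``basis`` lets callers reuse a precomputed spectral basis (first ``k``
    columns are taken); used by the cluster-count scan.
    """
    n = g.n_cells
    if not (2 <= k <= n):
        raise InvalidInputError(f"need 2 <= k <= n_cells, got k={k}")
    u = _spectral_basis(g, k, seed) if basis is None else basis[:, :k]
    return _kmeans_labels(_row_normalize(u), k, seed)


def sum_of_squares(x: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(SS_between, SS_within, SS_total) of ``labels`` on rows of ``x``.

    Satisfies SS_between + SS_within = SS_total up to rounding.
    """
    mu = x.mean(axis=0)
    ss_total = float(np.sum((x - mu) ** 2))
    ss_within = 0.0
    ss_between = 0.0
    for lab in np.unique(labels):
        grp = x[labels == lab]
        c = grp.mean(axis=0)
        ss_within += float(np.sum((grp - c) ** 2))
        ss_between += grp.shape[0] * float(np.sum((c - mu) ** 2))
    return ss_between, ss_within, ss_total


def scan_cluster_indices(
    z: CompressedMatrix | np.ndarray,
    j_range: range = range(2, 16),
    subsample: int = DEFAULT_SUBSAMPLE,
    seed: int = 0,
    k_nn: int | None = None,
) -> ClusterIndexScan:
    """Cluster a subsample at every j in ``j_range`` and score both indices.

    The labels at each j come from the spectral embedding of that j (so the
    scan reflects the growing eigenvector basis); the sums of squares are
    measured on the subsampled latent vectors, whose scale does not change
    with j.
    """
    values = z.values if isinstance(z, CompressedMatrix) else np.asarray(z, float)
    n = values.shape[0]
    j_lo, j_hi = min(j_range), max(j_range)
    sub_n = min(n, subsample)
    if sub_n < j_hi + 1:
        raise InvalidInputError(f"subsample {sub_n} too small for j up to {j_hi}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=sub_n, replace=False) if sub_n < n else np.arange(n)
    zs = values[idx]
    g = build_knn_affinity(zs, k_nn)
    basis = _spectral_basis(g, j_hi + 1, seed)  # one decomposition serves every j
    ssb, ssw, sst = {}, {}, {}
    # j = 1 (single cluster) anchors both indices: SS_between = 0 there
    ssb[1], ssw[1], sst[1] = sum_of_squares(zs, np.zeros(sub_n, dtype=int))
    ssb[1] = 0.0
    for j in range(max(2, j_lo - 1), j_hi + 2):
        u = _row_normalize(basis[:, :j])
        labels = _kmeans_labels(u, j, seed)
        ssb[j], ssw[j], sst[j] = sum_of_squares(zs, labels)
    js = np.arange(j_lo, j_hi + 1)
    index1 = np.array([ssb[j] / sst[j] if sst[j] > 0 else 0.0 for j in js])
    index2 = np.array([(ssw[j + 1] - ssw[j]) / ssw[j] if ssw[j] > 0 else 0.0 for j in js])

    # knee statistic: a candidate j is strong when the index gain achieved by
    # going to j dwarfs the gain from going one step further
    eps = 1e-12
    i1 = {j: ssb[j] / sst[j] if sst[j] > 0 else 0.0 for j in ssb}
    i1[1] = 0.0
    gain = {j: i1[j] - i1.get(j - 1, 0.0) for j in range(j_lo, j_hi + 2)}
    drop = {j: abs(ssw[j] - ssw[j - 1]) / ssw[j - 1] if ssw[j - 1] > 0 else 0.0
            for j in range(j_lo, j_hi + 2)}

    def _knee(entering: dict[int, float]) -> int:
        vals = np.array([max(entering[j], 0.0) for j in js])
        ratio = vals / np.array([max(entering[j + 1], eps) for j in js])
        # a knee must be preceded by a real gain, not a noise blip
        eligible = vals >= 0.1 * vals.max()
        if not eligible.any():
            return int(js[np.argmax(vals)])
        ratio[~eligible] = -np.inf
        return int(js[np.argmax(ratio)])

    k1 = _knee(gain)
    k2 = _knee(drop)
    return ClusterIndexScan(
        j_values=js,
        index1=index1,
        index2=index2,
        ss_between=np.array([ssb[j] for j in js]),
        ss_within=np.array([ssw[j] for j in js]),
        ss_total=np.array([sst[j] for j in js]),
        k_index1=k1,
        k_index2=k2,
    )


def predict_k(
    z: CompressedMatrix | np.ndarray,
    j_range: range = range(2, 16),
    subsample: int = DEFAULT_SUBSAMPLE,
    seed: int = 0,
    k_nn: int | None = None,
) -> int:
    """Estimated number of cell types: mean of the two index predictions.

    The mean rounds half up (predictions 4 and 5 give 5).
    """
    scan = scan_cluster_indices(z, j_range=j_range, subsample=subsample, seed=seed, k_nn=k_nn)
    k = int(np.floor((scan.k_index1 + scan.k_index2) / 2.0 + 0.5))
    logger.info(
        "predict_k: index1 -> %d, index2 -> %d, final %d", scan.k_index1, scan.k_index2, k
    )
    return k


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel to 0..k-1 in order of first occurrence (permutation-invariant form)."""
    labels = np.asarray(labels)
    _, first = np.unique(labels, return_index=True)
    mapping = {labels[i]: rank for rank, i in enumerate(np.sort(first))}
    return np.array([mapping[l] for l in labels], dtype=np.int64)


def consensus_wmetac(replicate_labels: list[np.ndarray], k: int | None = None) -> np.ndarray:
    """Merge replicate partitions by weighted meta-clustering.

    Cells that replicates disagree about (co-clustering chance s strictly
    between 0 and 1) carry weight s(1-s); clusters from all replicates are
    compared by cell-weighted Jaccard overlap of their member sets, merged
    by average-linkage hierarchical clustering into ``k`` meta-clusters, and
    every cell takes the meta-cluster that most of its replicate memberships
    fall into.  If all replicates encode the same partition the common
    partition is returned directly.
    """
    if len(replicate_labels) == 0:
        raise InvalidInputError("need at least one replicate")
    labs = [_canonical(np.asarray(l)) for l in replicate_labels]
    n = labs[0].shape[0]
    if any(l.shape[0] != n for l in labs):
        raise InvalidInputError("replicate label vectors have mismatched lengths")
    if k is None:
        counts = [len(np.unique(l)) for l in labs]
        vals, freq = np.unique(counts, return_counts=True)
        k = int(vals[freq == freq.max()].max())  # mode; ties toward more clusters

    nrep = len(labs)
    s = np.zeros((n, n), dtype=np.float32)
    for l in labs:
        s += (l[:, None] == l[None, :])
    s /= nrep
    w = s * (1.0 - s)
    if float(w.max()) == 0.0:  # perfect agreement across replicates
        return labs[0]
    # ambiguous cells count more, but boundedly so: raw s(1-s) row sums
    # concentrate all mass on disputed cells when replicates mostly agree,
    # which makes corresponding clusters read as dissimilar; mapping the
    # weights to [1, 2] keeps agreed cells in the overlap computation
    v = w.sum(axis=1).astype(np.float64)
    cell_weight = 1.0 + v / v.max()

    members: list[np.ndarray] = []  # boolean membership per cluster in the union C
    owner_rep: list[int] = []
    for r, l in enumerate(labs):
        for lab in np.unique(l):
            members.append(l == lab)
            owner_rep.append(r)
    c = len(members)
    memb = np.stack(members)  # c x n boolean
    wm = memb * cell_weight[None, :]
    inter = wm @ memb.T  # weighted intersection sizes
    tot = wm.sum(axis=1)
    union = tot[:, None] + tot[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(sim, 1.0)
    dist = squareform(1.0 - np.minimum(sim, 1.0), checks=False)
    meta = fcluster(linkage(dist, method="average"), t=min(k, c), criterion="maxclust") - 1

    votes = np.zeros((n, meta.max() + 1), dtype=np.int64)
    for ci in range(c):
        votes[memb[ci], meta[ci]] += 1
    final = votes.argmax(axis=1)  # argmax breaks ties toward the lower meta index
    return _canonical(final)


def vote_assign(
    core_labels: np.ndarray,
    core_indices: np.ndarray,
    z: CompressedMatrix | np.ndarray,
    k_vote: int = 10,
) -> np.ndarray:
    """Extend a core partition to all cells by k-nn majority vote.

    Core cells keep their labels; every other cell takes the majority label
    of its ``k_vote`` most Pearson-similar core cells, ties resolved by the
    single most similar neighbour's label.
    """
    values = z.values if isinstance(z, CompressedMatrix) else np.asarray(z, float)
    n = values.shape[0]
    core_indices = np.asarray(core_indices)
    core_labels = np.asarray(core_labels)
    if core_indices.size == 0:
        raise InvalidInputError("core subset is empty")
    if core_labels.shape[0] != core_indices.shape[0]:
        raise InvalidInputError("core_labels and core_indices must have equal length")
    if k_vote > core_indices.size:
        raise InvalidInputError("k_vote exceeds the core size")
    labels = np.full(n, -1, dtype=np.int64)
    labels[core_indices] = core_labels
    rest = np.setdiff1d(np.arange(n), core_indices)
    if rest.size == 0:
        return labels
    sim = pearson_similarity(values[rest], values[core_indices])
    k_lab = int(core_labels.max()) + 1
    nbr = np.argpartition(-sim, k_vote - 1, axis=1)[:, :k_vote]
    for i, row in enumerate(rest):
        neigh = nbr[i]
        cnt = np.bincount(core_labels[neigh], minlength=k_lab)
        top = cnt.max()
        winners = np.where(cnt == top)[0]
        if winners.size == 1:
            labels[row] = winners[0]
        else:
            labels[row] = core_labels[neigh[np.argmax(sim[i, neigh])]]
    return labels


def cluster_pipeline(
    x: ScaledMatrix,
    n_replicates: int = DEFAULT_N_REPLICATES,
    k: int | None = None,
    seed: int = 0,
    k_nn: int | None = None,
    j_range: range = range(2, 16),
    vote_threshold: int = DEFAULT_VOTE_THRESHOLD,
    core_size: int = DEFAULT_SUBSAMPLE,
    k_vote: int = 10,
    **vae_kwargs,
) -> ClusteringResult:
    """Full segregation: replicate compressions, spectral clustering, consensus.

    Trains ``n_replicates`` stacked VAEs with seeds derived from the master
    seed, clusters each compressed space, and merges the partitions with
    wMetaC.  ``k`` is predicted from the first compression when not given.
    When the data exceed ``vote_threshold`` cells, clustering runs on a
    random core of ``core_size`` cells and the rest are vote-assigned.
    """
    n = x.n_cells
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates + 2) % (2**31)
    use_vote = n > vote_threshold
    rng = np.random.default_rng(seeds[-1])
    core = rng.choice(n, size=min(core_size, n), replace=False) if use_vote else np.arange(n)

    zs: list[np.ndarray] = []
    for r in range(n_replicates):
        model = train_stacked_vae(x, seed=int(seeds[r]), **vae_kwargs)
        zs.append(encode(model, x).values)
    if k is None:
        k = predict_k(zs[0], j_range=j_range, seed=int(seeds[-2]), k_nn=k_nn)

    replicate_labels = []
    for r, z in enumerate(zs):
        g = build_knn_affinity(z[core], k_nn)
        replicate_labels.append(knn_spectral_cluster(g, k, seed=int(seeds[r])))
    core_labels = consensus_wmetac(replicate_labels, k=k)
    if use_vote:
        labels = vote_assign(core_labels, core, zs[0], k_vote=k_vote)
    else:
        labels = core_labels
    return ClusteringResult(
        labels=labels,
        k=int(k),
        replicate_labels=replicate_labels,
        method_metadata={
            "seed": seed,
            "k_nn": k_nn if k_nn is not None else default_k_nn(len(core)),
            "n_replicates": n_replicates,
            "voting": use_vote,
            "core_indices": core if use_vote else None,
        },
    )
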