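import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from schae.clustering import (
    build_knn_affinity,
    consensus_wmetac,
    default_k_nn,
    knn_spectral_cluster,
    predict_k,
    scan_cluster_indices,
    sum_of_squares,
    vote_assign,
)
from schae.latent_model import encode, train_stacked_vae
from schae.types import InvalidInputError


def dense_spectral_oracle(z, k, seed):
    """Independent dense spectral clustering: full Pearson affinity, L_sym
    eigenvectors via numpy, row-normalised, k-means."""
    zc = (z - z.mean(1, keepdims=True)) / z.std(1, keepdims=True)
    r = np.clip(zc @ zc.T / z.shape[1], -1, 1)
    a = (1 + r) / 2
    np.fill_diagonal(a, 0)
    d = a.sum(1)
    lsym = np.eye(len(a)) - a / np.sqrt(np.outer(d, d))
    vals, vecs = np.linalg.eigh(lsym)
    u = vecs[:, :k]
    u = u / np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-12)
    return KMeans(k, n_init=50, random_state=seed).fit_predict(u)


class TestAffinity:
    def test_identical_cells_have_similarity_one(self, rng):
        z = rng.standard_normal((10, 6))
        z[1] = z[0]
        g = build_knn_affinity(z, k_nn=3)
        assert g.matrix[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pair_zero(self):
        z = np.vstack([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [1.0, 3.0, 2.0]])
        g = build_knn_affinity(z, k_nn=2)
        assert g.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_full_knn_equals_dense_similarity(self, rng):
        z = rng.standard_normal((12, 5))
        g = build_knn_affinity(z, k_nn=11)
        zc = (z - z.mean(1, keepdims=True)) / z.std(1, keepdims=True)
        expected = (1 + np.clip(zc @ zc.T / 5, -1, 1)) / 2
        np.fill_diagonal(expected, 0)
        np.testing.assert_allclose(g.matrix.toarray(), np.maximum(expected, 0), atol=1e-12)

    def test_symmetric_zero_diagonal(self, rng):
        z = rng.standard_normal((30, 8))
        a = build_knn_affinity(z, k_nn=5).matrix.toarray()
        np.testing.assert_array_equal(a, a.T)
        np.testing.assert_array_equal(np.diag(a), 0)

    def test_zero_variance_cell_rejected(self):
        z = np.ones((5, 4))
        z[1:] += np.random.default_rng(0).standard_normal((4, 4))
        with pytest.raises(InvalidInputError, match="zero variance"):
            build_knn_affinity(z, k_nn=2)


class TestSpectral:
    def test_matches_dense_oracle_on_small_instances(self, rng):
        for trial in range(25):
            n = int(rng.integers(12, 50))
            k = int(rng.integers(2, 5))
            z = rng.standard_normal((n, 6)) + rng.integers(0, k, n)[:, None] * 2.0
            g = build_knn_affinity(z, k_nn=n - 1)
            ours = knn_spectral_cluster(g, k, seed=trial)
            oracle = dense_spectral_oracle(z, k, seed=trial)
            assert adjusted_rand_score(ours, oracle) == pytest.approx(1.0)

    def test_two_component_graph_recovered_exactly(self, rng):
        for trial in range(10):
            n1, n2 = int(rng.integers(5, 15)), int(rng.integers(5, 15))
            comp = np.concatenate([np.zeros(n1, int), np.ones(n2, int)])
            # block-diagonal affinity: two disconnected cliques
            a = np.zeros((n1 + n2, n1 + n2))
            a[:n1, :n1] = rng.uniform(0.5, 1.0, (n1, n1))
            a[n1:, n1:] = rng.uniform(0.5, 1.0, (n2, n2))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            import scipy.sparse as sp

            from schae.clustering import AffinityGraph, _spectral_basis

            g = AffinityGraph(matrix=sp.csr_matrix(a), k_nn=n1 + n2 - 1)
            deg = a.sum(1)
            lsym = np.eye(len(a)) - a / np.sqrt(np.outer(deg, deg))
            vals = np.linalg.eigvalsh(lsym)
            assert np.sum(np.abs(vals) < 1e-8) == 2  # one zero eigenvalue per component
            labels = knn_spectral_cluster(g, 2, seed=trial)
            assert adjusted_rand_score(labels, comp) == pytest.approx(1.0)

    def test_separated_blobs_exact(self, blobs_latent):
        z, labels = blobs_latent
        g = build_knn_affinity(z)
        out = knn_spectral_cluster(g, 4, seed=0)
        assert adjusted_rand_score(out, labels) == pytest.approx(1.0)


class TestClusterCountScan:
    def test_ss_decomposition(self, rng):
        x = rng.standard_normal((100, 7))
        labels = rng.integers(0, 4, 100)
        ssb, ssw, sst = sum_of_squares(x, labels)
        assert ssb + ssw == pytest.approx(sst, rel=1e-10)

    def test_single_cluster_index1_zero(self, rng):
        x = rng.standard_normal((50, 5))
        ssb, ssw, sst = sum_of_squares(x, np.zeros(50, int))
        assert ssb == pytest.approx(0.0, abs=1e-8)
        assert ssw == pytest.approx(sst)

    def test_each_cell_own_cluster_index1_one(self, rng):
        x = rng.standard_normal((20, 5))
        ssb, ssw, sst = sum_of_squares(x, np.arange(20))
        assert ssw == pytest.approx(0.0, abs=1e-10)
        assert ssb / sst == pytest.approx(1.0)

    def test_scan_decomposition_holds_everywhere(self, blobs_latent):
        z, _ = blobs_latent
        scan = scan_cluster_indices(z, j_range=range(2, 8), seed=0)
        np.testing.assert_allclose(
            scan.ss_between + scan.ss_within, scan.ss_total, rtol=1e-8
        )
        assert np.all(scan.index1 >= 0) and np.all(scan.index1 <= 1)

    def test_predicts_k_on_blobs(self, blobs_latent):
        z, _ = blobs_latent
        assert predict_k(z, j_range=range(2, 10), seed=0) == 4

    def test_subsample_too_small_rejected(self, blobs_latent):
        z, _ = blobs_latent
        with pytest.raises(InvalidInputError):
            scan_cluster_indices(z[:8], j_range=range(2, 16), seed=0)


class TestConsensus:
    def test_identical_replicates_up_to_relabeling(self):
        base = np.array([0, 0, 1, 1, 2, 2, 0, 1])
        reps = [base, (base + 1) % 3, 2 - base]
        out = consensus_wmetac(reps)
        assert adjusted_rand_score(out, base) == pytest.approx(1.0)

    def test_weight_maximised_at_half(self):
        s = np.linspace(0, 1, 101)
        w = s * (1 - s)
        assert s[np.argmax(w)] == pytest.approx(0.5)
        assert w.max() == pytest.approx(0.25)

    def test_consensus_at_least_as_good_as_replicates(self, rng):
        base = rng.integers(0, 4, 400)
        reps = []
        for r in range(10):
            l = base.copy()
            flip = rng.random(400) < 0.12
            l[flip] = rng.integers(0, 4, int(flip.sum()))
            reps.append(rng.permutation(4)[l])
        cons = consensus_wmetac(reps, k=4)
        best = max(adjusted_rand_score(base, l) for l in reps)
        assert adjusted_rand_score(base, cons) >= best - 0.02

    def test_label_permutation_invariance(self, rng):
        reps = [rng.integers(0, 3, 60) for _ in range(4)]
        out1 = consensus_wmetac(reps, k=3)
        permuted = [np.random.default_rng(i).permutation(3)[l] for i, l in enumerate(reps)]
        out2 = consensus_wmetac(permuted, k=3)
        assert adjusted_rand_score(out1, out2) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            consensus_wmetac([np.zeros(5, int), np.zeros(6, int)])


class TestVoteAssign:
    def test_full_core_returns_core_labels(self, blobs_latent):
        z, labels = blobs_latent
        out = vote_assign(labels, np.arange(len(labels)), z, k_vote=5)
        np.testing.assert_array_equal(out, labels)

    def test_duplicate_cell_inherits_label(self, blobs_latent):
        z, labels = blobs_latent
        core = np.arange(0, len(labels), 2)
        z2 = z.copy()
        z2[1] = z2[0]  # cell 1 duplicates core cell 0
        out = vote_assign(labels[core], core, z2, k_vote=1)
        assert out[1] == labels[0]

    def test_majority_vote_recovers_blobs(self, blobs_latent, rng):
        z, labels = blobs_latent
        core = rng.choice(len(labels), size=len(labels) // 2, replace=False)
        out = vote_assign(labels[core], core, z, k_vote=7)
        assert adjusted_rand_score(out, labels) == pytest.approx(1.0)

    def test_empty_core_rejected(self, blobs_latent):
        z, _ = blobs_latent
        with pytest.raises(InvalidInputError):
            vote_assign(np.array([]), np.array([]), z)


def test_latent_dim_choice_is_stable(groups3_scaled, groups3_latent):
    """Clustering accuracy barely moves when the latent width varies around 15."""
    x, truth = groups3_scaled
    z15, _, _ = groups3_latent
    base = adjusted_rand_score(
        truth.labels, knn_spectral_cluster(build_knn_affinity(z15.values), 3, seed=0)
    )
    z10 = encode(train_stacked_vae(x, m=10, seed=5), x)
    ari10 = adjusted_rand_score(
        truth.labels, knn_spectral_cluster(build_knn_affinity(z10.values), 3, seed=0)
    )
    assert abs(ari10 - base) <= 0.05


def test_default_k_nn_is_sqrt_capped():
    assert default_k_nn(100) == 10
    assert default_k_nn(5) == 3  # ceil(sqrt(5)), below the n-1 cap
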