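import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from schae.pseudotime import fit_stage_r2, infer_pseudotime, pearson_distance_matrix
from schae.synthetic import SimulationSpec, simulate_counts
from schae.types import CompressedMatrix, InvalidInputError


def cm(values):
    values = np.asarray(values, float)
    return CompressedMatrix(values, [f"c{i}" for i in range(len(values))])


def brute_force_mst_weight(d):
    """Minimum spanning-tree weight by exhaustive search over edge subsets."""
    n = d.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for subset in itertools.combinations(range(len(edges)), n - 1):
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        ok = True
        w = 0.0
        for ei in subset:
            i, j = edges[ei]
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
            w += d[i, j]
        if ok and w < best:
            best = w
    return best


class TestInferPseudotime:
    def test_start_cell_time_zero(self, rng):
        z = cm(rng.standard_normal((10, 5)))
        res = infer_pseudotime(z, "c3")
        assert res.times[3] == 0.0
        assert np.all(res.times >= 0)
        assert np.all(np.isfinite(res.times))
        assert len(res.tree_edges) == 9

    def test_chain_additivity(self):
        # three latent profiles forming a chain a--b--c in Pearson distance
        z = cm([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.5, 3.6], [1.0, 2.5, 3.4, 3.0]])
        d = pearson_distance_matrix(z.values)
        res = infer_pseudotime(z, "c0")
        # MST of 3 nodes drops the largest edge; times add along the chain
        order = np.argsort(res.times)
        far = order[-1]
        mid = order[1]
        assert res.times[far] == pytest.approx(res.times[mid] + d[mid, far], abs=1e-9)

    def test_missing_start_cell(self, rng):
        z = cm(rng.standard_normal((5, 4)))
        with pytest.raises(InvalidInputError, match="not found"):
            infer_pseudotime(z, "nope")

    def test_single_cell_rejected(self, rng):
        z = cm(rng.standard_normal((1, 4)))
        with pytest.raises(InvalidInputError):
            infer_pseudotime(z, "c0")

    def test_mst_weight_matches_brute_force(self, rng):
        for trial in range(20):
            n = int(rng.integers(4, 8))
            z = rng.standard_normal((n, 6))
            d = pearson_distance_matrix(z)
            res = infer_pseudotime(cm(z), "c0")
            total = sum(w for *_, w in res.tree_edges)
            assert total == pytest.approx(brute_force_mst_weight(d), abs=1e-9)

    def test_tree_triangle_equality(self, rng):
        z = cm(rng.standard_normal((15, 6)))
        res = infer_pseudotime(z, "c0")
        # build adjacency, walk path start->d and check additivity via parents
        import scipy.sparse as sp
        from scipy.sparse.csgraph import dijkstra

        n = 15
        a = np.zeros((n, n))
        for i, j, w in res.tree_edges:
            a[i, j] = a[j, i] = max(w, 1e-300)
        dist0, pred = dijkstra(sp.csr_matrix(a), directed=False, indices=0,
                               return_predecessors=True)
        for dcell in range(1, n):
            c = pred[dcell]  # on the path from start to dcell
            if c >= 0:
                path_cd = dist0[dcell] - dist0[c]
                assert res.times[dcell] == pytest.approx(res.times[c] + path_cd, abs=1e-9)

    def test_duplicate_cell_attaches_at_zero_cost(self, rng):
        z = rng.standard_normal((12, 6))
        res1 = infer_pseudotime(cm(z), "c0")
        z2 = np.vstack([z, z[5]])
        res2 = infer_pseudotime(cm(z2), "c0")
        np.testing.assert_allclose(res2.times[:12], res1.times, atol=1e-8)
        assert res2.times[12] == pytest.approx(res1.times[5], abs=1e-8)

    def test_noiseless_trajectory_perfectly_ordered(self):
        spec = SimulationSpec(
            n_cells=300, n_genes=50, de_fraction=1.0, trajectory=True,
            noiseless=True, dropout_target=0.0, seed=7,
        )
        mat, truth = simulate_counts(spec)
        z = CompressedMatrix(mat.values, mat.cell_ids)
        res = infer_pseudotime(z, mat.cell_ids[0])
        rho = spearmanr(res.times, truth.times).statistic
        assert abs(rho) == pytest.approx(1.0)


class TestStageR2:
    def test_times_equal_ranks_r2_one(self):
        stages = np.array(["s0", "s1", "s2", "s0", "s1", "s2"])
        times = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        assert fit_stage_r2(times, stages) == pytest.approx(1.0)

    def test_permuted_times_r2_near_zero(self, rng):
        n = 2000
        stages = rng.integers(0, 4, n)
        times = rng.permutation(stages.astype(float))
        assert fit_stage_r2(times, stages) < 0.01

    def test_bounds(self, rng):
        for _ in range(10):
            t = rng.standard_normal(30)
            s = rng.integers(0, 3, 30)
            if len(np.unique(s)) < 2:
                continue
            r2 = fit_stage_r2(t, s)
            assert 0.0 <= r2 <= 1.0

    def test_constant_times_return_zero(self):
        assert fit_stage_r2(np.ones(6), np.array([0, 0, 1, 1, 2, 2])) == 0.0

    def test_single_stage_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_stage_r2(np.arange(4.0), np.zeros(4))
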