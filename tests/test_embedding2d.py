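import numpy as np
import pytest

from schae.embedding2d import (
    _kl_grad_wrt_coords,
    _q_from_coords,
    fit_embedding,
    kl_divergence,
    neighbor_probabilities,
    transform_distances,
)
from schae.types import CompressedMatrix, InvalidInputError


def cm(values):
    values = np.asarray(values, float)
    return CompressedMatrix(values, [f"c{i}" for i in range(len(values))])


class TestTransformDistances:
    def test_rows_standardised(self, rng):
        z = rng.standard_normal((20, 6))
        t = transform_distances(z).values
        n = 20
        off = ~np.eye(n, dtype=bool)
        for i in range(n):
            row = t[i][off[i]]
            assert row.mean() == pytest.approx(0.0, abs=1e-6)
            assert row.std() == pytest.approx(1.0, abs=1e-6)

    def test_equidistant_cells_all_zero(self):
        # three mutually equidistant cells: zero spread is guarded to 0
        z = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        t = transform_distances(z).values
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_monotone_within_row(self, rng):
        z = rng.standard_normal((15, 8))
        from schae.pseudotime import pearson_distance_matrix

        d = pearson_distance_matrix(z)
        t = transform_distances(z).values
        i = 3
        others = np.delete(np.arange(15), i)
        order = others[np.argsort(d[i, others])]
        assert np.all(np.diff(t[i, order]) >= -1e-12)

    def test_too_few_cells_rejected(self):
        with pytest.raises(InvalidInputError):
            transform_distances(np.random.default_rng(0).standard_normal((2, 4)))


class TestNeighborProbabilities:
    def test_joint_sums_to_one_symmetric_zero_diagonal(self, rng):
        z = rng.standard_normal((12, 5))
        p = neighbor_probabilities(transform_distances(z))
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p, p.T, atol=1e-15)
        np.testing.assert_array_equal(np.diag(p), 0.0)
        assert np.all(p >= 0)

    def test_identical_distance_profiles_give_identical_rows(self):
        t = np.zeros((4, 4))
        t[0, 2:] = t[1, 2:] = 1.5
        t[2:, 0] = t[2:, 1] = 1.5
        from schae.embedding2d import _conditional_from_t

        c = _conditional_from_t(t)
        np.testing.assert_allclose(c[0, 2:], c[1, 2:])

    def test_nearest_neighbor_gets_largest_probability(self, rng):
        z = rng.standard_normal((10, 6))
        from schae.embedding2d import _conditional_from_t
        from schae.pseudotime import pearson_distance_matrix

        d = pearson_distance_matrix(z)
        c = _conditional_from_t(transform_distances(z).values)
        for i in range(10):
            others = np.delete(np.arange(10), i)
            assert c[i].argmax() == others[np.argmin(d[i, others])]


class TestKL:
    def test_kl_of_identical_distributions_is_zero(self, rng):
        z = rng.standard_normal((10, 4))
        p = neighbor_probabilities(transform_distances(z))
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_kl_nonnegative_and_matches_direct_sum(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 20))
            a = rng.uniform(0.1, 1, (n, n))
            b = rng.uniform(0.1, 1, (n, n))
            for m in (a, b):
                np.fill_diagonal(m, 0)
                m += m.T
                m /= m.sum()
            direct = sum(
                a[i, j] * np.log(a[i, j] / b[i, j])
                for i in range(n)
                for j in range(n)
                if i != j
            )
            assert kl_divergence(a, b) == pytest.approx(direct, abs=1e-10)
            assert kl_divergence(a, b) >= 0

    def test_gradient_matches_finite_differences(self, rng):
        n = 8
        y = rng.standard_normal((n, 2))
        p = neighbor_probabilities(transform_distances(rng.standard_normal((n, 5))))
        kl, g = _kl_grad_wrt_coords(y, p)
        h = 1e-6
        for i in (0, 3, 7):
            for d in (0, 1):
                yp, ym = y.copy(), y.copy()
                yp[i, d] += h
                ym[i, d] -= h
                num = (
                    kl_divergence(p, _q_from_coords(yp)[0])
                    - kl_divergence(p, _q_from_coords(ym)[0])
                ) / (2 * h)
                assert g[i, d] == pytest.approx(num, abs=1e-5)

    def test_rigid_motion_leaves_q_unchanged(self, rng):
        y = rng.standard_normal((12, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        q1 = _q_from_coords(y)[0]
        q2 = _q_from_coords(y @ rot.T + np.array([3.0, -1.0]))[0]
        np.testing.assert_allclose(q1, q2, atol=1e-10)


class TestFitEmbedding:
    def test_kl_decreases_and_checkpoints_non_increasing(self, rng):
        z = cm(rng.standard_normal((40, 6)) + rng.integers(0, 2, 40)[:, None] * 3)
        emb = fit_embedding(z, epochs=30, seed=0)
        assert emb.final_kl <= emb.kl_history[0]
        assert np.all(np.diff(emb.checkpoint_kl) <= 1e-12)
        assert emb.coords.shape == (40, 2)
        assert np.all(np.isfinite(emb.coords))

    def test_permutation_equivariance(self, rng):
        z = rng.standard_normal((25, 5))
        perm = rng.permutation(25)
        emb1 = fit_embedding(cm(z), epochs=15, seed=3)
        emb2 = fit_embedding(cm(z[perm]), epochs=15, seed=3)
        np.testing.assert_allclose(emb2.coords, emb1.coords[perm], atol=1e-6)
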