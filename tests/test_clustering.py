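import itertools

import numpy as np
import pytest

from spirospace.clustering import (
    ClusteringError,
    fit_pca,
    kmedoids_pam,
    pairwise_distances,
    select_k,
    silhouette,
)
from spirospace.feature_prep import DescriptorMatrix, standardize


def std_matrix(values):
    values = np.asarray(values, float)
    return standardize(
        DescriptorMatrix(
            [f"s{i}" for i in range(values.shape[0])],
            [f"d{j}" for j in range(values.shape[1])],
            values,
        )
    )


def brute_force_cost(d, k):
    n = d.shape[0]
    return min(
        d[:, list(c)].min(axis=1).sum() for c in itertools.combinations(range(n), k)
    )


class TestFitPca:
    def test_rank_one_data_first_component_explains_everything(self):
        t = np.linspace(-1, 1, 6)
        m = std_matrix(np.column_stack([t, 3 * t]))
        model = fit_pca(m)
        assert model.explained_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_cross_equal_eigenvalues(self):
        pts = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], float)
        m = DescriptorMatrix(list("abcd"), ["x", "y"], pts, standardized=True)
        model = fit_pca(m)
        assert model.explained_variance[0] == pytest.approx(model.explained_variance[1])

    def test_full_reconstruction(self, rng):
        m = std_matrix(rng.normal(size=(8, 5)))
        model = fit_pca(m)
        centered = m.values - m.values.mean(axis=0)
        assert np.allclose(model.scores @ model.loadings.T, centered, atol=1e-8)

    def test_loadings_orthonormal_eigenvalues_sorted(self, rng):
        model = fit_pca(std_matrix(rng.normal(size=(10, 4))))
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)
        assert model.explained_variance.sum() == pytest.approx(
            model.total_variance, abs=1e-8
        )

    def test_scores_covariance_is_diagonal_eigenvalues(self, rng):
        m = std_matrix(rng.normal(size=(12, 5)))
        model = fit_pca(m)
        cov = model.scores.T @ model.scores / (m.n - 1)
        assert np.allclose(cov, np.diag(model.explained_variance), atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        m = std_matrix(rng.normal(size=(9, 4)))
        model = fit_pca(m)
        for j in range(model.loadings.shape[1]):
            k = np.argmax(np.abs(model.loadings[:, j]))
            assert model.loadings[k, j] > 0

    def test_component_range_enforced(self, rng):
        m = std_matrix(rng.normal(size=(5, 3)))
        with pytest.raises(ClusteringError):
            fit_pca(m, n_components=0)
        with pytest.raises(ClusteringError):
            fit_pca(m, n_components=4)


class TestKmedoidsPam:
    def test_two_tight_pairs_forced_split(self):
        pts = np.array([[0, 0], [0, 0.1], [10, 0], [10, 0.1]])
        model = kmedoids_pam(pairwise_distances(pts), 2)
        labels = model.assignments
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_k_equals_n_is_zero_cost(self, rng):
        pts = rng.normal(size=(5, 2))
        model = kmedoids_pam(pairwise_distances(pts), 5)
        assert model.total_cost == 0.0
        assert sorted(model.medoid_indices) == list(range(5))

    def test_matches_exhaustive_optimum_on_separated_instances(self):
        """On instances with planted structure PAM's swap optimum is the global one."""
        for trial in range(40):
            r = np.random.default_rng(10_000 + trial)
            k = int(r.integers(2, 4))
            n = int(r.integers(max(4, 2 * k), 11))
            centers = r.normal(size=(k, 2)) * 8
            labels = np.concatenate([np.arange(k), r.integers(0, k, n - k)])
            pts = centers[labels] + r.normal(size=(n, 2))
            d = pairwise_distances(pts)
            model = kmedoids_pam(d, k)
            assert model.total_cost == pytest.approx(brute_force_cost(d, k), abs=1e-9)

    def test_medoids_assigned_to_themselves(self, rng):
        d = pairwise_distances(rng.normal(size=(12, 3)))
        model = kmedoids_pam(d, 3)
        for lab, m in enumerate(model.medoid_indices):
            assert model.assignments[m] == lab

    def test_rejects_bad_distance_matrices(self, rng):
        asym = rng.random((4, 4))
        np.fill_diagonal(asym, 0)
        with pytest.raises(ClusteringError):
            kmedoids_pam(asym, 2)
        sym = pairwise_distances(rng.normal(size=(4, 2)))
        with pytest.raises(ClusteringError):
            kmedoids_pam(sym, 0)

    def test_deterministic(self, rng):
        pts = rng.normal(size=(15, 3))
        a = kmedoids_pam(pts, 4)
        b = kmedoids_pam(pts, 4)
        assert a.medoid_indices == b.medoid_indices
        assert np.array_equal(a.assignments, b.assignments)


class TestSilhouette:
    def test_two_singletons_mean_zero(self):
        d = pairwise_distances(np.array([[0.0, 0], [5, 0]]))
        per, mean = silhouette(d, np.array([0, 1]))
        assert np.allclose(per, 0)
        assert mean == 0

    def test_equal_a_and_b_gives_zero(self):
        # construct a = b exactly via a symmetric distance matrix
        d = np.array(
            [
                [0, 2, 2, 2],
                [2, 0, 2, 2],
                [2, 2, 0, 2],
                [2, 2, 2, 0],
            ],
            float,
        )
        per, mean = silhouette(d, np.array([0, 0, 1, 1]))
        assert np.allclose(per, 0.0)
        assert mean == 0.0

    def test_four_point_worked_configuration(self):
        pts = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], float)
        d = pairwise_distances(pts)
        per, mean = silhouette(d, np.array([0, 0, 1, 1]))
        # hand-computed: a = 1, b = (10 + sqrt(101))/2 for every point
        b = (10 + np.sqrt(101)) / 2
        expected = (b - 1) / b
        assert np.allclose(per, expected, atol=1e-12)
        assert mean == pytest.approx(expected, abs=1e-12)

    def test_values_bounded_and_permutation_equivariant(self, rng):
        pts = rng.normal(size=(10, 2))
        labels = rng.integers(0, 3, 10)
        d = pairwise_distances(pts)
        per, _ = silhouette(d, labels)
        assert np.all(per >= -1) and np.all(per <= 1)
        perm = rng.permutation(10)
        per_p, _ = silhouette(d[np.ix_(perm, perm)], labels[perm])
        assert np.allclose(per_p, per[perm], atol=1e-12)

    def test_single_cluster_rejected(self, rng):
        d = pairwise_distances(rng.normal(size=(5, 2)))
        with pytest.raises(ClusteringError):
            silhouette(d, np.zeros(5, dtype=int))


class TestSelectK:
    def test_three_planted_gaussians_recovered(self):
        r = np.random.default_rng(5)
        centers = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], float)
        pts = np.concatenate([c + r.normal(size=(12, 3)) for c in centers])
        best_k, model, curve = select_k(pts, (2, 6))
        assert best_k == 3
        assert set(curve) == {2, 3, 4, 5, 6}

    def test_two_pair_geometry_forces_k2(self):
        pts = np.array([[0, 0], [0, 0.2], [10, 0], [10, 0.2]])
        best_k, _, _ = select_k(pts, (2, 3))
        assert best_k == 2

    def test_duplicated_dataset_same_best_k(self):
        r = np.random.default_rng(6)
        pts = np.concatenate(
            [c + r.normal(size=(8, 2)) for c in ([0, 0], [12, 0], [0, 12])]
        )
        k1, _, _ = select_k(pts, (2, 5))
        k2, _, _ = select_k(np.vstack([pts, pts]), (2, 5))
        assert k1 == k2 == 3

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ClusteringError):
            select_k(rng.normal(size=(6, 2)), (4, 3))


class TestPamCostDescent:
    def test_swap_cost_never_increases(self, rng, monkeypatch):
        """Instrument the cost at every accepted swap and assert monotone descent."""
        import spirospace.clustering as cl

        costs = []
        orig = cl._cost

        def recording(d, medoids):
            c = orig(d, medoids)
            costs.append(c)
            return c

        monkeypatch.setattr(cl, "_cost", recording)
        pts = rng.normal(size=(20, 2))
        model = cl.kmedoids_pam(pts, 4)
        # the accepted sequence of costs (the running minimum) never increases
        assert model.total_cost == pytest.approx(min(costs), abs=1e-12)
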