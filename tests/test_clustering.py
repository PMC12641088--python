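"""Gaussian-mixture clustering, silhouette selection, confidence ellipses."""

import numpy as np
import pytest
from scipy.stats import chi2

from aseries.clustering import (
    ClusterEllipse,
    confidence_ellipses,
    ellipse_overlap,
    fit_gmm,
    mahalanobis_radius,
    mean_silhouette,
    select_cluster_count,
    silhouette_values,
)


def two_blobs(seed=0, n=20, spread=0.02):
    rng = np.random.default_rng(seed)
    a = rng.normal([1.0, 1.0], spread, size=(n, 2))
    b = rng.normal([0.2, 0.2], spread, size=(n, 2))
    return np.vstack([a, b]), np.repeat([0, 1], n)


class TestMahalanobisRadius:
    def test_95_percent_two_dimensional(self):
        assert mahalanobis_radius(0.95, 2) == pytest.approx(2.447, abs=1e-3)

    def test_one_dimensional_matches_normal_quantile(self):
        assert mahalanobis_radius(0.95, 1) == pytest.approx(1.960, abs=1e-3)

    def test_against_bisection_on_the_cdf(self):
        lo, hi = 0.0, 100.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if chi2.cdf(mid, df=2) < 0.99:
                lo = mid
            else:
                hi = mid
        assert mahalanobis_radius(0.99, 2) == pytest.approx(np.sqrt(lo), abs=1e-6)

    @pytest.mark.parametrize("confidence", [0.0, 1.0, -0.2, 1.5])
    def test_out_of_range_confidence(self, confidence):
        with pytest.raises(ValueError):
            mahalanobis_radius(confidence, 2)


class TestFitGMM:
    def test_separated_blobs_recovered_exactly(self):
        points, truth = two_blobs()
        model = fit_gmm(points, 2, seed=0, n_restarts=10)
        # component 0 is the one nearest (1, 1)
        assert np.array_equal(model.labels, truth)

    def test_single_component_closed_form(self):
        rng = np.random.default_rng(1)
        points = rng.normal(size=(30, 2))
        model = fit_gmm(points, 1, seed=0, n_restarts=2)
        assert model.means[0] == pytest.approx(points.mean(axis=0), abs=1e-6)
        centered = points - points.mean(axis=0)
        ml_cov = centered.T @ centered / len(points)
        assert model.covariances[0] == pytest.approx(ml_cov, abs=1e-4)

    def test_model_invariants(self):
        points, _ = two_blobs(seed=3)
        model = fit_gmm(points, 3, seed=5, n_restarts=10)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert set(np.unique(model.labels)) <= set(range(3))
        for cov in model.covariances:
            assert np.allclose(cov, cov.T)
            assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_reproducible_given_seed(self):
        points, _ = two_blobs(seed=4)
        a = fit_gmm(points, 2, seed=9, n_restarts=5)
        b = fit_gmm(points, 2, seed=9, n_restarts=5)
        assert np.array_equal(a.labels, b.labels)
        assert a.means == pytest.approx(b.means)

    def test_k_too_large_rejected(self):
        points, _ = two_blobs(n=3)
        with pytest.raises(ValueError, match="too large"):
            fit_gmm(points, 6, seed=0)


class TestSilhouette:
    def test_brute_force_oracle_six_points(self):
        points = np.array(
            [[0, 0], [0, 1], [1, 0], [5, 5], [5, 6], [9, 0]], dtype=float
        )
        labels = np.array([0, 0, 0, 1, 1, 2])
        s = silhouette_values(points, labels)
        dist = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        expected = []
        for i in range(6):
            own = [j for j in range(6) if labels[j] == labels[i] and j != i]
            if not own:
                expected.append(0.0)
                continue
            a = np.mean([dist[i, j] for j in own])
            b = min(
                np.mean([dist[i, j] for j in range(6) if labels[j] == c])
                for c in set(labels) - {labels[i]}
            )
            expected.append((b - a) / max(a, b))
        assert s == pytest.approx(expected)

    def test_two_tight_distant_blobs(self):
        points, labels = two_blobs()
        assert mean_silhouette(points, labels) > 0.9

    def test_all_singletons_mean_zero(self):
        points = np.arange(10, dtype=float).reshape(5, 2)
        assert mean_silhouette(points, np.arange(5)) == 0.0

    def test_matches_sklearn_on_generic_labels(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(2)
        points = rng.normal(size=(40, 2))
        labels = rng.integers(0, 3, size=40)
        assert silhouette_values(points, labels) == pytest.approx(
            silhouette_samples(points, labels), abs=1e-10
        )

    def test_label_permutation_invariance(self):
        points, labels = two_blobs(seed=6)
        permuted = 1 - labels
        assert mean_silhouette(points, labels) == pytest.approx(
            mean_silhouette(points, permuted)
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            mean_silhouette(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestSelectClusterCount:
    def test_three_blobs_selects_three(self):
        rng = np.random.default_rng(8)
        points = np.vstack(
            [
                rng.normal([1.0, 1.0], 0.03, (15, 2)),
                rng.normal([2.0, 0.8], 0.03, (15, 2)),
                rng.normal([0.3, 0.2], 0.03, (15, 2)),
            ]
        )
        best_k, model, trace = select_cluster_count(points, range(2, 7), seed=0,
                                                    n_restarts=10)
        assert best_k == 3
        assert model.mean_silhouette == max(trace.values())

    def test_trace_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(9)
        points = np.vstack(
            [rng.normal([0, 0], 0.3, (6, 2)), rng.normal([3, 3], 0.3, (6, 2))]
        )
        _, _, trace = select_cluster_count(points, range(2, 5), seed=1,
                                           n_restarts=10)
        for k, sil in trace.items():
            model = fit_gmm(points, k, seed=1, n_restarts=10)
            assert sil == pytest.approx(mean_silhouette(points, model.labels))

    def test_empty_k_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_cluster_count(np.zeros((10, 2)), [], seed=0)


class TestConfidenceEllipses:
    def test_identity_covariance_gives_circle(self):
        e = ClusterEllipse(np.zeros(2), np.eye(2), mahalanobis_radius(0.95, 2), 0.95)
        boundary = np.array([[2.447, 0.0], [0.0, 2.447]])
        outside = np.array([[2.46, 0.0]])
        assert e.contains(boundary).all()
        assert not e.contains(outside).any()

    def test_axis_lengths_follow_eigenvalues(self):
        cov = np.diag([4.0, 1.0])
        radius = mahalanobis_radius(0.95, 2)
        e = ClusterEllipse(np.zeros(2), cov, radius, 0.95)
        # semi-axes radius*sqrt(eigenvalue): ratio 2:1
        assert e.contains(np.array([[2 * radius - 1e-6, 0.0]]))[0]
        assert not e.contains(np.array([[0.0, 2 * radius - 1e-6]]))[0]
        assert e.contains(np.array([[0.0, radius - 1e-6]]))[0]

    def test_one_ellipse_per_component(self):
        points, _ = two_blobs(seed=10)
        model = fit_gmm(points, 2, seed=0, n_restarts=5)
        ellipses = confidence_ellipses(model, 0.95)
        assert len(ellipses) == 2
        assert all(e.radius == pytest.approx(2.4477, abs=1e-3) for e in ellipses)

    def test_identical_ellipses_overlap_fully(self):
        e = ClusterEllipse(np.zeros(2), np.eye(2), 2.0, 0.95)
        assert ellipse_overlap(e, e) == pytest.approx(1.0)

    def test_grid_overlap_matches_monte_carlo(self):
        e1 = ClusterEllipse(np.zeros(2), np.eye(2), 2.0, 0.95)
        e2 = ClusterEllipse(np.array([1.5, 0.0]), np.diag([2.0, 0.5]), 2.0, 0.95)
        grid = ellipse_overlap(e1, e2, grid=500)
        rng = np.random.default_rng(0)
        lo, hi = np.array([-4.0, -4.0]), np.array([4.5, 4.0])
        pts = rng.uniform(lo, hi, size=(200_000, 2))
        in1, in2 = e1.contains(pts), e2.contains(pts)
        mc = (in1 & in2).sum() / min(in1.sum(), in2.sum())
        assert grid == pytest.approx(mc, abs=0.01)

    def test_disjoint_ellipses_overlap_zero(self):
        e1 = ClusterEllipse(np.zeros(2), np.eye(2) * 0.01, 1.0, 0.95)
        e2 = ClusterEllipse(np.array([5.0, 5.0]), np.eye(2) * 0.01, 1.0, 0.95)
        assert ellipse_overlap(e1, e2) == 0.0
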