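import itertools

import numpy as np
import pytest
from scipy import stats

from gammaplane.cohort import (
    CohortScatter,
    centroid_distances,
    cohort_report,
    fit_power_law,
    kmeans_cityblock,
    linear_fit,
    ranksum_test,
)
from gammaplane.datasets import reference_cohort_scatter


class TestPowerFit:
    def test_exact_power_law_recovered(self):
        x = np.linspace(0.5, 4, 12)
        fit = fit_power_law(np.column_stack([x, 2.0 * x**-1.0]))
        assert fit.coefficient == pytest.approx(2.0, abs=1e-8)
        assert fit.exponent == pytest.approx(-1.0, abs=1e-8)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_loglog_exact_data_zero_sse(self, rng):
        a, b = 3.7, -1.4
        x = rng.uniform(0.3, 5, 20)
        fit = fit_power_law(np.column_stack([x, a * x**b]))
        assert fit.coefficient == pytest.approx(a, abs=1e-8)
        assert fit.exponent == pytest.approx(b, abs=1e-8)
        assert fit.sse < 1e-12

    def test_reference_cohort_fit(self):
        sc = reference_cohort_scatter()
        fit = fit_power_law(sc.points)
        assert fit.coefficient == pytest.approx(6.362, abs=0.005)
        assert fit.exponent == pytest.approx(-1.908, abs=0.005)
        assert fit.sse == pytest.approx(20.44, abs=0.01)
        assert fit.r_squared == pytest.approx(0.8942, abs=0.0005)

    def test_rejects_nonpositive_and_tiny_inputs(self):
        with pytest.raises(ValueError):
            fit_power_law([[1.0, -1.0], [2.0, 1.0], [3.0, 1.0]])
        with pytest.raises(ValueError):
            fit_power_law([[1.0, 1.0], [2.0, 0.5]])


class TestKMeansCityblock:
    def test_separated_blobs_recovered(self, rng):
        blob1 = rng.normal([0, 0], 0.1, size=(5, 2))
        blob2 = rng.normal([10, 10], 0.1, size=(5, 2))
        res = kmeans_cityblock(np.vstack([blob1, blob2]), k=2, restarts=10, seed=0)
        assert len(set(res.assignments[:5])) == 1
        assert len(set(res.assignments[5:])) == 1
        assert res.assignments[0] != res.assignments[5]

    def test_cost_non_increasing_per_iteration(self, rng):
        X = rng.uniform(0, 10, size=(40, 2))
        res = kmeans_cityblock(X, k=2, restarts=5, seed=1)
        assert all(b <= a + 1e-12 for a, b in zip(res.cost_history, res.cost_history[1:]))

    def test_beats_random_assignments(self, rng):
        X = rng.uniform(0, 10, size=(15, 2))
        res = kmeans_cityblock(X, k=2, restarts=20, seed=2)
        for _ in range(1000):
            assign = rng.integers(0, 2, 15)
            if len(set(assign)) < 2:
                continue
            cen = np.array([np.median(X[assign == j], axis=0) for j in range(2)])
            cost = np.abs(X - cen[assign]).sum()
            assert res.cost <= cost + 1e-9

    def test_centroids_are_componentwise_medians(self, rng):
        X = rng.uniform(0, 10, size=(21, 2))
        res = kmeans_cityblock(X, k=2, restarts=10, seed=3)
        for j in range(2):
            np.testing.assert_allclose(
                res.centroids[j], np.median(X[res.assignments == j], axis=0)
            )

    def test_deterministic_given_seed(self, rng):
        X = rng.uniform(0, 5, size=(12, 2))
        r1 = kmeans_cityblock(X, seed=7)
        r2 = kmeans_cityblock(X, seed=7)
        np.testing.assert_array_equal(r1.assignments, r2.assignments)
        assert r1.cost == r2.cost

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_cityblock(np.ones((5, 2)), k=2)


class TestCentroidDistances:
    def test_zero_at_centroid(self):
        assert centroid_distances([[2.96, 0.78]], [2.96, 0.78])[0] == 0.0

    def test_l1_distance(self):
        assert centroid_distances([[1, 1]], [4, 5])[0] == pytest.approx(7.0)


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(1.0, 8.0)
        fit = linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        x = rng.uniform(0, 10, 25)
        y = 1.3 * x - 0.4 + rng.normal(0, 0.5, 25)
        fit = linear_fit(x, y)
        X = np.column_stack([x, np.ones(25)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_reference_nc_age_on_shape(self):
        sc = reference_cohort_scatter()
        nc = sc.subset("NC")
        fit = linear_fit(sc.points[nc, 0], sc.ages[nc])
        assert fit.slope == pytest.approx(14.2, abs=0.05)
        assert fit.intercept == pytest.approx(22.05, abs=0.05)

    def test_constant_x_singular(self):
        with pytest.raises(ValueError, match="singular"):
            linear_fit(np.ones(5), np.arange(5.0))


class TestRanksum:
    def test_identical_samples_p_one(self):
        stat, p = ranksum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_exact_matches_enumeration(self, rng):
        """p equals brute-force enumeration over all rank assignments."""
        for nx, ny in [(3, 3), (4, 5), (5, 5)]:
            x = rng.normal(0, 1, nx)
            y = rng.normal(1, 1, ny)
            _, p = ranksum_test(x, y)
            ranks = stats.rankdata(np.concatenate([x, y]))
            mu = ranks.sum() * nx / (nx + ny)
            d_obs = abs(ranks[:nx].sum() - mu)
            hits = total = 0
            for combo in itertools.combinations(range(nx + ny), nx):
                total += 1
                hits += abs(ranks[list(combo)].sum() - mu) >= d_obs - 1e-12
            assert p == pytest.approx(hits / total, abs=1e-12)

    def test_exact_matches_scipy_when_tie_free(self, rng):
        x, y = rng.normal(0, 1, 6), rng.normal(0.8, 1, 7)
        _, p = ranksum_test(x, y)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(expected, abs=1e-12)

    def test_reference_fano_groups_differ(self):
        sc = reference_cohort_scatter()
        _, p = ranksum_test(sc.fano[sc.subset("NC")], sc.fano[sc.subset("PD")])
        assert p < 0.01

    def test_large_samples_use_asymptotic(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(1.0, 1, 30)
        _, p = ranksum_test(x, y)
        assert 0 < p < 0.01


class TestCohortReport:
    def test_reference_cohort_medians(self):
        report = cohort_report(reference_cohort_scatter(), seed=0)
        assert report["max_shift"]["all"]["median"] == pytest.approx(27.7137)
        assert report["max_shift"]["NC"]["median"] == pytest.approx(9.8507)
        assert report["fano"]["NC"]["median"] == pytest.approx(0.78615)
        assert report["fano"]["PD"]["median"] == pytest.approx(6.0915)

    def test_medians_match_sort_oracle(self, rng):
        sc = reference_cohort_scatter()
        report = cohort_report(sc, seed=0)

        def sort_median(v):
            s = sorted(v)
            n = len(s)
            return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])

        assert report["fano"]["all"]["median"] == sort_median(sc.fano)
        assert report["max_shift"]["all"]["median"] == sort_median(sc.max_shifts)

    def test_synthetic_contrast_ordering(self, rng):
        # group B generated with larger scale: report medians must order as generated
        n = 8
        pts_a = np.column_stack([rng.uniform(2, 4, n), rng.uniform(0.5, 1.0, n)])
        pts_b = np.column_stack([rng.uniform(0.7, 1.2, n), rng.uniform(4, 12, n)])
        sc = CohortScatter(
            participant_ids=[f"x{i}" for i in range(2 * n)],
            points=np.vstack([pts_a, pts_b]),
            labels=["NC"] * n + ["PD"] * n,
            ages=rng.uniform(40, 80, 2 * n),
            max_shifts=np.concatenate([rng.uniform(5, 15, n), rng.uniform(20, 80, n)]),
        )
        report = cohort_report(sc, seed=0)
        assert report["fano"]["PD"]["median"] > report["fano"]["NC"]["median"]
        assert report["max_shift"]["PD"]["median"] > report["max_shift"]["NC"]["median"]

    def test_small_group_skips_with_warning(self, rng):
        sc = CohortScatter(
            participant_ids=["a", "b", "c", "d"],
            points=np.array([[1, 1], [2, 1.5], [3, 2], [1.5, 1.2]]),
            labels=["NC", "NC", "NC", "PD"],
            ages=np.array([50.0, 60, 70, 55]),
            max_shifts=np.array([5.0, 6, 7, 8]),
        )
        with pytest.warns(UserWarning):
            report = cohort_report(sc, seed=0)
        assert report["power_fit"]["PD"] is None
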