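import math

import numpy as np
import pytest
from scipy import special

from gammaplane.signatures import (
    chunk_entries,
    entry_signatures,
    fit_gamma_mle,
    gamma_pdf,
    optimal_bin_width,
)


class TestChunkEntries:
    def test_disjoint_blocks_and_trailing_discard(self, series_factory, rng):
        series = series_factory(rng.gamma(2, 1, 250))
        entries = chunk_entries(series, window=100)
        assert len(entries) == 2
        assert all(e.samples.size == 100 for e in entries)

    def test_exact_window_gives_one_entry(self, series_factory, rng):
        entries = chunk_entries(series_factory(rng.gamma(2, 1, 100)), window=100)
        assert len(entries) == 1

    def test_matches_bruteforce_slicing(self, series_factory, rng):
        values = rng.gamma(2, 1, 1000)
        entries = chunk_entries(series_factory(values), window=100)
        assert len(entries) == 10
        for i, e in enumerate(entries):
            np.testing.assert_array_equal(e.samples, values[i * 100 : (i + 1) * 100])
            assert e.entry_index == i + 1

    def test_short_series_warns_and_returns_empty(self, series_factory):
        with pytest.warns(UserWarning, match="shorter than window"):
            assert chunk_entries(series_factory(np.ones(5)), window=100) == []

    def test_window_below_two_rejected(self, series_factory):
        with pytest.raises(ValueError):
            chunk_entries(series_factory(np.ones(10)), window=1)


class TestBinWidth:
    def test_formula_unit_sd(self):
        # sd 1, N=1000: 3.49 / 10
        x = np.arange(1000, dtype=float)
        x = (x - x.mean()) / x.std(ddof=1)
        assert optimal_bin_width(x) == pytest.approx(0.349, abs=1e-12)

    def test_linear_in_sd(self):
        x = np.arange(1000, dtype=float)
        x = (x - x.mean()) / x.std(ddof=1)
        assert optimal_bin_width(2 * x) == pytest.approx(0.698, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        x = rng.gamma(2, 1, 100)
        expected = 3.49 * np.std(x, ddof=1) * 100 ** (-1 / 3)
        assert optimal_bin_width(x) == pytest.approx(expected, rel=1e-12)

    def test_constant_sample_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            optimal_bin_width(np.full(10, 3.3))


class TestGammaPdf:
    def test_exponential_special_case_at_zero_boundary(self):
        # a=1, b=1 is Exponential(1); density -> 1 as x -> 0+
        assert gamma_pdf(1e-12, 1, 1) == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_value(self):
        assert gamma_pdf(2.0, 1.0, 2.0) == pytest.approx(0.5 * math.exp(-1), rel=1e-12)

    def test_matches_explicit_formula(self, rng):
        a, b = 2.7, 0.9
        x = rng.gamma(a, b, 20)
        expected = x ** (a - 1) * np.exp(-x / b) / (b**a * special.gamma(a))
        np.testing.assert_allclose(gamma_pdf(x, a, b), expected, rtol=1e-12)

    def test_normalizes_to_one(self):
        from scipy.integrate import quad

        val, _ = quad(gamma_pdf, 0, np.inf, args=(0.7476, 13.4048))
        assert val == pytest.approx(1.0, abs=1e-6)


class TestGammaMLE:
    def test_recovers_reference_signature(self, rng):
        x = rng.gamma(2.1892, 1.6624, 10_000)
        est = fit_gamma_mle(x)
        assert 2.0 <= est.a <= 2.4
        assert 1.55 <= est.b <= 1.80

    def test_exponential_data_shape_one(self):
        # exponential data is Gamma with shape 1
        rng = np.random.default_rng(12345)
        est = fit_gamma_mle(rng.exponential(2.0, 10_000))
        assert est.a == pytest.approx(1.0, rel=0.05)
        assert est.ci_a[0] <= 1.0 <= est.ci_a[1]

    def test_matches_profile_likelihood_grid(self, rng):
        """1-D brute force: for Gamma, b-hat(a) = mean/a in closed form, so
        maximizing the profile log-likelihood over a grid of a to 3 decimals
        is an independent oracle for the MLE."""
        x = rng.gamma(2.0, 1.5, 50)
        grid = np.arange(0.2, 8.0, 0.001)
        b_prof = x.mean() / grid
        loglik = (
            (grid - 1) * np.log(x).sum()
            - x.sum() / b_prof
            - 50 * (grid * np.log(b_prof) + special.gammaln(grid))
        )
        a_grid = grid[np.argmax(loglik)]
        est = fit_gamma_mle(x)
        assert est.a == pytest.approx(a_grid, abs=1.5e-3)
        assert est.b == pytest.approx(x.mean() / est.a, rel=1e-6)

    def test_ci_coverage_near_nominal(self, rng):
        a0, b0 = 2.0, 1.5
        hits_a = hits_b = 0
        n_rep = 200
        for _ in range(n_rep):
            est = fit_gamma_mle(rng.gamma(a0, b0, 100))
            hits_a += est.ci_a[0] <= a0 <= est.ci_a[1]
            hits_b += est.ci_b[0] <= b0 <= est.ci_b[1]
        assert 0.90 * n_rep <= hits_a <= 0.99 * n_rep
        assert 0.90 * n_rep <= hits_b <= 0.99 * n_rep

    def test_scale_equivariance(self, rng):
        x = rng.gamma(2.0, 3.0, 500)
        e1, e2 = fit_gamma_mle(x), fit_gamma_mle(10.0 * x)
        assert e2.a == pytest.approx(e1.a, abs=1e-6)
        assert e2.b == pytest.approx(10.0 * e1.b, rel=1e-6)

    def test_fano_identity_variance_over_mean_is_scale(self, rng):
        est = fit_gamma_mle(rng.gamma(1.3, 4.0, 100))
        assert est.variance / est.mean == pytest.approx(est.b, rel=1e-14)

    @pytest.mark.parametrize("bad", [np.zeros(20), -np.ones(20), np.ones(5)])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            fit_gamma_mle(bad)


class TestEntrySignatures:
    def _entries(self, series_factory, values, window=100):
        return chunk_entries(series_factory(values), window=window)

    def test_clean_entries_all_survive(self, series_factory, rng):
        entries = self._entries(series_factory, rng.gamma(2, 1, 1000))
        estimates, discarded = entry_signatures(entries, seed=1)
        assert len(estimates) == 10
        assert discarded == 0

    def test_contaminated_entries_discarded(self, series_factory, rng):
        values = rng.gamma(2, 1, 1000)
        for block in (2, 7):  # far second mode in two entries
            sl = slice(block * 100, block * 100 + 50)
            values[sl] = 1000.0 + rng.normal(0, 1, 50)
        estimates, discarded = entry_signatures(
            self._entries(series_factory, values), seed=1
        )
        assert discarded == 2
        assert len(estimates) == 8

    def test_all_contaminated_warns_empty(self, series_factory, rng):
        values = np.concatenate(
            [np.concatenate([rng.normal(5, 0.1, 50), rng.normal(5000, 0.1, 50)])
             for _ in range(3)]
        )
        with pytest.warns(UserWarning, match="excluded"):
            estimates, discarded = entry_signatures(
                self._entries(series_factory, values), seed=1
            )
        assert estimates == [] and discarded == 3

    def test_length_plus_discarded_equals_input(self, series_factory, rng):
        values = rng.gamma(2, 1, 700)
        values[250:300] = 800.0 + rng.normal(0, 0.5, 50)
        entries = self._entries(series_factory, values)
        estimates, discarded = entry_signatures(entries, seed=1)
        assert len(estimates) + discarded == len(entries)

    def test_acquisition_order_preserved(self, series_factory, rng):
        # drifting scale: fitted b should trend with the generative order
        values = np.concatenate([rng.gamma(2.0, b, 100) for b in (1, 2, 4, 8)])
        estimates, _ = entry_signatures(self._entries(series_factory, values), seed=1)
        assert len(estimates) == 4
        assert np.all(np.diff([e.b for e in estimates]) > 0)
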