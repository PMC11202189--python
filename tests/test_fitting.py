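"""Levenberg-Marquardt fitter: recovery, uncertainties, invariances, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from relkin import (
    KineticParams,
    ReleaseSeries,
    brute_force_fit,
    fit_release,
    goodness_of_fit,
    initial_guess,
    mass_released,
)
from relkin.fitting import InsufficientDataError, NoSignalError, fit_report

from conftest import HIGH_TRIPLE, LOW_TRIPLE, noiseless_series


def noisy_series(p, noise_frac, seed, n=50, t_max=2000.0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n)
    m = np.clip(mass_released(t, p) + rng.normal(0, noise_frac * p.m_inf, n), 0.0, None)
    return ReleaseSeries(t, m)


class TestReleaseSeries:
    def test_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ReleaseSeries(np.array([0.0, 1.0, 1.0]), np.zeros(3))
        with pytest.raises(ValueError, match="equal length"):
            ReleaseSeries(np.array([0.0, 1.0]), np.zeros(3))
        with pytest.raises(ValueError, match=">= 0"):
            ReleaseSeries(np.array([0.0, 1.0]), np.array([0.0, -1.0]))

    def test_time_rescaling(self):
        s = noiseless_series(LOW_TRIPLE)
        s_days = s.with_times_scaled(1 / 24.0)
        assert s_days.times[-1] == pytest.approx(2000.0 / 24.0)


class TestInitialGuess:
    def test_noiseless_guess_close_to_truth(self, low_series):
        g = initial_guess(low_series)
        assert g.m_inf == pytest.approx(LOW_TRIPLE.m_inf, rel=0.15)
        assert g.tau0 == pytest.approx(LOW_TRIPLE.tau0, rel=0.15)
        assert g.sigma == pytest.approx(LOW_TRIPLE.sigma, rel=0.15)

    def test_fallback_with_two_usable_points(self):
        s = ReleaseSeries(np.array([0.0, 10.0, 20.0]), np.array([0.0, 1.0, 1.1]))
        g = initial_guess(s)
        assert g.sigma == 1.0

    def test_all_zero_masses_rejected(self):
        s = ReleaseSeries(np.linspace(0, 10, 6), np.zeros(6))
        with pytest.raises(NoSignalError):
            initial_guess(s)

    def test_decreasing_masses_still_return_a_guess(self):
        s = ReleaseSeries(np.linspace(1, 10, 6), np.linspace(5, 1, 6))
        g = initial_guess(s)
        assert g.m_inf > 0


class TestNoiselessRecovery:
    def test_study_triples_recovered_to_machine_precision(self, study_triple):
        series = noiseless_series(study_triple)
        result = fit_release(series)
        assert result.converged
        rel = np.abs(result.params.as_array() / study_triple.as_array() - 1.0)
        assert np.all(rel <= 1e-6)
        assert result.r_squared == pytest.approx(1.0, abs=1e-12)
        assert result.rmse == pytest.approx(0.0, abs=1e-9 * study_triple.m_inf)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        m=st.floats(0.5, 300.0),
        tau0=st.floats(50.0, 900.0),
        sigma=st.floats(0.6, 10.0),
    )
    def test_recovery_for_random_triples_with_adequate_coverage(self, m, tau0, sigma):
        p = KineticParams(m, tau0, sigma)
        from relkin import half_release_time

        t_max = max(2.5 * half_release_time(p), 10.0)
        series = noiseless_series(p, n=60, t_max=t_max)
        result = fit_release(series)
        assert result.converged
        rel = np.abs(result.params.as_array() / p.as_array() - 1.0)
        assert np.all(rel <= 1e-6)

    def test_sigma_fixed_reduces_to_exponential_fit(self):
        p = KineticParams(5.0, 300.0, 1.0)
        series = noiseless_series(p, n=40, t_max=1500.0)
        result = fit_release(series, sigma_fixed=1.0)
        assert result.converged
        assert result.params.sigma == 1.0
        assert result.params.m_inf == pytest.approx(5.0, rel=1e-8)
        assert result.params.tau0 == pytest.approx(300.0, rel=1e-8)
        # frozen parameter carries no uncertainty
        assert result.stderr[2] == 0.0


class TestAgainstIndependentOptimizer:
    def test_matches_scipy_trf_on_noisy_data(self):
        series = noisy_series(LOW_TRIPLE, 0.02, seed=11)
        ours = fit_release(series)

        def resid(q):
            return series.masses - mass_released(series.times, KineticParams(*np.exp(q)))

        ref = least_squares(
            resid, np.log(initial_guess(series).as_array()), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        ref_params = np.exp(ref.x)
        ref_ssr = float(resid(ref.x) @ resid(ref.x))
        assert ours.params.as_array() == pytest.approx(ref_params, rel=1e-6)
        assert ours.ssr <= ref_ssr * (1.0 + 1e-9)


class TestUncertainties:
    def test_noisy_truth_within_three_stderr(self):
        series = noisy_series(LOW_TRIPLE, 0.02, seed=3)
        result = fit_release(series)
        assert result.converged
        err = np.abs(result.params.as_array() - LOW_TRIPLE.as_array())
        assert np.all(err <= 3.0 * np.array(result.stderr))

    def test_covariance_symmetric_psd_and_stderr_diagonal(self):
        series = noisy_series(LOW_TRIPLE, 0.02, seed=5)
        result = fit_release(series)
        cov = result.covariance
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12 * np.abs(cov).max())
        assert np.array(result.stderr) == pytest.approx(np.sqrt(np.diag(cov)))

    def test_two_sigma_coverage_over_replicates(self):
        """~95% of noisy replicates should bracket the truth at +-2 stderr."""
        hits = np.zeros(3)
        n_rep = 200
        for seed in range(n_rep):
            series = noisy_series(LOW_TRIPLE, 0.02, seed=seed)
            result = fit_release(series)
            if not result.converged:
                continue
            hits += (
                np.abs(result.params.as_array() - LOW_TRIPLE.as_array())
                <= 2.0 * np.array(result.stderr)
            )
        coverage = hits / n_rep
        assert np.all(coverage >= 0.90) and np.all(coverage <= 0.99)


class TestGoodnessOfFit:
    def test_perfect_and_degenerate(self, low_series):
        r2, rmse = goodness_of_fit(low_series, LOW_TRIPLE)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert rmse == pytest.approx(0.0, abs=1e-12)
        constant = ReleaseSeries(np.linspace(0, 10, 6), np.full(6, 2.0))
        r2_const, _ = goodness_of_fit(constant, KineticParams(2.0, 1.0, 1.0))
        assert np.isnan(r2_const)

    def test_normalized_rmse_tracks_noise_level(self):
        series = noisy_series(LOW_TRIPLE, 0.02, seed=9)
        result = fit_release(series)
        assert result.rmse_normalized == pytest.approx(0.02, abs=0.01)


class TestBruteForceOracle:
    def test_grid_containing_truth_is_found_noiseless(self, low_series):
        bf = brute_force_fit(
            low_series, [2.0, 3.0, 4.0], [700.0, 808.0, 900.0], [1.0, 1.37, 2.0]
        )
        assert bf == KineticParams(3.0, 808.0, 1.37)

    def test_lm_refines_grid_optimum(self):
        series = noisy_series(LOW_TRIPLE, 0.02, seed=21, n=30)
        lm = fit_release(series)
        m_grid = np.linspace(2.4, 3.6, 11)
        t_grid = np.linspace(650.0, 970.0, 11)
        s_grid = np.linspace(1.0, 1.8, 11)
        bf = brute_force_fit(series, m_grid, t_grid, s_grid)
        ssr_bf = goodness_of_fit(series, bf)[1] ** 2 * len(series)
        assert lm.ssr <= ssr_bf + 1e-12
        assert abs(bf.m_inf - lm.params.m_inf) <= m_grid[1] - m_grid[0]
        assert abs(bf.tau0 - lm.params.tau0) <= t_grid[1] - t_grid[0]
        assert abs(bf.sigma - lm.params.sigma) <= s_grid[1] - s_grid[0]

    def test_empty_grid_rejected(self, low_series):
        with pytest.raises(ValueError, match="empty"):
            brute_force_fit(low_series, [], [800.0], [1.0])


class TestInvariances:
    def test_time_unit_rescaling(self):
        """Fitting in days must rescale tau0 by 24 and leave sigma, m_inf, R^2 alone."""
        series_h = noisy_series(LOW_TRIPLE, 0.01, seed=13)
        series_d = series_h.with_times_scaled(1 / 24.0)
        fit_h = fit_release(series_h)
        fit_d = fit_release(series_d)
        assert fit_d.params.tau0 == pytest.approx(fit_h.params.tau0 / 24.0, rel=1e-6)
        assert fit_d.params.sigma == pytest.approx(fit_h.params.sigma, rel=1e-6)
        assert fit_d.params.m_inf == pytest.approx(fit_h.params.m_inf, rel=1e-6)
        assert fit_d.r_squared == pytest.approx(fit_h.r_squared, abs=1e-9)


class TestContracts:
    def test_too_few_points(self):
        s = ReleaseSeries(np.linspace(0, 10, 3), np.array([0.0, 1.0, 2.0]))
        with pytest.raises(InsufficientDataError):
            fit_release(s)

    def test_report_renders(self, low_series):
        text = fit_report(fit_release(low_series))
        for token in ("m_inf", "tau0", "sigma", "R^2", "converged", "covariance"):
            assert token in text
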