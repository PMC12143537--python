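import numpy as np
import pytest
from scipy.stats import multivariate_normal

from ecostates import (
    DfaConfig,
    aicc,
    fit_dfa,
    kalman_loglik,
    loading_intervals,
    rotate_and_align,
    select_dfa,
    standardize,
    make_dataset,
)
from ecostates.dfa import DfaError, DfaParams, n_free_params
from tests.conftest import random_walk_config


def stacked_gaussian_loglik(y, params):
    """Independent oracle: log-density of the stacked observed vector under
    the jointly Gaussian law implied by the random-walk factor model."""
    T, n = y.shape
    Z = params.Z
    m = Z.shape[1]
    Sx = np.empty((T * m, T * m))
    for s in range(T):
        for t in range(T):
            Sx[s * m:(s + 1) * m, t * m:(t + 1) * m] = (
                params.x0_var + min(s, t)
            ) * np.eye(m)
    H = np.kron(np.eye(T), Z)
    Sy = H @ Sx @ H.T + np.kron(np.eye(T), params.R)
    mu = np.tile(Z @ params.x0_mean, T)
    obs = np.isfinite(y.ravel())
    return multivariate_normal.logpdf(
        y.ravel()[obs], mean=mu[obs], cov=Sy[np.ix_(obs, obs)]
    )


def random_instance(rng, T, n, m, missing=0.2):
    Z = rng.uniform(-1, 1, size=(n, m))
    A = rng.uniform(-0.5, 0.5, size=(n, n))
    R = A @ A.T + np.eye(n) * rng.uniform(0.2, 1.0)
    params = DfaParams(Z=Z, R=R, x0_mean=rng.normal(size=m), x0_var=rng.uniform(0.5, 5))
    y = rng.normal(size=(T, n))
    if missing:
        y[rng.random((T, n)) < missing] = np.nan
        for j in range(n):  # keep the instance non-degenerate
            if not np.isfinite(y[:, j]).any():
                y[0, j] = rng.normal()
    return y, params


class TestKalmanLoglik:
    def test_single_step_closed_form(self):
        params = DfaParams(Z=np.array([[1.0]]), R=np.array([[1.0]]),
                           x0_mean=np.zeros(1), x0_var=1.0)
        y = np.array([[0.0]])
        assert kalman_loglik(params, y) == pytest.approx(-0.5 * np.log(4 * np.pi))

    @pytest.mark.parametrize("T,n,m", [(4, 2, 1), (6, 3, 2), (8, 3, 1), (5, 2, 2)])
    def test_matches_stacked_gaussian_oracle(self, T, n, m):
        rng = np.random.default_rng(1000 + 10 * T + n + m)
        for _ in range(4):
            y, params = random_instance(rng, T, n, m)
            assert kalman_loglik(params, y) == pytest.approx(
                stacked_gaussian_loglik(y, params), abs=1e-6
            )

    def test_fully_missing_timestep_drops_its_term(self, rng):
        y, params = random_instance(rng, 6, 2, 1, missing=0.0)
        y2 = y.copy()
        y2[3] = np.nan
        assert kalman_loglik(params, y2) == pytest.approx(
            stacked_gaussian_loglik(y2, params), abs=1e-6
        )

    def test_dimension_mismatch_rejected(self, rng):
        y, params = random_instance(rng, 5, 3, 1)
        with pytest.raises(ValueError, match="dimensions"):
            kalman_loglik(params, y[:, :2])

    def test_non_psd_innovation_rejected(self):
        params = DfaParams(Z=np.array([[1.0]]), R=np.array([[-2.0]]),
                           x0_mean=np.zeros(1), x0_var=1.0)
        with pytest.raises(DfaError, match="positive definite"):
            kalman_loglik(params, np.array([[0.0]]))


class TestAicc:
    def test_closed_form_values(self):
        assert aicc(0.0, 1, 10) == pytest.approx(2.5)
        assert aicc(-100.0, 5, 38) == pytest.approx(211.875)

    def test_zero_params_identity(self):
        assert aicc(-7.25, 0, 20) == pytest.approx(14.5)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(0.0, 9, 10)


class TestFitDfa:
    def test_em_loglik_monotone(self, small_fit):
        diffs = np.diff(small_fit.loglik_path)
        assert diffs.min() >= -1e-7

    def test_noiseless_limit_recovers_series(self, rng):
        y = np.cumsum(rng.normal(size=60))
        y = (y - y.mean()) / y.std(ddof=1)
        cfg = DfaConfig(n_trends=1, fixed_R=np.array([[1e-6]]), seed=0)
        from ecostates import IndicatorPanel, IndicatorSeries

        years = np.arange(1960, 2020)
        panel = IndicatorPanel(years, [IndicatorSeries("s", years, y)])
        fit = fit_dfa(panel, cfg)
        recon = fit.params.Z[0, 0] * fit.trends[0]
        assert np.abs(recon - y).max() < 0.01

    def test_single_seed_parameter_recovery(self):
        ds = make_dataset(random_walk_config(seed=77))
        fit = fit_dfa(ds.panel, DfaConfig(n_trends=1, r_structure="diagonal_equal", seed=0))
        assert fit.converged
        c = np.corrcoef(fit.trends[0], ds.true_trends[0])[0, 1]
        s = np.sign(c)
        assert abs(c) >= 0.95
        assert np.mean(np.abs(s * fit.params.Z[:, 0] - ds.true_Z[:, 0])) <= 0.15

    def test_more_trends_than_series_rejected(self, default_dataset):
        std = standardize(default_dataset.panel)
        small = std.window(std.years[0], std.years[-1])
        small.series = small.series[:1]
        with pytest.raises(DfaError, match="at least 2 series"):
            fit_dfa(small, DfaConfig(n_trends=2))

    def test_aicc_consistent_with_loglik_and_k(self, small_fit):
        n_obs = small_fit.panel.n_observed
        assert small_fit.aicc == pytest.approx(
            aicc(small_fit.loglik, small_fit.n_params, n_obs)
        )

    @pytest.mark.parametrize(
        "structure", ["diagonal_equal", "diagonal_unequal", "equalvarcov", "unconstrained"]
    )
    def test_estimated_R_satisfies_declared_structure(self, structure, default_dataset):
        std = standardize(default_dataset.panel)
        fit = fit_dfa(std, DfaConfig(
            n_trends=1, r_structure=structure, seed=1, max_iterations=200
        ))
        R = fit.params.R
        off = R[~np.eye(R.shape[0], dtype=bool)]
        diag = np.diag(R)
        if structure == "diagonal_equal":
            assert np.all(off == 0.0) and np.all(diag == diag[0])
        elif structure == "diagonal_unequal":
            assert np.all(off == 0.0)
        elif structure == "equalvarcov":
            assert np.all(diag == diag[0]) and np.all(off == off[0])
        else:
            np.testing.assert_array_equal(R, R.T)

    def test_identifiability_zeros_in_unrotated_loadings(self, default_dataset):
        std = standardize(default_dataset.panel)
        fit = fit_dfa(std, DfaConfig(
            n_trends=2, r_structure="diagonal_equal", seed=2, max_iterations=300
        ))
        assert fit.params.Z[0, 1] == 0.0


class TestSelection:
    def test_single_candidate_returned(self, default_dataset):
        std = standardize(default_dataset.panel)
        fit = select_dfa(std, trend_candidates=(1,), r_candidates=("diagonal_equal",),
                         seed=0, max_iterations=400)
        assert fit.n_trends == 1
        assert len(fit.candidates) == 1

    def test_fewer_params_win_at_equal_loglik(self):
        # AICc is monotone in k at fixed loglik and n
        assert aicc(-50.0, 3, 100) < aicc(-50.0, 5, 100)

    def test_candidate_table_has_delta(self, default_dataset):
        std = standardize(default_dataset.panel)
        fit = select_dfa(std, trend_candidates=(1,),
                         r_candidates=("diagonal_equal", "diagonal_unequal"),
                         seed=0, max_iterations=400)
        tab = fit.candidates
        assert tab["delta_aicc"].min() == pytest.approx(0.0)
        assert len(tab) == 2


class TestRotation:
    def test_one_trend_rotation_is_sign_alignment_only(self, small_fit):
        rot = rotate_and_align(small_fit)
        assert rot.params.Z[:, 0].sum() >= 0
        assert np.abs(np.abs(rot.params.Z) - np.abs(small_fit.params.Z)).max() < 1e-12

    def test_likelihood_and_fitted_values_invariant(self, default_dataset):
        std = standardize(default_dataset.panel)
        fit = fit_dfa(std, DfaConfig(
            n_trends=2, r_structure="diagonal_equal", seed=4, max_iterations=500
        ))
        rot = rotate_and_align(fit)
        assert kalman_loglik(rot.params, std) == pytest.approx(fit.loglik, abs=1e-8)
        np.testing.assert_allclose(
            rot.fitted_values(), fit.fitted_values(), atol=1e-8
        )

    def test_idempotent(self, default_dataset):
        std = standardize(default_dataset.panel)
        fit = fit_dfa(std, DfaConfig(
            n_trends=2, r_structure="diagonal_equal", seed=4, max_iterations=500
        ))
        rot = rotate_and_align(fit)
        rot2 = rotate_and_align(rot)
        np.testing.assert_allclose(rot2.params.Z, rot.params.Z, atol=1e-8)
        np.testing.assert_allclose(rot2.trends, rot.trends, atol=1e-8)


class TestLoadingIntervals:
    def test_wald_arithmetic_and_significance(self, small_fit):
        ests = loading_intervals(rotate_and_align(small_fit))
        for e in ests:
            if not e.degenerate:
                assert e.ci_low <= e.estimate <= e.ci_high
                assert e.ci_low == pytest.approx(e.estimate - 1.959964 * e.se, rel=1e-4)
                assert e.significant == (e.ci_low > 0 or e.ci_high < 0)

    def test_strong_loadings_are_significant(self, small_fit):
        """The default scenario has |loading| >= 0.3 against noise sd 0.5:
        most loadings should exclude zero at 95%."""
        ests = loading_intervals(rotate_and_align(small_fit))
        assert np.mean([e.significant for e in ests]) > 0.6

    def test_nominal_coverage_of_wald_intervals(self):
        """Pooled across replicates and loadings, 95% Wald intervals cover
        the true loadings at a near-nominal rate (40-year, 8-series panels
        simulated from the exact factor model)."""
        covered = total = 0
        for rep in range(60):
            ds = make_dataset(random_walk_config(seed=500 + rep, T=40, n=8))
            fit = fit_dfa(ds.panel, DfaConfig(
                n_trends=1, r_structure="diagonal_equal", seed=1,
                max_iterations=20000,
            ))
            fit = rotate_and_align(fit)
            s = np.sign(np.corrcoef(fit.trends[0], ds.true_trends[0])[0, 1])
            for e, zt in zip(loading_intervals(fit), ds.true_Z[:, 0]):
                if not e.degenerate:
                    covered += e.ci_low <= s * zt <= e.ci_high
                    total += 1
        assert total > 400
        assert 0.88 <= covered / total <= 0.99
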