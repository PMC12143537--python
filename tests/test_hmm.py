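import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy import stats

from ecostates import (
    HmmConfig,
    baum_welch,
    forward_loglik,
    select_hmm,
    to_segments,
    viterbi,
)
from ecostates.hmm import HmmError, HmmFit


def make_fit(means, variances, transition, initial):
    means = np.asarray(means, float)
    return HmmFit(
        K=len(means), state_means=means, state_vars=np.asarray(variances, float),
        transition=np.asarray(transition, float), initial=np.asarray(initial, float),
        loglik=np.nan, n_params=0, aicc=np.nan,
        decoded_path=np.empty(0, dtype=int), converged=True, iterations=0,
    )


def enumerate_paths_loglik(x, fit):
    """Brute-force marginal log-likelihood: logsumexp over all K^T paths."""
    T, K = len(x), fit.K
    logB = stats.norm.logpdf(x[:, None], fit.state_means, np.sqrt(fit.state_vars))
    with np.errstate(divide="ignore"):
        logA = np.log(fit.transition)
        logpi = np.log(fit.initial)
    terms = []
    for path in itertools.product(range(K), repeat=T):
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        terms.append(lp)
    return logsumexp(terms)


def enumerate_paths_best(x, fit):
    """Brute-force Viterbi: the maximal joint log-probability."""
    T, K = len(x), fit.K
    logB = stats.norm.logpdf(x[:, None], fit.state_means, np.sqrt(fit.state_vars))
    with np.errstate(divide="ignore"):
        logA = np.log(fit.transition)
        logpi = np.log(fit.initial)
    best = -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        best = max(best, lp)
    return best


def random_fit(rng, K):
    A = rng.dirichlet(np.ones(K) * 2, size=K)
    return make_fit(
        means=np.sort(rng.normal(0, 2, K)),
        variances=rng.uniform(0.2, 2.0, K),
        transition=A,
        initial=rng.dirichlet(np.ones(K)),
    )


def path_logprob(x, fit, path0):
    logB = stats.norm.logpdf(x[:, None], fit.state_means, np.sqrt(fit.state_vars))
    with np.errstate(divide="ignore"):
        logA = np.log(fit.transition)
        logpi = np.log(fit.initial)
    lp = logpi[path0[0]] + logB[0, path0[0]]
    for t in range(1, len(x)):
        lp += logA[path0[t - 1], path0[t]] + logB[t, path0[t]]
    return lp


class TestForwardOracle:
    @pytest.mark.parametrize("K,T", [(2, 6), (2, 10), (3, 6), (3, 8)])
    def test_forward_matches_path_enumeration(self, K, T):
        rng = np.random.default_rng(100 * K + T)
        for _ in range(5):
            fit = random_fit(rng, K)
            x = rng.normal(0, 2, T)
            assert forward_loglik(x, fit) == pytest.approx(
                enumerate_paths_loglik(x, fit), abs=1e-8
            )

    def test_single_state_reduces_to_gaussian_density(self, rng):
        fit = make_fit([0.5], [2.0], [[1.0]], [1.0])
        x = rng.normal(size=25)
        expected = stats.norm.logpdf(x, 0.5, np.sqrt(2.0)).sum()
        assert forward_loglik(x, fit) == pytest.approx(expected, abs=1e-10)

    def test_label_permutation_invariance(self, rng):
        fit = random_fit(rng, 3)
        x = rng.normal(size=30)
        perm = [2, 0, 1]
        fit_p = make_fit(
            fit.state_means[perm], fit.state_vars[perm],
            fit.transition[np.ix_(perm, perm)], fit.initial[perm],
        )
        assert forward_loglik(x, fit) == pytest.approx(
            forward_loglik(x, fit_p), abs=1e-10
        )


class TestViterbiOracle:
    @pytest.mark.parametrize("K,T", [(2, 8), (3, 7)])
    def test_viterbi_attains_enumerated_maximum(self, K, T):
        rng = np.random.default_rng(17 * K + T)
        for _ in range(5):
            fit = random_fit(rng, K)
            x = rng.normal(0, 2, T)
            path = viterbi(x, fit) - 1
            assert path_logprob(x, fit, path) == pytest.approx(
                enumerate_paths_best(x, fit), abs=1e-10
            )

    def test_tie_broken_toward_lower_label(self):
        # identical emissions in both states; sticky symmetric transitions
        fit = make_fit([0.0, 0.0], [1.0, 1.0], [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5])
        path = viterbi(np.zeros(10), fit)
        np.testing.assert_array_equal(path, np.ones(10, dtype=int))

    def test_separated_blocks_decoded_exactly(self, rng):
        x = np.r_[rng.normal(-2, 0.1, 25), rng.normal(2, 0.1, 25)]
        fit = make_fit([-2.0, 2.0], [0.01, 0.01], [[0.95, 0.05], [0.05, 0.95]], [0.5, 0.5])
        path = viterbi(x, fit)
        np.testing.assert_array_equal(path, np.r_[np.ones(25), 2 * np.ones(25)])


class TestBaumWelch:
    def test_two_block_series_recovered(self, rng):
        x = np.r_[rng.normal(-2, 0.1, 25), rng.normal(2, 0.1, 25)]
        fit = baum_welch(x, K=2, config=HmmConfig(seed=0))
        np.testing.assert_array_equal(
            fit.decoded_path, np.r_[np.ones(25), 2 * np.ones(25)]
        )
        assert fit.persistence.min() >= 0.9
        assert fit.state_means[0] < fit.state_means[1]

    def test_constant_series_degenerates(self):
        with pytest.raises(HmmError, match="degenerate"):
            baum_welch(np.ones(30), K=2, config=HmmConfig(seed=0, n_restarts=5))

    def test_fit_dominates_every_restart(self, rng):
        """The returned fit's loglik is the argmax over restart finals."""
        from ecostates.hmm import _em_single

        x = np.r_[rng.normal(-1, 0.5, 20), rng.normal(1, 0.5, 20)]
        cfg = HmmConfig(seed=3, n_restarts=8)
        fit = baum_welch(x, K=2, config=cfg)
        ss = np.random.SeedSequence([cfg.seed, 2])
        finals = []
        for s in ss.spawn(cfg.n_restarts):
            res = _em_single(x, 2, cfg, np.random.default_rng(s))
            if res is not None:
                finals.append(res[4])
        assert fit.loglik == pytest.approx(max(finals), abs=1e-9)

    def test_rows_stochastic_and_labels_ascending(self, rng):
        x = rng.normal(size=60) + np.repeat([0, 3.0], 30)
        fit = baum_welch(x, K=3, config=HmmConfig(seed=1, n_restarts=10))
        np.testing.assert_allclose(fit.transition.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(fit.state_means) >= 0)
        assert set(fit.decoded_path) <= {1, 2, 3}
        np.testing.assert_allclose(fit.persistence, np.diag(fit.transition))

    def test_loglik_matches_hmmlearn(self, rng):
        """Independent cross-check of the forward likelihood on a fitted model."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        x = np.r_[rng.normal(-1, 0.6, 30), rng.normal(1, 0.6, 30)]
        fit = baum_welch(x, K=2, config=HmmConfig(seed=2))
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        ref.startprob_ = fit.initial
        ref.transmat_ = fit.transition
        ref.means_ = fit.state_means[:, None]
        ref.covars_ = fit.state_vars[:, None]
        assert ref.score(x[:, None]) == pytest.approx(fit.loglik, abs=1e-6)


class TestSelection:
    def test_single_candidate_returned_unconditionally(self, rng):
        x = np.r_[rng.normal(-1, 0.5, 20), rng.normal(1, 0.5, 20)]
        fit = select_hmm(x, HmmConfig(state_candidates=(2,), seed=0, n_restarts=5))
        assert fit.K == 2
        assert len(fit.candidates) == 1

    def test_aicc_parameter_count(self, rng):
        x = np.r_[rng.normal(-2, 0.5, 25), rng.normal(2, 0.5, 25)]
        fit = baum_welch(x, K=2, config=HmmConfig(seed=0, n_restarts=5))
        assert fit.n_params == 2 * 1 + 2 * 2 + 1  # transitions + means/vars + initial
        from ecostates import aicc

        assert fit.aicc == pytest.approx(aicc(fit.loglik, fit.n_params, len(x)))

    def test_too_short_series_fails_with_table(self, rng):
        x = rng.normal(size=5)
        with pytest.raises(HmmError, match="candidate table"):
            select_hmm(x, HmmConfig(seed=0, n_restarts=3))


class TestSegments:
    def test_run_length_encoding(self):
        segs = to_segments([1, 1, 2, 2], [2000, 2001, 2002, 2003], [0.9, 0.8])
        assert segs.segments == [(2000, 2001, 1), (2002, 2003, 2)]
        df = segs.to_frame()
        assert df.loc[0, "persistence"] == pytest.approx(0.9)
        assert df.loc[1, "persistence"] == pytest.approx(0.8)

    def test_constant_path_single_segment(self):
        segs = to_segments([1] * 5, range(1990, 1995))
        assert segs.segments == [(1990, 1994, 1)]

    def test_alternating_path(self):
        segs = to_segments([1, 2, 1, 2], [2000, 2001, 2002, 2003])
        assert len(segs.segments) == 4
        assert all(s == e for s, e, _ in segs.segments)
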