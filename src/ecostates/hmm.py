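"""Gaussian hidden Markov models for ecosystem-state detection on DFA trends.

Each smoothed latent trend is treated as a univariate annual series whose
years belong to one of K in {2, 3} discrete ecosystem states; each state k
emits Normal(mean_k, var_k) values and states evolve by a row-stochastic
transition matrix.  Estimation is Baum-Welch EM with multiple seeded
restarts; the state count is chosen by AICc; the most probable state path
(Viterbi) is reported as year-range segments, and the transition-matrix
diagonal gives each state's persistence (the probability of staying in the
same state next year).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HmmConfig",
    "HmmFit",
    "StateSegments",
    "baum_welch",
    "forward_loglik",
    "viterbi",
    "select_hmm",
    "to_segments",
    "HmmError",
]

_VAR_FLOOR = 1e-8


class HmmError(RuntimeError):
    pass


@dataclass(frozen=True)
class HmmConfig:
    """Settings for HMM estimation on one trend.

    ``initial_mode``: "free" estimates the initial state distribution as
    K-1 free parameters (counted in AICc); "stationary" ties it to the
    stationary distribution of the transition matrix.
    """

    state_candidates: tuple = (2, 3)
    n_restarts: int = 20
    max_iterations: int = 500
    loglik_tolerance: float = 1e-6
    seed: int = 0
    initial_mode: str = "free"

    def __post_init__(self):
        if not self.state_candidates or any(k not in (2, 3) for k in self.state_candidates):
            raise ValueError("state_candidates must be a non-empty subset of {2, 3}")
        if self.initial_mode not in ("free", "stationary"):
            raise ValueError("initial_mode must be 'free' or 'stationary'")


@dataclass
class HmmFit:
    """Fitted Gaussian HMM with states labelled in ascending order of mean."""

    K: int
    state_means: np.ndarray
    state_vars: np.ndarray
    transition: np.ndarray
    initial: np.ndarray
    loglik: float
    n_params: int
    aicc: float
    decoded_path: np.ndarray  # 1-based state labels per year
    converged: bool
    iterations: int
    candidates: pd.DataFrame | None = None

    @property
    def persistence(self) -> np.ndarray:
        """Per-state probability of remaining in the same state next year."""
        return np.diag(self.transition).copy()


@dataclass
class StateSegments:
    """Run-length encoding of a decoded path into (start_year, end_year, state)."""

    segments: list  # of (start_year, end_year, state)
    persistence: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for start, end, state in self.segments:
            pers = (
                float(self.persistence[state - 1])
                if len(self.persistence) >= state
                else np.nan
            )
            rows.append(dict(start_year=start, end_year=end, state=state, persistence=pers))
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _emission_logprobs(x, means, variances):
    sd = np.sqrt(variances)
    return stats.norm.logpdf(x[:, None], loc=means[None, :], scale=sd[None, :])


def _forward_backward(logB, transition, initial):
    """Scaled forward-backward. Returns loglik, gamma (T x K), xi sums (K x K)."""
    T, K = logB.shape
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = initial * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transition) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (transition @ bb) / c[t + 1]
        xi += np.outer(alpha[t], bb / c[t + 1]) * transition
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + logB.max(axis=1).sum())
    return loglik, gamma, xi


def forward_loglik(trend, fit: HmmFit) -> float:
    """Exact HMM marginal log-likelihood via the scaled forward recursion."""
    x = np.asarray(trend, dtype=float)
    if x.ndim != 1:
        raise ValueError("trend must be one-dimensional")
    K = fit.K
    if len(fit.state_means) != K or fit.transition.shape != (K, K):
        raise ValueError("fit dimensions do not match")
    logB = _emission_logprobs(x, fit.state_means, fit.state_vars)
    T = len(x)
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    a = fit.initial * B[0]
    ll = np.log(a.sum())
    a = a / a.sum()
    for t in range(1, T):
        a = (a @ fit.transition) * B[t]
        s = a.sum()
        ll += np.log(s)
        a /= s
    return float(ll + shift.sum())


def viterbi(trend, fit: HmmFit) -> np.ndarray:
    """Most probable joint state path (1-based labels); ties break toward
    the lower state label."""
    x = np.asarray(trend, dtype=float)
    logB = _emission_logprobs(x, fit.state_means, fit.state_vars)
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(fit.transition)
        logpi = np.log(fit.initial)
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA           # cand[j, k]
        back[t] = np.argmax(cand, axis=0)      # first max -> lower label
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path + 1


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _stationary(transition):
    vals, vecs = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    v = np.abs(v)
    return v / v.sum()


def _em_single(x, K, config: HmmConfig, rng) -> tuple | None:
    """One EM run from a quantile-split + jitter initialization.

    Returns (means, vars, transition, initial, loglik, converged, iters)
    or None if the run collapsed (a state variance below the floor).
    """
    T = len(x)
    sd = float(np.std(x))
    qs = np.quantile(x, [(i + 0.5) / K for i in range(K)])
    means = qs + rng.normal(0.0, 0.25 * sd if sd > 0 else 0.25, size=K)
    variances = np.full(K, max(np.var(x), _VAR_FLOOR))
    transition = np.full((K, K), 0.2 / (K - 1)) + np.eye(K) * (0.8 - 0.2 / (K - 1))
    initial = np.full(K, 1.0 / K)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        logB = _emission_logprobs(x, means, variances)
        ll, gamma, xi = _forward_backward(logB, transition, initial)
        if np.abs(ll - ll_prev) < config.loglik_tolerance:
            converged = True
            break
        ll_prev = ll
        w = gamma.sum(axis=0)
        if np.any(w < 1e-10):  # a state lost all responsibility
            return None
        means = (gamma * x[:, None]).sum(axis=0) / w
        variances = (gamma * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / w
        if np.any(variances < _VAR_FLOOR):
            return None
        transition = xi / xi.sum(axis=1, keepdims=True)
        if config.initial_mode == "free":
            initial = gamma[0] / gamma[0].sum()
        else:
            initial = _stationary(transition)
    logB = _emission_logprobs(x, means, variances)
    ll, _, _ = _forward_backward(logB, transition, initial)
    return means, variances, transition, initial, float(ll), converged, it


def _n_params(K: int, initial_mode: str) -> int:
    # transitions K(K-1) + means/vars 2K + initial probabilities K-1 (if free)
    k = K * (K - 1) + 2 * K
    if initial_mode == "free":
        k += K - 1
    return k


def baum_welch(trend, K: int, config: HmmConfig | None = None) -> HmmFit:
    """Fit a K-state Gaussian HMM by EM with seeded restarts.

    The best run by final log-likelihood is kept; states are relabelled in
    ascending order of mean with all parameters permuted consistently, and
    the Viterbi path is decoded on the relabelled fit.
    """
    config = config or HmmConfig()
    x = np.asarray(trend, dtype=float)
    if x.ndim != 1:
        raise ValueError("trend must be one-dimensional")
    if np.isnan(x).any():
        raise ValueError("trend must have no missing values")
    if K not in (2, 3):
        raise ValueError("K must be 2 or 3")
    if len(x) < 3 * K:
        raise HmmError(f"series too short for a {K}-state HMM (T={len(x)})")
    ss = np.random.SeedSequence([config.seed, K])
    rngs = [np.random.default_rng(s) for s in ss.spawn(config.n_restarts)]
    best = None
    for rng in rngs:
        res = _em_single(x, K, config, rng)
        if res is None:
            continue
        if best is None or res[4] > best[4]:
            best = res
    if best is None:
        raise HmmError(
            f"all {config.n_restarts} restarts degenerate (variance collapse) for K={K}"
        )
    means, variances, transition, initial, ll, converged, it = best
    order = np.argsort(means, kind="stable")
    means = means[order]
    variances = variances[order]
    transition = transition[np.ix_(order, order)]
    initial = initial[order]
    k = _n_params(K, config.initial_mode)
    T = len(x)
    from .dfa import aicc as _aicc  # shared small-sample criterion

    fit = HmmFit(
        K=K,
        state_means=means,
        state_vars=variances,
        transition=transition,
        initial=initial,
        loglik=ll,
        n_params=k,
        aicc=_aicc(ll, k, T),
        decoded_path=np.empty(0, dtype=int),
        converged=converged,
        iterations=it,
    )
    fit.decoded_path = viterbi(x, fit)
    return fit


def select_hmm(trend, config: HmmConfig | None = None) -> HmmFit:
    """Fit every candidate state count and keep the minimum-AICc converged
    fit; raises with the full candidate table if all candidates fail."""
    config = config or HmmConfig()
    rows = []
    fits = []
    for K in config.state_candidates:
        try:
            fit = baum_welch(trend, K, config)
            rows.append(dict(K=K, loglik=fit.loglik, n_params=fit.n_params,
                             aicc=fit.aicc, converged=fit.converged))
            fits.append(fit)
        except (HmmError, ValueError) as e:
            rows.append(dict(K=K, loglik=np.nan, n_params=np.nan,
                             aicc=np.nan, converged=False, error=str(e)))
            fits.append(None)
    table = pd.DataFrame(rows)
    ok = [i for i, f in enumerate(fits) if f is not None and f.converged]
    if not ok:
        raise HmmError(f"no HMM candidate converged; candidate table:\n{table}")
    best_i = min(ok, key=lambda i: fits[i].aicc)
    table["delta_aicc"] = table["aicc"] - fits[best_i].aicc
    best = fits[best_i]
    best.candidates = table
    return best


def to_segments(decoded_path, years, persistence=None) -> StateSegments:
    """Run-length encode a decoded path into maximal constant-state year
    ranges tiling the trend's span."""
    path = np.asarray(decoded_path, dtype=int)
    years = np.asarray(years, dtype=int)
    if path.shape != years.shape:
        raise ValueError("path and years must have the same length")
    segs = []
    start = 0
    for t in range(1, len(path) + 1):
        if t == len(path) or path[t] != path[start]:
            segs.append((int(years[start]), int(years[t - 1]), int(path[start])))
            start = t
    pers = np.asarray(persistence, dtype=float) if persistence is not None else np.empty(0)
    return StateSegments(segments=segs, persistence=pers)
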