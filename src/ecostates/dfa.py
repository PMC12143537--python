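"""Maximum-likelihood Dynamic Factor Analysis for annual indicator panels.

Model
-----
Observed standardized series ``y_t`` (n x 1) load on a small number m of
shared latent trends ``x_t``:

    y_t = Z x_t + v_t,      v_t ~ MVN(0, R)
    x_t = x_{t-1} + w_t,    w_t ~ MVN(0, I_m)

The latent process is a multivariate random walk whose innovation
covariance is fixed to the identity for identifiability; Z (loadings) and
R (observation covariance) are estimated by EM with an exact Kalman
filter/smoother E-step that handles missing observations by treating them
as additional latent variables.  Remaining rotational freedom for m = 2 is
removed during estimation by fixing the upper-triangular entries of the
first m rows of Z to zero, and resolved for reporting by varimax rotation
plus a deterministic sign convention.

Model structure (number of trends, observation-covariance pattern) is
chosen by small-sample AICc.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors

from .panel import IndicatorPanel

R_STRUCTURES = ("diagonal_equal", "diagonal_unequal", "equalvarcov", "unconstrained")

__all__ = [
    "DfaConfig",
    "DfaParams",
    "DfaFit",
    "LoadingEstimate",
    "kalman_loglik",
    "fit_dfa",
    "aicc",
    "select_dfa",
    "rotate_and_align",
    "loading_intervals",
    "DfaError",
]


class DfaError(RuntimeError):
    pass


@dataclass(frozen=True)
class DfaConfig:
    """Estimation settings for one DFA fit.

    ``n_trends`` is capped at 2: the analysis targets communicable
    ecosystem-level summaries, not a full factor decomposition.
    """

    n_trends: int = 1
    r_structure: str = "diagonal_unequal"
    max_iterations: int = 5000
    loglik_tolerance: float = 1e-6
    seed: int = 0
    x0_var: float = 5.0
    fixed_R: np.ndarray | None = None  # bypasses the R update (testing / profiling)

    def __post_init__(self):
        if self.n_trends not in (1, 2):
            raise ValueError("n_trends must be 1 or 2")
        if self.r_structure not in R_STRUCTURES:
            raise ValueError(f"unknown r_structure {self.r_structure!r}")
        if self.loglik_tolerance <= 0:
            raise ValueError("loglik_tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class DfaParams:
    """Loadings Z (n x m), observation covariance R (n x n), initial-state prior."""

    Z: np.ndarray
    R: np.ndarray
    x0_mean: np.ndarray
    x0_var: float


@dataclass
class LoadingEstimate:
    series: str
    trend: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    significant: bool
    degenerate: bool = False  # unbounded interval from a singular Hessian


@dataclass
class DfaFit:
    """A fitted DFA: parameters, smoothed trends with SEs, likelihood, AICc."""

    params: DfaParams
    config: DfaConfig
    panel: IndicatorPanel
    trends: np.ndarray        # m x T smoothed states
    trend_ses: np.ndarray     # m x T pointwise standard errors
    loglik: float
    n_params: int
    aicc: float
    converged: bool
    iterations: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    rotation: np.ndarray | None = None      # set by rotate_and_align
    base_params: DfaParams | None = None    # pre-rotation params (identified form)
    candidates: pd.DataFrame | None = None  # set by select_dfa

    @property
    def n_trends(self) -> int:
        return self.params.Z.shape[1]

    def fitted_values(self) -> np.ndarray:
        """T x n model-implied values Z x_t."""
        return (self.params.Z @ self.trends).T

    def trends_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.n_trends):
            for t, yr in enumerate(self.panel.years):
                rows.append((int(yr), k + 1, self.trends[k, t], self.trend_ses[k, t]))
        return pd.DataFrame(rows, columns=["year", "trend", "estimate", "se"])


# ---------------------------------------------------------------------------
# Kalman filter / smoother (unit random walk state, Q = I, missing data)
# ---------------------------------------------------------------------------
# The per-year recursions are JIT-compiled when numba is available; the
# bodies are written in the numpy subset numba supports so the same code
# runs (slower) without it.

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap


@_njit(cache=True)
def _filter_core(y, Z, R, x0_mean, x0_var):
    """Forward pass. Missing entries at each step are handled by dropping
    the corresponding rows of y, Z and R; a step with no observations
    skips the update.  Returns (ok, loglik, filtered means/covs, predicted
    means/covs); ok=False flags a non-positive-definite innovation."""
    T, n = y.shape
    m = Z.shape[1]
    Im = np.eye(m)
    a = x0_mean.copy()
    P = x0_var * Im
    loglik = 0.0
    ms = np.empty((T, m))
    Vs = np.empty((T, m, m))
    preds_a = np.empty((T, m))
    preds_P = np.empty((T, m, m))
    ln2pi = np.log(2.0 * np.pi)
    ok = True
    for t in range(T):
        if t > 0:
            a = ms[t - 1]
            P = Vs[t - 1] + Im
        preds_a[t] = a
        preds_P[t] = P
        idx = np.where(np.isfinite(y[t]))[0]
        p = idx.size
        if p == 0:
            ms[t] = a
            Vs[t] = P
            continue
        Zo = Z[idx]
        v = y[t][idx] - Zo @ a
        PZt = P @ Zo.T
        F = Zo @ PZt + R[idx][:, idx]
        L = np.linalg.cholesky(F)  # raises LinAlgError if not PD (caught by caller)
        if not np.all(np.isfinite(L)):
            ok = False
            break
        alpha = np.linalg.solve(L, v)
        K = np.linalg.solve(L.T, np.linalg.solve(L, PZt.T)).T  # P Z' F^-1
        ms[t] = a + K @ v
        Vt = P - K @ PZt.T
        Vs[t] = 0.5 * (Vt + Vt.T)
        logdet = 0.0
        for i in range(p):
            logdet += np.log(L[i, i])
        loglik += -0.5 * (p * ln2pi + 2.0 * logdet + alpha @ alpha)
    return ok, loglik, ms, Vs, preds_a, preds_P


def _filter(y, Z, R, x0_mean, x0_var):
    try:
        ok, ll, ms, Vs, pa, pP = _filter_core(
            np.ascontiguousarray(y, dtype=np.float64),
            np.ascontiguousarray(Z, dtype=np.float64),
            np.ascontiguousarray(R, dtype=np.float64),
            np.ascontiguousarray(np.asarray(x0_mean, dtype=np.float64).reshape(-1)),
            float(x0_var),
        )
    except np.linalg.LinAlgError as e:
        raise DfaError("innovation covariance not positive definite") from e
    if not ok or not np.isfinite(ll):
        raise DfaError("innovation covariance not positive definite")
    return ll, ms, Vs, pa, pP


@_njit(cache=True)
def _smooth_core(ms, Vs, preds_a, preds_P):
    """Rauch-Tung-Striebel backward pass for the unit-transition model."""
    T, m = ms.shape
    xs = np.empty_like(ms)
    Ps = np.empty_like(Vs)
    xs[T - 1] = ms[T - 1]
    Ps[T - 1] = Vs[T - 1]
    for t in range(T - 2, -1, -1):
        J = np.linalg.solve(preds_P[t + 1].T, Vs[t].T).T  # V_t P_{t+1|t}^-1
        xs[t] = ms[t] + J @ (xs[t + 1] - preds_a[t + 1])
        Pt = Vs[t] + J @ (Ps[t + 1] - preds_P[t + 1]) @ J.T
        Ps[t] = 0.5 * (Pt + Pt.T)
    return xs, Ps


def _smooth(ms, Vs, preds_a, preds_P):
    return _smooth_core(ms, Vs, preds_a, preds_P)


def kalman_loglik(params: DfaParams, panel: IndicatorPanel | np.ndarray) -> float:
    """Exact marginal log-likelihood of the observed entries.

    Accepts a panel or a raw T x n matrix with NaN for missing values.
    """
    y = panel.values if isinstance(panel, IndicatorPanel) else np.asarray(panel, float)
    Z, R = params.Z, params.R
    if y.shape[1] != Z.shape[0] or R.shape != (Z.shape[0], Z.shape[0]):
        raise ValueError("parameter dimensions do not match panel")
    ll, *_ = _filter(y, Z, R, params.x0_mean, params.x0_var)
    return float(ll)


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------

def _free_z_indices(n: int, m: int):
    """(row, col) of free loadings; entries above the diagonal in the first
    m rows are pinned to zero for identifiability."""
    return [(i, j) for j in range(m) for i in range(n) if not (i < m and j > i)]


def _project_R(S: np.ndarray, structure: str) -> np.ndarray:
    """Exact constrained M-step for R given the unconstrained maximizer S.

    Each structure is a linear family closed under inversion, so matching
    the pattern averages of S maximizes the expected log-likelihood within
    the family.
    """
    n = S.shape[0]
    if structure == "diagonal_unequal":
        return np.diag(np.diag(S).copy())
    if structure == "diagonal_equal":
        return np.eye(n) * float(np.mean(np.diag(S)))
    if structure == "equalvarcov":
        var = float(np.mean(np.diag(S)))
        if n > 1:
            cov = float((S.sum() - np.trace(S)) / (n * (n - 1)))
        else:
            cov = 0.0
        return np.full((n, n), cov) + np.eye(n) * (var - cov)
    return 0.5 * (S + S.T)  # unconstrained


@_njit(cache=True)
def _estep_stats_core(y, Z, R, xs, Ps):
    """Sufficient statistics S_xx, S_yx, S_yy with missing y treated as latent."""
    T, n = y.shape
    m = xs.shape[1]
    S_xx = np.zeros((m, m))
    S_yx = np.zeros((n, m))
    S_yy = np.zeros((n, n))
    for t in range(T):
        xhat = xs[t]
        P = Ps[t] + np.outer(xhat, xhat)
        S_xx += P
        fin = np.isfinite(y[t])
        if fin.all():
            yo = y[t]
            S_yx += np.outer(yo, xhat)
            S_yy += np.outer(yo, yo)
            continue
        oi = np.where(fin)[0]
        mi = np.where(~fin)[0]
        Eyx = np.empty((n, m))
        Eyy = np.empty((n, n))
        if oi.size > 0:
            yo = y[t][oi]
            Zo = Z[oi]
            Zm = Z[mi]
            Roo = R[oi][:, oi]
            Rmo = R[mi][:, oi]
            G = np.linalg.solve(Roo.T, Rmo.T).T        # R_mo R_oo^-1
            A = Zm - G @ Zo
            yhat_m = Zm @ xhat + G @ (yo - Zo @ xhat)
            Eyx_o = np.outer(yo, xhat)
            Eyx_m = Zm @ P + G @ (Eyx_o - Zo @ P)
            Vm = (R[mi][:, mi] - G @ Rmo.T) + A @ Ps[t] @ A.T
            oo = np.outer(yo, yo)
            om = np.outer(yo, yhat_m)
            mm = Vm + np.outer(yhat_m, yhat_m)
            for a in range(oi.size):
                Eyx[oi[a]] = Eyx_o[a]
                for b in range(oi.size):
                    Eyy[oi[a], oi[b]] = oo[a, b]
                for b in range(mi.size):
                    Eyy[oi[a], mi[b]] = om[a, b]
                    Eyy[mi[b], oi[a]] = om[a, b]
            for a in range(mi.size):
                Eyx[mi[a]] = Eyx_m[a]
                for b in range(mi.size):
                    Eyy[mi[a], mi[b]] = mm[a, b]
        else:
            # whole year unobserved: moments are fully model-implied
            Eyx = Z @ P
            Eyy = R + Z @ P @ Z.T  # Var(y|x) = R, E[Z x x' Z'] = Z P Z'
        S_yx += Eyx
        S_yy += 0.5 * (Eyy + Eyy.T)
    return S_xx, S_yx, S_yy


def _estep_stats(y, Z, R, xs, Ps):
    return _estep_stats_core(
        np.ascontiguousarray(y), np.ascontiguousarray(Z),
        np.ascontiguousarray(R), np.ascontiguousarray(xs), np.ascontiguousarray(Ps),
    )


def _update_Z(S_xx, S_yx, R, free_idx, n, m):
    """Constrained GLS update of Z: solve the normal equations restricted to
    the free entries (coupled across rows when R is non-diagonal)."""
    Rinv = np.linalg.inv(R)
    k = len(free_idx)
    A = np.empty((k, k))
    b = np.empty(k)
    M = Rinv @ S_yx
    for a_i, (i, j) in enumerate(free_idx):
        b[a_i] = M[i, j]
        for a_k, (p, q) in enumerate(free_idx):
            A[a_i, a_k] = Rinv[i, p] * S_xx[q, j]
    z = np.linalg.solve(A, b)
    Z = np.zeros((n, m))
    for a_i, (i, j) in enumerate(free_idx):
        Z[i, j] = z[a_i]
    return Z


def n_free_params(n: int, m: int, r_structure: str) -> int:
    """Count of estimated parameters: free loadings plus R parameters."""
    z_free = n * m - m * (m - 1) // 2
    r_free = {
        "diagonal_equal": 1,
        "diagonal_unequal": n,
        "equalvarcov": 2,
        "unconstrained": n * (n + 1) // 2,
    }[r_structure]
    return z_free + r_free


def _init_params(y, config: DfaConfig) -> DfaParams:
    """SVD-based starting loadings plus a small seeded uniform perturbation;
    R initialised from sample variances projected to the declared structure."""
    T, n = y.shape
    m = config.n_trends
    rng = np.random.default_rng(config.seed)
    y0 = np.where(np.isfinite(y), y, 0.0)
    try:
        _, sv, Vt = np.linalg.svd(y0, full_matrices=False)
        Z0 = (Vt[:m].T * (sv[:m] / np.sqrt(max(T, 1))))
    except np.linalg.LinAlgError:
        Z0 = np.zeros((n, m))
    Z0 = Z0 + rng.uniform(-0.1, 0.1, size=(n, m))
    for i, j in itertools.product(range(m), range(m)):
        if j > i:
            Z0[i, j] = 0.0
    var0 = np.nanvar(y, axis=0, ddof=1)
    var0 = np.where(np.isfinite(var0) & (var0 > 0), var0, 1.0)
    R0 = _project_R(np.diag(var0), config.r_structure)
    if config.fixed_R is not None:
        R0 = np.array(config.fixed_R, dtype=float)
        if R0.ndim == 0:
            R0 = np.eye(n) * float(R0)
    return DfaParams(Z=Z0, R=R0, x0_mean=np.zeros(m), x0_var=config.x0_var)


def fit_dfa(panel: IndicatorPanel, config: DfaConfig) -> DfaFit:
    """EM fit of the DFA model to a standardized panel.

    The log-likelihood is non-decreasing across iterations (exact E-step,
    exact conditional M-steps); estimation stops when the absolute
    improvement drops below ``loglik_tolerance`` or at ``max_iterations``,
    in which case the fit is returned with ``converged=False``.
    """
    y = panel.values
    T, n = y.shape
    m = config.n_trends
    if n < m:
        raise DfaError(f"need at least {m} series to fit {m} trends (got {n})")
    params = _init_params(y, config)
    free_idx = _free_z_indices(n, m)
    ll_path = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        ll, ms, Vs, pa, pP = _filter(y, params.Z, params.R, params.x0_mean, params.x0_var)
        ll_path.append(ll)
        if np.abs(ll - ll_prev) < config.loglik_tolerance:
            converged = True
            break
        ll_prev = ll
        xs, Ps = _smooth(ms, Vs, pa, pP)
        S_xx, S_yx, S_yy = _estep_stats(y, params.Z, params.R, xs, Ps)
        Z_new = _update_Z(S_xx, S_yx, params.R, free_idx, n, m)
        if config.fixed_R is None:
            S = (S_yy - Z_new @ S_yx.T - S_yx @ Z_new.T + Z_new @ S_xx @ Z_new.T) / T
            R_new = _project_R(S, config.r_structure)
        else:
            R_new = params.R
        params = replace(params, Z=Z_new, R=R_new)
    ll, ms, Vs, pa, pP = _filter(y, params.Z, params.R, params.x0_mean, params.x0_var)
    xs, Ps = _smooth(ms, Vs, pa, pP)
    ses = np.sqrt(np.maximum(np.array([np.diag(P) for P in Ps]), 0.0)).T
    k = n_free_params(n, m, config.r_structure)
    if config.fixed_R is not None:
        k = len(free_idx)
    n_obs = int(np.isfinite(y).sum())
    return DfaFit(
        params=params,
        config=config,
        panel=panel,
        trends=xs.T.copy(),
        trend_ses=ses,
        loglik=float(ll),
        n_params=k,
        aicc=aicc(float(ll), k, n_obs),
        converged=converged,
        iterations=it,
        loglik_path=np.asarray(ll_path),
    )


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Small-sample corrected AIC:
    -2 loglik + 2k + 2k(k+1)/(n - k - 1)."""
    if n_obs <= n_params + 1:
        raise ValueError(
            f"AICc undefined: n_obs={n_obs} must exceed n_params+1={n_params + 1}"
        )
    k = n_params
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def select_dfa(
    panel: IndicatorPanel,
    trend_candidates=(1, 2),
    r_candidates=R_STRUCTURES,
    **config_kwargs,
) -> DfaFit:
    """Fit every (n_trends, r_structure) candidate and keep the minimum-AICc
    converged fit.  The full candidate table (with delta-AICc) is attached
    to the returned fit; non-converged candidates are excluded from the
    ranking since AICc is meaningless away from an optimum.
    """
    if not trend_candidates or not r_candidates:
        raise ValueError("candidate sets must be non-empty")
    rows = []
    fits: list[DfaFit | None] = []
    for m in trend_candidates:
        for rs in r_candidates:
            cfg = DfaConfig(n_trends=m, r_structure=rs, **config_kwargs)
            try:
                fit = fit_dfa(panel, cfg)
                rows.append(
                    dict(n_trends=m, r_structure=rs, loglik=fit.loglik,
                         n_params=fit.n_params, aicc=fit.aicc, converged=fit.converged)
                )
                fits.append(fit)
            except (DfaError, np.linalg.LinAlgError) as e:
                rows.append(
                    dict(n_trends=m, r_structure=rs, loglik=np.nan,
                         n_params=np.nan, aicc=np.nan, converged=False, error=str(e))
                )
                fits.append(None)
    table = pd.DataFrame(rows)
    ok = [i for i, f in enumerate(fits) if f is not None and f.converged]
    if not ok:
        raise DfaError(f"no DFA candidate converged; candidate table:\n{table}")
    best_i = min(ok, key=lambda i: fits[i].aicc)
    table["delta_aicc"] = table["aicc"] - fits[best_i].aicc
    best = fits[best_i]
    best.candidates = table
    return best


# ---------------------------------------------------------------------------
# rotation, alignment, confidence intervals
# ---------------------------------------------------------------------------

def rotate_and_align(fit: DfaFit) -> DfaFit:
    """Varimax-rotate 2-trend solutions and fix trend signs for reporting.

    The rotation is applied jointly to Z and the trends so all fitted
    values (and the likelihood) are invariant.  Each trend's sign is
    chosen so that the sum of its loadings is non-negative; applying the
    function twice is a no-op.
    """
    m = fit.n_trends
    Z = fit.params.Z
    if m >= 2:
        _, Tmat = rotate_factors(Z, "varimax")
    else:
        Tmat = np.eye(1)
    Z_rot = Z @ Tmat
    signs = np.where(Z_rot.sum(axis=0) < 0, -1.0, 1.0)
    Tfull = Tmat * signs  # column sign flips
    Z_rot = Z @ Tfull
    trends = Tfull.T @ fit.trends
    ses = np.empty_like(fit.trend_ses)
    # rotate pointwise state covariances for the SEs (diag of T' V T)
    for t in range(fit.trends.shape[1]):
        V = np.diag(fit.trend_ses[:, t] ** 2)
        ses[:, t] = np.sqrt(np.maximum(np.diag(Tfull.T @ V @ Tfull), 0.0))
    base = fit.base_params if fit.base_params is not None else fit.params
    prev_rot = fit.rotation if fit.rotation is not None else np.eye(m)
    new_params = DfaParams(Z=Z_rot, R=fit.params.R.copy(),
                           x0_mean=Tfull.T @ fit.params.x0_mean, x0_var=fit.params.x0_var)
    return replace(
        fit,
        params=new_params,
        trends=trends,
        trend_ses=ses,
        base_params=base,
        rotation=prev_rot @ Tfull,
    )


def _pack_r(R: np.ndarray, structure: str) -> np.ndarray:
    n = R.shape[0]
    if structure == "diagonal_equal":
        return np.array([R[0, 0]])
    if structure == "diagonal_unequal":
        return np.diag(R).copy()
    if structure == "equalvarcov":
        return np.array([R[0, 0], R[0, 1] if n > 1 else 0.0])
    return R[np.tril_indices(n)]


def _unpack_r(theta: np.ndarray, structure: str, n: int) -> np.ndarray:
    if structure == "diagonal_equal":
        return np.eye(n) * theta[0]
    if structure == "diagonal_unequal":
        return np.diag(theta)
    if structure == "equalvarcov":
        var, cov = theta
        return np.full((n, n), cov) + np.eye(n) * (var - cov)
    R = np.zeros((n, n))
    R[np.tril_indices(n)] = theta
    return R + np.tril(R, -1).T


def _hessian(f, theta, rel_step=1e-4):
    """Central-difference Hessian of a scalar function."""
    k = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                f0 = f(theta)
                H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def loading_intervals(fit: DfaFit, level: float = 0.95) -> list[LoadingEstimate]:
    """Wald confidence intervals for the (rotated/aligned) loadings.

    The observed information is the numerical Hessian of the negative
    log-likelihood at the MLE in the identified parameterization (free
    loadings + R parameters); the loading covariance block is then pushed
    through the fixed rotation.  A singular Hessian yields unbounded
    intervals flagged as degenerate rather than an exception.
    """
    base = fit.base_params if fit.base_params is not None else fit.params
    n, m = base.Z.shape
    structure = fit.config.r_structure
    free_idx = _free_z_indices(n, m)
    y = fit.panel.values

    z0 = np.array([base.Z[i, j] for i, j in free_idx])
    if fit.config.fixed_R is None:
        r0 = _pack_r(base.R, structure)
    else:
        r0 = np.empty(0)
    theta0 = np.concatenate([z0, r0])
    nz = len(z0)

    def negll(theta):
        Z = np.zeros((n, m))
        for a, (i, j) in enumerate(free_idx):
            Z[i, j] = theta[a]
        R = base.R if fit.config.fixed_R is not None else _unpack_r(theta[nz:], structure, n)
        p = DfaParams(Z=Z, R=R, x0_mean=base.x0_mean, x0_var=base.x0_var)
        try:
            return -kalman_loglik(p, y)
        except DfaError:
            return np.inf

    H = _hessian(negll, theta0)
    cov_z = None
    try:
        cov = np.linalg.inv(H)
        dvar = np.diag(cov)[:nz]
        if np.all(np.isfinite(dvar)) and np.all(dvar > 0):
            cov_z = cov[:nz, :nz]
    except np.linalg.LinAlgError:
        cov_z = None

    zcrit = stats.norm.ppf(0.5 * (1.0 + level))
    rot = fit.rotation if fit.rotation is not None else np.eye(m)
    out = []
    if cov_z is not None:
        # embed into full vec(Z) covariance (column-major), then rotate
        C = np.zeros((n * m, n * m))
        flat = [j * n + i for i, j in free_idx]
        C[np.ix_(flat, flat)] = cov_z
        K = np.kron(rot.T, np.eye(n))
        C_rot = K @ C @ K.T
        se_mat = np.sqrt(np.maximum(np.diag(C_rot), 0.0)).reshape(m, n).T
    else:
        se_mat = np.full((n, m), np.inf)
    names = fit.panel.names
    for j in range(m):
        for i in range(n):
            est = float(fit.params.Z[i, j])
            se = float(se_mat[i, j])
            degenerate = not np.isfinite(se)
            lo, hi = est - zcrit * se, est + zcrit * se
            out.append(
                LoadingEstimate(
                    series=names[i], trend=j + 1, estimate=est, se=se,
                    ci_low=lo, ci_high=hi,
                    significant=bool(np.isfinite(se) and (lo > 0.0 or hi < 0.0)),
                    degenerate=degenerate,
                )
            )
    return out


def loadings_frame(estimates: list[LoadingEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(series=e.series, trend=e.trend, estimate=e.estimate, se=e.se,
                 ci_low=e.ci_low, ci_high=e.ci_high, significant=e.significant)
            for e in estimates
        ]
    )
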