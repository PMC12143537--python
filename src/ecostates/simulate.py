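"""Synthetic indicator panels with known regime structure.

Generates data with exactly the statistical features the analysis assumes:
one or two shared latent trends that combine a regime-switching mean with
a random-walk component, indicator loadings of both signs, structured
observation noise, staggered series start years and sporadic missing
values.  The generating parameters are retained so trend, loading and
state recovery can be verified.

The default scenario mirrors the scale of the shorter analysis window of
the motivating application: 38 years (1985-2022), 12 indicators, one
trend, a single regime shift 30 years in (the 2014 analogue).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .panel import IndicatorPanel, IndicatorSeries, write_panel

__all__ = [
    "RegimeSpec",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_regime_trend",
    "simulate_dfa_panel",
    "simulate_ar1_pair",
    "make_dataset",
    "default_scenario",
]


@dataclass(frozen=True)
class RegimeSpec:
    """Regime structure of a latent trend.

    Either ``change_years`` gives explicit 0-based indices at which the
    state advances to the next one in sequence, or ``transition`` gives a
    row-stochastic matrix from which the state sequence is simulated.
    ``means`` are the state-dependent trend levels; ``sds`` the within-state
    emission noise around those levels.
    """

    means: tuple = (-1.0, 1.0)
    sds: tuple = (0.3, 0.3)
    change_years: tuple | None = None
    transition: tuple | None = None  # nested tuples, row-stochastic

    def __post_init__(self):
        if len(self.means) != len(self.sds):
            raise ValueError("means and sds must have the same length")
        if (self.change_years is None) == (self.transition is None):
            raise ValueError("specify exactly one of change_years or transition")
        if self.transition is not None:
            A = np.asarray(self.transition, dtype=float)
            K = len(self.means)
            if A.shape != (K, K) or np.any(A < 0) or not np.allclose(A.sum(axis=1), 1.0):
                raise ValueError("transition must be a row-stochastic K x K matrix")


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for a synthetic panel; (config, seed) determines every draw."""

    T: int = 38
    n_series: int = 12
    n_trends: int = 1
    regimes: tuple = (RegimeSpec(change_years=(29,)),)  # one spec per trend
    walk_sd: float = 0.25
    loading_min: float = 0.3
    loading_max: float = 1.0
    r_structure: str = "diagonal_equal"
    noise_sd: float | tuple = 0.5
    noise_cov: float = 0.0  # off-diagonal covariance for equalvarcov
    start_offsets: tuple | None = (0, 0, 0, 0, 0, 0, 5, 5, 5, 13, 13, 13)
    missing_rate: float = 0.05
    start_year: int = 1985
    seed: int = 0

    def __post_init__(self):
        if self.T < 20:
            raise ValueError("T must be at least 20")
        if len(self.regimes) != self.n_trends:
            raise ValueError("one RegimeSpec per trend required")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.start_offsets is not None and len(self.start_offsets) != self.n_series:
            raise ValueError("start_offsets must have one entry per series")


@dataclass
class SyntheticDataset:
    """A simulated panel bundled with its generating truth."""

    panel: IndicatorPanel
    true_trends: np.ndarray   # m x T
    true_states: np.ndarray   # m x T, 1-based
    true_Z: np.ndarray        # n x m
    true_R: np.ndarray        # n x n
    config: SimulationConfig = None

    def write(self, csv_path, truth_path=None):
        """Panel as the standard CSV dialect; truth as JSON."""
        write_panel(self.panel, csv_path)
        if truth_path is not None:
            truth = dict(
                true_trends=self.true_trends.tolist(),
                true_states=self.true_states.tolist(),
                true_Z=self.true_Z.tolist(),
                true_R=self.true_R.tolist(),
                config=_config_dict(self.config) if self.config else None,
            )
            with open(truth_path, "w") as fh:
                json.dump(truth, fh, indent=1)


def _config_dict(config):
    d = asdict(config)
    return d


# ---------------------------------------------------------------------------
# latent trend
# ---------------------------------------------------------------------------

def simulate_regime_trend(
    T: int, regime: RegimeSpec, walk_sd: float = 0.25, rng=None, seed: int | None = None
):
    """Simulate one latent trend: state-dependent mean plus within-state
    noise plus a shared random-walk component.

    Returns (trend, states) with 1-based state labels.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    K = len(regime.means)
    states = np.empty(T, dtype=int)
    if regime.change_years is not None:
        states[:] = 0
        for i, cy in enumerate(regime.change_years):
            if not (0 < cy < T):
                raise ValueError("change years must fall inside the series")
            states[cy:] = i + 1
        if states.max() >= K:
            raise ValueError("more change years than states")
    else:
        A = np.asarray(regime.transition, dtype=float)
        s = int(rng.integers(K))
        for t in range(T):
            states[t] = s
            s = int(rng.choice(K, p=A[s]))
    means = np.asarray(regime.means, dtype=float)
    sds = np.asarray(regime.sds, dtype=float)
    walk = np.cumsum(rng.normal(0.0, walk_sd, size=T)) if walk_sd > 0 else np.zeros(T)
    noise = rng.normal(0.0, 1.0, size=T) * sds[states]
    trend = means[states] + noise + walk
    return trend, states + 1


# ---------------------------------------------------------------------------
# observation layer
# ---------------------------------------------------------------------------

def _build_R(config: SimulationConfig) -> np.ndarray:
    n = config.n_series
    if config.r_structure == "diagonal_equal":
        return np.eye(n) * float(config.noise_sd) ** 2
    if config.r_structure == "diagonal_unequal":
        sds = np.asarray(config.noise_sd, dtype=float)
        if sds.ndim == 0:
            sds = np.full(n, float(sds))
        return np.diag(sds**2)
    if config.r_structure == "equalvarcov":
        var = float(config.noise_sd) ** 2
        cov = float(config.noise_cov)
        if abs(cov) >= var:
            raise ValueError("|noise_cov| must be smaller than the variance")
        return np.full((n, n), cov) + np.eye(n) * (var - cov)
    raise ValueError(f"unsupported r_structure {config.r_structure!r} for simulation")


def simulate_dfa_panel(trends, config: SimulationConfig, rng=None) -> SyntheticDataset:
    """Observe latent trends through signed loadings and structured noise,
    then impose staggered starts and random missing years.

    ``trends`` is (m, T) (a 1-D array is treated as a single trend).
    Loadings are drawn uniformly on +/-[loading_min, loading_max].
    """
    x = np.atleast_2d(np.asarray(trends, dtype=float))
    m, T = x.shape
    if m != config.n_trends or T != config.T:
        raise ValueError("trends shape inconsistent with config")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = config.n_series
    mag = rng.uniform(config.loading_min, config.loading_max, size=(n, m))
    sign = rng.choice([-1.0, 1.0], size=(n, m))
    Z = mag * sign
    R = _build_R(config)
    L = np.linalg.cholesky(R)
    noise = rng.normal(size=(T, n)) @ L.T
    y = x.T @ Z.T + noise

    offsets = config.start_offsets or tuple([0] * n)
    mask = np.ones((T, n), dtype=bool)
    for j, off in enumerate(offsets):
        mask[: int(off), j] = False
    if config.missing_rate > 0:
        holes = rng.random((T, n)) < config.missing_rate
        mask &= ~holes
    if np.any(mask.sum(axis=0) < 2):
        bad = [j for j in range(n) if mask[:, j].sum() < 2]
        raise ValueError(f"missingness leaves fewer than 2 observations in series {bad}")

    y_obs = np.where(mask, y, np.nan)
    years = np.arange(config.start_year, config.start_year + T)
    series = [
        IndicatorSeries(name=f"ind{j + 1:02d}", years=years, values=y_obs[:, j])
        for j in range(n)
    ]
    panel = IndicatorPanel(years, series)
    return SyntheticDataset(
        panel=panel, true_trends=x, true_states=np.empty((m, 0)),
        true_Z=Z, true_R=R, config=config,
    )


def make_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate trends and panel from one config; fully determined by
    (config, config.seed)."""
    rng = np.random.default_rng(config.seed)
    trends = np.empty((config.n_trends, config.T))
    states = np.empty((config.n_trends, config.T), dtype=int)
    for k, regime in enumerate(config.regimes):
        trends[k], states[k] = simulate_regime_trend(
            config.T, regime, walk_sd=config.walk_sd, rng=rng
        )
    ds = simulate_dfa_panel(trends, config, rng=rng)
    ds.true_states = states
    return ds


def default_scenario(seed: int = 0, **overrides) -> SimulationConfig:
    """The package's reference scenario (see module docstring)."""
    return SimulationConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# AR(1) fixture for the correlation-correction tests
# ---------------------------------------------------------------------------

def simulate_ar1_pair(phi_x: float, phi_y: float, N: int, seed=None, rng=None):
    """Two independent stationary AR(1) series with unit marginal variance."""
    if abs(phi_x) >= 1 or abs(phi_y) >= 1:
        raise ValueError("|phi| must be < 1 for stationarity")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for phi in (phi_x, phi_y):
        z = np.empty(N)
        z[0] = rng.normal()
        innov_sd = np.sqrt(1.0 - phi**2)
        eps = rng.normal(0.0, innov_sd, size=N - 1)
        for t in range(1, N):
            z[t] = phi * z[t - 1] + eps[t - 1]
        out.append(z)
    return out[0], out[1]
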