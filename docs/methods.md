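# Methods

This note documents the models implemented in `ecostates`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## The indicator panel

The unit of analysis is a panel of annual indicator series (temperature
indices, plankton biomass, forage-fish CPUE, seabird reproductive metrics,
...) on one contiguous calendar-year grid. Series typically start in
different years and have sporadic gaps; both are represented as missing
values on the common grid so that the annual state equation below always
advances exactly one year per step. Strictly positive, highly skewed
abundance series can be transformed as ln(x + 0.01) before analysis; the
offset keeps zero catches finite.

Before trend extraction every series is z-scored over its observed entries
(sample sd, ddof = 1). Loadings on mixed-unit indicators are not
comparable without this; the stored per-series mean and sd invert the
transform exactly. Standardization is a package choice: it is the
conventional preprocessing for this model class, and nothing downstream
depends on the original units.

## Dynamic factor analysis

The m-trend DFA model (m = 1 or 2) is the linear-Gaussian state space

    y_t = Z x_t + v_t,   v_t ~ MVN(0, R)
    x_t = x_{t-1} + w_t, w_t ~ MVN(0, I_m)

with the trend-innovation covariance fixed to the identity for
identifiability. Four observation-covariance families are supported:
equal-variance diagonal, unequal-variance diagonal, equal variance with a
single shared covariance ("equalvarcov"), and unconstrained symmetric.

**Estimation.** EM with an exact Kalman filter/smoother E-step. Missing
observations are dropped from the filter update at their time step (the
marginal likelihood is exact), and treated as additional latent variables
in the M-step sufficient statistics, so panels with staggered starts use
every observed value and nothing else. The constrained M-steps are exact:

- Z solves the GLS normal equations restricted to its free entries
  (entries above the diagonal in the first m rows are pinned to zero —
  the standard identification of the rotational freedom during fitting);
- R is the pattern average of the unconstrained maximizer. Each supported
  R family is a linear matrix family closed under inversion, for which
  pattern-averaging is the exact constrained maximizer.

Because both conditional maximizations are exact, the log-likelihood is
non-decreasing across iterations; this is asserted by the test suite on
every fit.

**Initialization and convergence.** Z starts from an SVD of the
zero-filled standardized panel plus a small seeded uniform perturbation
(the perturbation makes restarts and seeds meaningful; the SVD start cuts
the long EM tail substantially). R starts from sample variances projected
to the declared structure. The initial state has a fixed diffuse prior
x_1 ~ N(0, 5 I). Convergence is declared when the absolute log-likelihood
improvement falls below 1e-6 (default), up to 5000 iterations by default;
experiments that must always reach the optimum raise the cap to 20000.
Non-convergence is reported honestly (`converged=False`), never hidden.

**Model selection.** All (trend count x R structure) candidates are fitted
and ranked by small-sample AICc,

    AICc = -2 logL + 2k + 2k(k+1)/(n_obs - k - 1),

with k the number of free loadings plus R parameters and n_obs the count
of observed (non-missing) data points — missing-heavy panels must not
inflate the effective sample size. Non-converged candidates are excluded
from ranking (an information criterion is meaningless away from an
optimum) but kept in the reported candidate table.

**Rotation and reporting.** Two-trend solutions are varimax-rotated
(jointly on Z and the trends, so fitted values and the likelihood are
invariant); each trend's sign is then fixed so its loading sum is
non-negative. The operation is idempotent. Loading confidence intervals
are Wald intervals from the numerically differentiated observed
information (central differences on the free parameters at the MLE), with
the loading covariance block pushed through the fixed rotation. A singular
Hessian produces unbounded, flagged intervals rather than an exception.
A parametric bootstrap was considered and not implemented: the coverage
simulation below shows the Hessian intervals are adequate at these panel
sizes.

## Hidden Markov ecosystem states

Each smoothed trend is fed, as a point estimate, to univariate Gaussian
HMMs with K = 2 and K = 3 states (trend uncertainty is not propagated;
the states are descriptions of the trend estimate, which is how the
results are reported and used). Estimation is Baum-Welch EM with 20
seeded restarts by default (means initialized by quantile split plus
jitter of 0.25 trend-sd, sticky 0.8-diagonal transition start). The
initial state distribution is estimated freely and counted in the
parameter total k = K(K-1) + 2K + (K-1); tying it to the stationary
distribution of the transition matrix is available by configuration.
Restarts whose state variance collapses below 1e-8 (the unbounded
Gaussian-likelihood singularity) are discarded; if every restart
collapses the fit fails loudly. States are relabelled in ascending order
of mean, the state count is chosen by AICc over {2, 3}, Viterbi decoding
breaks ties toward the lower state label, and each state's persistence is
reported as the corresponding diagonal element of the transition matrix.

## Non-stationarity screening

Pearson correlations between each standardized indicator and each trend
are computed in centered 11-year moving windows (stride 1); a window is
emitted only when it contains at least 8 complete pairs with non-zero
variance. Inference uses the effective sample size

    1/N* = 1/N + (2/N) sum_{j=1..L} rho_xx(j) rho_yy(j)

with the small-sample-corrected autocorrelation estimator
rho(j) = N/(N-j) x (lag-j autocovariance / variance). The lag cap L is
max(2, window // 5) inside windows and N/5 for full series, reflecting
how many lags are estimable. N* is clipped to (2, N]; when the correction
sum is non-positive N* = N exactly. Confidence intervals (90% by default)
are Fisher-z intervals with SE = 1/sqrt(N* - 3); the z scale makes the
interval invertible and testable, and the coverage experiment below
verifies it is near-nominal for autocorrelated series. Windows whose N*
falls at or below 3 receive the non-informative interval (-1, 1).

Two change rules are screened per indicator-trend pair: a **sign change**
requires two windows with opposite-signed correlations that both exclude
zero; a **magnitude change** is any pair of windows (not only adjacent
ones — the rule is a range condition) whose correlations differ by more
than 0.5.

## Synthetic data

The generator produces exactly the structure the analysis assumes: latent
trends built as state-dependent means (from explicit change years or a
simulated Markov chain) plus within-state Gaussian noise plus a
random-walk component; observations y_t = Z x_t + v_t with loadings drawn
uniformly on +/-[0.3, 1] and structured noise; leading-year truncation per
series and random missing years. Every draw is determined by (config,
seed).

The reference scenario is 38 years x 12 series, one trend with a single
mean shift from -1 to +1 after year 30, within-state sd 0.3, walk sd
0.25, equal-variance noise sd 0.5, staggered starts (six series full
span, three starting 5 years in, three 13 years in) and 5% random
missingness. This mirrors the scale of a 1985-2022 ecosystem-indicator
panel with a large late shift, series of 25-38 years, and survey gaps.
Recovery experiments that need the estimation model to be exactly true
(likelihood oracles, loading coverage, trend-count calibration) instead
simulate a pure unit-variance random-walk trend with no regime structure.

What the generator does **not** emulate: nonlinear indicator responses,
observation noise that is autocorrelated or non-Gaussian, trend
innovations that differ from the fitted random walk, and the multi-survey
heterogeneity of real monitoring programs. Passing recovery tests
therefore demonstrates correctness of the estimators under their own
assumptions, not robustness to their violation.

## Problem sizes used in the verification experiments

- Exact-likelihood oracles: 50 random instances with T <= 8, n <= 3
  (stacked joint-Gaussian density) and 50 with T <= 10, K <= 3
  (exhaustive K^T path enumeration).
- DFA recovery: 20 replicates of the 50-year, 12-series random-walk
  scenario; trend-count calibration: 25 replicates; loading-interval
  coverage: 60 replicates of a 40-year, 8-series variant, pooled across
  loadings.
- HMM calibration: 25 replicates each for the 2-state (T=50, 3-sd
  separation) and 3-state (T=60, 4-sd separation) designs; decoding
  accuracy: 25 replicates (2-sd separation, persistence 0.9); end-to-end
  shift recovery: 10 replicates of the reference scenario.
- Correlation-correction coverage: 2000 independent AR(1) pairs
  (phi = 0.5, N = 40).

These sizes were chosen to make the sampling error of each measured rate
small relative to its acceptance band while keeping the full suite
comfortably runnable on one CPU.

## Known limitations

- Trend counts above 2 and HMM state counts above 3 are out of scope by
  design (the method targets communicable ecosystem summaries).
- HMMs consume smoothed trend point estimates; decoded state boundaries
  near the ends of noisy trends inherit the smoother's uncertainty.
- The equalvarcov and unconstrained R families can be weakly identified
  on short, gap-heavy panels; such candidates may legitimately fail to
  converge and are then excluded from selection.
- Wald loading intervals rely on a quadratic local approximation; on very
  short panels the bootstrap would be preferable.
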