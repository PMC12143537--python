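import numpy as np
import pytest

from ecostates import (
    DfaConfig,
    RegimeSpec,
    SimulationConfig,
    default_scenario,
    fit_dfa,
    make_dataset,
    standardize,
)


def random_walk_config(seed, T=50, n=12, noise_sd=0.5, r_structure="diagonal_equal"):
    """A panel generated from the exact DFA model: one unit-variance random
    walk trend, signed loadings with |l| >= 0.3, structured noise, no gaps."""
    return SimulationConfig(
        T=T,
        n_series=n,
        n_trends=1,
        regimes=(RegimeSpec(means=(0.0,), sds=(0.0,), change_years=()),),
        walk_sd=1.0,
        noise_sd=noise_sd,
        r_structure=r_structure,
        start_offsets=None,
        missing_rate=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The reference regime-shift scenario (38 years, 12 series, shift at
    year 30)."""
    return make_dataset(default_scenario(seed=11))


@pytest.fixture(scope="session")
def small_fit(default_dataset):
    """A converged single-trend fit of the default scenario, reused by
    rotation / interval / pipeline-adjacent tests."""
    std = standardize(default_dataset.panel)
    fit = fit_dfa(std, DfaConfig(n_trends=1, r_structure="diagonal_equal", seed=3))
    assert fit.converged
    return fit


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
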