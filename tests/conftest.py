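import numpy as np
import pandas as pd
import pytest

from tatspc import SyntheticConfig, TATSeries, generate_tat_series


@pytest.fixture
def rng():
    return np.random.default_rng(20210924)


@pytest.fixture
def small_series():
    """A hand-written 12-case series (enough for the default EWMA window)."""
    wet = [20, 18, 25, 15, 22, 19, 30, 17, 16, 21, 14, 18]
    dry = [12, 10, 9, 14, 11, 8, 13, 10, 9, 12, 7, 9]
    overall = [35, 30, 36, 31, 35, 29, 45, 29, 27, 35, 23, 29]
    return TATSeries.from_records(wet, dry, overall)


@pytest.fixture
def synthetic_series():
    """One draw from the default generator configuration."""
    return generate_tat_series(SyntheticConfig(seed=42))


def small_config(n_cases, seed, **overrides):
    """Default-like generator config scaled down to short series."""
    kwargs = dict(
        n_cases=n_cases,
        seed=seed,
        changepoints_wet=((max(2, n_cases // 3), -0.4),),
        changepoints_dry=((max(2, n_cases // 4), -0.4),),
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def random_series(rng, n):
    """A valid random TATSeries of length n, for property checks."""
    wet = rng.integers(1, 40, size=n)
    dry = rng.integers(1, 30, size=n)
    overall = wet + dry + rng.integers(0, 15, size=n)
    return TATSeries.from_records(wet, dry, overall)
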