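import warnings

import numpy as np
import pytest

from lonesense import simulate_cohort, strong_coupling_config


@pytest.fixture(scope="session")
def small_cohort():
    """A compact strong-coupling cohort in fast (summary) PPG mode, shared by
    modeling-level tests."""
    cfg = strong_coupling_config(n_participants=8, n_days=10, ppg_mode="summary",
                                 ppg_period_hours=4, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_assembly(small_cohort):
    from lonesense import assemble_features, build_streams

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        streams = build_streams(small_cohort)
        return assemble_features(streams, small_cohort.ema)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
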