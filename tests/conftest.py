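import numpy as np
import pandas as pd
import pytest

import metacogvbq as m


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """12 simulated subjects: sessions, truth table, summaries, kept trials."""
    rng = np.random.default_rng(2024)
    sessions, truth = m.simulate_cohort(12, m.SessionConfig(), rng)
    summaries, tables, reports = m.summarise_cohort(sessions, truth)
    return dict(sessions=sessions, truth=truth, summaries=summaries,
                tables=tables, reports=reports)


def make_null_summaries(n, rng):
    """Subject-level covariate table with no map effects attached."""
    return pd.DataFrame({
        "aroc": rng.normal(0.65, 0.06, n),
        "d_prime": rng.normal(1.5, 0.3, n),
        "mean_confidence": rng.normal(60.0, 12.0, n),
        "criterion": rng.normal(0.0, 0.2, n),
        "variance_bias_beta": rng.normal(-2.0, 1.5, n),
        "staircase_mean_signal_diff": rng.normal(-4.0, 3.0, n),
        "age": rng.normal(24.0, 5.0, n),
        "gender": (rng.random(n) < 0.6).astype(int),
        "tiv": rng.normal(1450.0, 110.0, n),
    })


@pytest.fixture(scope="session")
def null_summaries():
    return make_null_summaries
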