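import numpy as np
import pandas as pd
import pytest

from mdci.simulate import SimulationConfig, simulate_cohort


def make_events(rows):
    """Build an events frame from (subject_id, code, event_date, setting,
    position, admission_date, discharge_date) tuples; dates as ISO strings
    or None."""
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "code", "event_date", "setting", "position",
            "admission_date", "discharge_date",
        ],
    )
    for c in ("event_date", "admission_date", "discharge_date"):
        df[c] = pd.to_datetime(df[c])
    return df


def make_subjects(ids, index_date="2014-01-01", **extra):
    df = pd.DataFrame({"subject_id": list(ids)})
    df["index_date"] = pd.to_datetime(index_date)
    for k, v in extra.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured simulated cohort shared across tests."""
    cfg = SimulationConfig(n_subjects=500, n_conditions=15, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_survival():
    """Small censored dataset with a known binary covariate effect."""
    rng = np.random.default_rng(5)
    n = 40
    x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1.0 / (0.3 * np.exp(0.8 * x)))
    c = rng.exponential(5.0, n)
    time = np.minimum(t, c) + rng.uniform(0, 1e-3, n)  # break ties
    event = (t <= c).astype(int)
    X = np.column_stack([x, rng.binomial(1, 0.4, n), rng.binomial(1, 0.3, n)]).astype(float)
    return X, time, event
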