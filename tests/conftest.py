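"""Shared fixtures: small simulated studies reused across test modules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mlvarnet as m
from mlvarnet.data import ESMDataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


GAMMA3 = np.array([[0.30, 0.10, 0.00],
                   [0.00, 0.25, 0.10],
                   [0.05, 0.00, 0.20]])


def small_config(**overrides):
    """Three-variable study config small enough for per-test mixed fits."""
    base = dict(
        variables=["calm", "worry", "sad"],
        n_persons=40,
        n_days=4,
        n_beeps=8,
        gamma=GAMMA3,
        sigma=0.8 * np.eye(3),
        omega=[np.diag([0.09, 0.01, 0.0025, 0.0025])] * 3,
        stationary_means=np.array([4.0, 3.0, 3.0]),
        missing_rate=0.1,
        seed=42,
    )
    base.update(overrides)
    return m.SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim3():
    """One-period three-variable dataset plus its lagged design."""
    data = m.simulate_esm(small_config())
    design = m.build_lagged_design(data)
    return data, design


@pytest.fixture(scope="session")
def model3(sim3):
    """Stacked mixed-model fit of the three-variable study."""
    _data, design = sim3
    model = m.fit_mlvar(design)
    assert not model.errors
    return model


@pytest.fixture(scope="session")
def sim3_two_period():
    """Two-period dataset with therapy/neuroticism covariates (no true
    moderator effects) and its lagged design."""
    cfg = small_config(
        n_periods=2, n_days=3, seed=7,
        therapy_effect=np.zeros((3, 3)), neuro_effect=np.zeros((3, 3)),
    )
    data = m.simulate_esm(cfg)
    design = m.build_lagged_design(data)
    return data, design


@pytest.fixture(scope="session")
def neuro_fit(sim3_two_period):
    data, design = sim3_two_period
    ga = m.assign_neuroticism_groups(data.covariates()["neuroticism"], scale="neo-ffi")
    return ga, m.fit_neuroticism_model(design, ga)


def make_esm(rows, variables, scale=(1.0, 7.0)):
    """Build an ESMDataset from (person, day, beep, values...) tuples; a
    value of None is item-missing, an absent tuple a skipped beep."""
    recs = []
    for r in rows:
        person, day, beep = r[:3]
        vals = r[3:]
        recs.append((person, day, beep, 0, *vals))
    df = pd.DataFrame(recs, columns=["person", "day", "beep", "period", *variables])
    for v in variables:
        df[v] = pd.to_numeric(df[v], errors="coerce")
    return ESMDataset(df, list(variables), scale)
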