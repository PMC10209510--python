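import numpy as np
import pandas as pd
import pytest

from fingercode import GeneratorConfig, make_factorized_tuning, simulate_counts
from fingercode.datasets import SessionData, TrialDataset


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Two hands x five fingers, 3 sessions, small units — fast but full-grid."""
    return GeneratorConfig(
        n_sessions=3, n_units_per_session=40, trials_per_condition=16, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> TrialDataset:
    return simulate_counts(make_factorized_tuning(small_config), small_config)


@pytest.fixture(scope="session")
def contra_config() -> GeneratorConfig:
    """Right-hand-only task with No-Go (Dunnett baseline present)."""
    return GeneratorConfig.contralateral_delay(
        n_sessions=2, n_units_per_session=30, trials_per_condition=16, seed=12
    )


@pytest.fixture(scope="session")
def contra_dataset(contra_config) -> TrialDataset:
    return simulate_counts(make_factorized_tuning(contra_config), contra_config)


def make_session(rates, conditions, session_id="s00"):
    """Hand-built session from a rate matrix and condition labels."""
    rates = np.asarray(rates, dtype=float)
    hands, fingers = [], []
    for c in conditions:
        if c == "nogo":
            hands.append("right")
            fingers.append("nogo")
        else:
            h, f = c.split("_")
            hands.append(h)
            fingers.append(f)
    labels = pd.DataFrame({"hand": hands, "finger_type": fingers, "cue_variant": "x"})
    return SessionData(
        session_id, rates, labels, [f"u{i:03d}" for i in range(rates.shape[1])]
    )
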