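import numpy as np
import pandas as pd
import pytest

from codaqol import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_compositions(rng):
    """1000 random strictly positive compositions closed to 24 h."""
    from codaqol.coda import close

    raw = rng.lognormal(mean=1.0, sigma=0.8, size=(1000, 3))
    return close(raw, 24.0)


@pytest.fixture(scope="session")
def survey():
    """One clean simulated wave (no missingness) shared across tests."""
    cfg = simulate.GeneratorConfig(
        n=800, seed=42, missing_qol=0.0, missing_age=0.0, missing_sex=0.0
    )
    df, meta = simulate.generate_survey(cfg)
    return df, meta


@pytest.fixture
def raw_activity_table():
    """Small raw survey table with activity-level durations."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4],
            "year": [2021] * 4,
            "chores_hours": [0.5, 0.2, 0.3, 0.1],
            "indoor_play_hours": [1.0, 1.5, 1.2, 0.8],
            "outdoor_play_hours": [2.0, 1.0, 1.5, 1.1],
            "screen_learning_hours": [1.0, 0.5, 0.8, 1.2],
            "screen_entertainment_hours": [1.5, 2.0, 1.0, 1.6],
            "reading_hours": [0.5, 0.3, 0.4, 0.2],
            "crafts_hours": [1.0, 0.7, 0.6, 0.9],
            "nap_hours": [1.5, 1.0, 1.2, 1.4],
            "night_sleep_hours": [9.5, 10.0, 10.3, 9.8],
            "age_years": [3.0, 4.2, 2.8, 5.1],
            "sex": ["girl", "boy", "girl", "boy"],
            "qol_total": [80.0, 75.0, 90.0, 70.0],
        }
    )
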