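import numpy as np
import pandas as pd
import pytest

import vmrstats as v


@pytest.fixture(scope="session")
def small_config() -> v.SyntheticConfig:
    """A reduced plate: 3 strains x 2 stages x 2 bio reps, 2x6 wells, 2 trials."""
    return v.SyntheticConfig(
        rows=2,
        cols=6,
        stages=[3, 6],
        stage_mult={3: 0.6, 6: 1.0},
        stage_resp_mod={3: 0.3, 6: 1.0},
        n_bio_reps=2,
        n_trials=2,
        record_lead_s=40,
        phase_len_s=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return v.generate_plate_experiment(small_config)


@pytest.fixture(scope="session")
def small_windows(small_experiment) -> v.WindowedActivitySet:
    activity, _, schedule = small_experiment
    return v.extract_windows(activity, schedule)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_activity() -> v.ActivityMatrix:
    """Two animals, constant metadata, seconds 1..5."""
    rows = []
    for animal, base in (("a1", 0.2), ("a2", 0.4)):
        for s in range(1, 6):
            rows.append(
                {
                    "animal_id": animal,
                    "strain": "AB",
                    "stage_dpf": 6,
                    "well": "A1",
                    "bio_rep": "rep1",
                    "plate_id": "p1",
                    "second": s,
                    "activity": base,
                }
            )
    return v.ActivityMatrix(pd.DataFrame(rows))
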