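import numpy as np
import pandas as pd
import pytest

from scoretodoor.io import derive_from_frames
from scoretodoor.news import load_band_table
from scoretodoor.simulate import GeneratorConfig, simulate_study


@pytest.fixture(scope="session")
def bands():
    return load_band_table("news2_scale1")


@pytest.fixture(scope="session")
def study_mixed():
    """Small synthetic study with every archetype and some missing data."""
    cfg = GeneratorConfig(
        n_patients=300,
        seed=42,
        frac_ed_direct=0.3,
        frac_never_sustained=0.25,
        frac_over_cap=0.05,
        missingness_rate=0.03,
    )
    return cfg, simulate_study(cfg)


@pytest.fixture(scope="session")
def cohort_medium():
    """Included-only cohort large enough for stable model fits."""
    cfg = GeneratorConfig(
        n_patients=1500,
        seed=7,
        frac_ed_direct=0.0,
        frac_never_sustained=0.0,
        frac_over_cap=0.0,
        max_pre_obs=4,
    )
    tables = simulate_study(cfg)
    analysis = tables.covariates.merge(tables.outcomes, on="patient_id")
    cohort, ledger = derive_from_frames(tables.observations, tables.events, analysis)
    assert ledger.included == cfg.n_patients
    return cohort


def random_observation_frame(n: int, seed: int) -> pd.DataFrame:
    """Uniformly scattered (mostly abnormal) vitals for oracle checks."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "patient_id": [f"r{i}" for i in range(n)],
            "timestamp": pd.Timestamp("2020-06-01") + pd.to_timedelta(np.arange(n), unit="min"),
            "respiratory_rate": rng.integers(4, 41, n),
            "spo2": rng.integers(80, 101, n),
            "on_oxygen": rng.random(n) < 0.4,
            "systolic_bp": rng.integers(60, 261, n),
            "heart_rate": rng.integers(25, 181, n),
            "consciousness": rng.choice(
                ["alert", "new_confusion", "voice", "pain", "unresponsive"], n, p=[0.7, 0.1, 0.1, 0.05, 0.05]
            ),
            "temperature": np.round(rng.uniform(33.0, 41.0, n), 1),
        }
    )
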