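import numpy as np
import pandas as pd
import pytest

from traumameta.equating import load_reference_crosswalk
from traumameta.synth import StudyConfig, default_study_configs, generate_cohort


@pytest.fixture(scope="session")
def reference_crosswalk():
    return load_reference_crosswalk()


@pytest.fixture(scope="session")
def small_cohort():
    """Five-study cohort at reduced scale with missingness applied."""
    return generate_cohort(default_study_configs(scale=0.1), seed=11)


@pytest.fixture(scope="session")
def complete_cohort():
    """Single mid-size study, all follow-ups observed, with item data."""
    cfg = StudyConfig("demo", 600, "BDI", followup_rate=1.0)
    return generate_cohort([cfg], seed=5, apply_missing=False)


def make_persistence_frame(rng, n, beta_sev, sev_col="w1_dep_severity", sev_sd=8.0):
    """Wide-table-shaped frame of acute-onset participants where persistence
    follows a known logistic model in covariates and one acute severity."""
    df = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "study_id": rng.choice(["s1", "s2"], size=n),
            "age": np.clip(rng.normal(38, 13, n), 18, 90),
            "female": rng.random(n) < 0.4,
            "single": rng.random(n) < 0.5,
            "below_secondary": rng.random(n) < 0.2,
            "prior_trauma": rng.choice(
                ["none", "non-interpersonal", "interpersonal"], size=n
            ),
            "index_trauma": rng.choice(["MVA", "other_accident", "assault"], size=n),
        }
    )
    sev = np.clip(rng.normal(18, sev_sd, n), 0, 63)
    df[sev_col] = sev
    eta = -1.0 + 0.3 * df["female"] + beta_sev * (sev - sev.mean())
    persistent = rng.random(n) < 1 / (1 + np.exp(-eta))
    df["ptsd_trajectory"] = np.where(persistent, "Persistent", "Acute")
    df["mdd_trajectory"] = df["ptsd_trajectory"]
    for c in ("w1_ptsd_severity", "w1_ptsd_B", "w1_ptsd_C", "w1_ptsd_D"):
        if c != sev_col:
            df[c] = np.clip(rng.normal(30, 10, n), 0, 136)
    if "w1_dep_severity" not in df.columns:
        df["w1_dep_severity"] = np.clip(rng.normal(10, 6, n), 0, 63)
    return df, eta
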