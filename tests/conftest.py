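import numpy as np
import pandas as pd
import pytest

from elncut import GeneratorConfig, generate_cohort


def uniform_positivity_config(**overrides) -> GeneratorConfig:
    """Config with covariate-independent latent positivity so the true
    positive-node distribution has a closed form."""
    fields = dict(
        positivity_log_odds={},
        positivity_intercept=-0.6,
        seed=11,
    )
    fields.update(overrides)
    return GeneratorConfig(**fields)


def null_config(**overrides) -> GeneratorConfig:
    """No occult penalty, no break: survival independent of ELN count."""
    fields = dict(occult_log_hazard=0.0, break_eln=None, seed=29)
    fields.update(overrides)
    return GeneratorConfig(**fields)


def benefit_config(**overrides) -> GeneratorConfig:
    """Occult penalty plus a staging-adequacy break at 16 examined nodes."""
    fields = dict(occult_log_hazard=0.3, break_eln=16, seed=31)
    fields.update(overrides)
    return GeneratorConfig(**fields)


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    return generate_cohort(null_config(n_patients=20_000))


@pytest.fixture(scope="session")
def benefit_cohort() -> pd.DataFrame:
    return generate_cohort(benefit_config(n_patients=20_000))


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(GeneratorConfig(n_patients=2_000, seed=5))


def toy_cohort(eln, positive, time=None, event=None, **constant_cols) -> pd.DataFrame:
    """Hand-built minimal cohort table with constant covariates."""
    n = len(eln)
    base = {
        "patient_id": [f"T{i:03d}" for i in range(n)],
        "age": 60.0,
        "sex": "male",
        "histology": "adenocarcinoma",
        "t_stage": "T1",
        "tumor_location": "upper_lobe",
        "operation_type": "lobectomy",
    }
    base.update(constant_cols)
    df = pd.DataFrame(base)
    df["eln_count"] = np.asarray(eln, dtype=int)
    df["positive_count"] = np.asarray(positive, dtype=int)
    df["n_stage"] = np.where(df["positive_count"] == 0, "N0", "N1")
    df["time"] = 1.0 if time is None else np.asarray(time, dtype=float)
    df["event"] = 1 if event is None else np.asarray(event, dtype=int)
    return df
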