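import numpy as np
import pandas as pd
import pytest

from greencomp.cohort import SCHEMA_COLUMNS
from greencomp.synthetic import default_config, generate_cohort, with_exposure_slope


@pytest.fixture(scope="session")
def small_cohort():
    """Complete 500-row cohort with a real glucose effect (-50 mg/dl per
    NDVI unit); shared read-only across tests."""
    cfg = with_exposure_slope(
        default_config(n_participants=500, seed=11, missingness=False),
        "glucose", -50.0,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_config():
    return with_exposure_slope(
        default_config(n_participants=500, seed=11, missingness=False),
        "glucose", -50.0,
    )


def make_toy_cohort(n=40, seed=0, n_income_levels=1, binary_outcome=False,
                    beta_a=5.0, gamma_female=0.0, intercept=1.0):
    """Tiny cohort whose confounders take few distinct values (sex, and
    optionally income), for enumeration oracles.  Outcomes are generated
    noiselessly (gaussian) or from a logistic model (binary)."""
    rng = np.random.default_rng(seed)
    sex = rng.choice(["male", "female"], size=n)
    income = rng.choice(["ge55k", "30to55k", "le30k"][:n_income_levels], size=n)
    a = rng.uniform(-0.1, 0.4, size=n)
    female = (sex == "female").astype(float)
    inc1 = (income == "30to55k").astype(float)
    inc2 = (income == "le30k").astype(float)
    lp = intercept + (beta_a + gamma_female * female) * a \
        + 0.8 * female + 0.5 * inc1 + 1.1 * inc2
    frame = pd.DataFrame({c: np.nan for c in SCHEMA_COLUMNS}, index=range(n))
    frame["ndvi"] = a
    frame["sex"] = sex
    frame["income"] = income
    frame["race"] = "white"
    frame["ethnicity"] = "non_hispanic"
    frame["education"] = "hs_plus"
    frame["age"] = 50.0
    if binary_outcome:
        frame["mets"] = (rng.uniform(size=n) < 1 / (1 + np.exp(-(lp - 2.0)))).astype(float)
    else:
        frame["glucose"] = lp
    return frame
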