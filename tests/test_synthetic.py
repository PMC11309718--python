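import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.special import expit

import statsmodels.formula.api as smf

from greencomp.errors import ConfigurationError, SchemaError
from greencomp.synthetic import (
    AgeSpec,
    ConfounderSpec,
    ExposureModel,
    Interaction,
    OutcomeModel,
    SyntheticConfig,
    default_config,
    generate_cohort,
    inject_missingness,
    true_rd,
    with_exposure_slope,
)


def degenerate_confounders(sex_p=1.0):
    """All confounders fixed at their reference except sex."""
    probs = {
        "sex": {"male": sex_p, "female": 1.0 - sex_p},
        "income": {"ge55k": 1.0},
        "race": {"white": 1.0},
        "ethnicity": {"non_hispanic": 1.0},
        "education": {"hs_plus": 1.0},
    }
    return ConfounderSpec(probabilities=probs, age=AgeSpec(mean=50, sd=0))


class TestGenerateCohort:
    def test_determinism_byte_identical(self):
        cfg = default_config(n_participants=300, seed=42)
        a = generate_cohort(cfg).to_csv(index=False)
        b = generate_cohort(cfg).to_csv(index=False)
        assert a == b

    def test_different_seed_differs(self):
        a = generate_cohort(default_config(n_participants=300, seed=1))
        b = generate_cohort(default_config(n_participants=300, seed=2))
        assert not a["ndvi"].equals(b["ndvi"])

    def test_zero_noise_zero_slope_equals_linear_predictor(self):
        # glucose = 100 + 12*female exactly, independent of NDVI
        models = {
            "glucose": OutcomeModel("gaussian", 100.0, 0.0,
                                    {"sex": {"female": 12.0}}, None, 0.0),
        }
        cfg = SyntheticConfig(
            n_participants=200, seed=7,
            confounders=degenerate_confounders(sex_p=0.5),
            exposure_model=ExposureModel(0.2, {}, 0.05),
            outcome_models=models, mets_mode="logistic",
        )
        cfg = replace(cfg, outcome_models={**models, "mets": OutcomeModel(
            "binomial", -1.0, 0.0, {}, None, 0.0)})
        cohort = generate_cohort(cfg)
        expected = 100.0 + 12.0 * (cohort["sex"].astype(object) == "female")
        np.testing.assert_allclose(cohort["glucose"], expected)

    def test_exposure_within_physical_range(self):
        cfg = default_config(n_participants=2000, seed=3)
        cohort = generate_cohort(cfg)
        ndvi = cohort["ndvi"].dropna()
        assert ndvi.between(-1, 1).all()

    def test_age_within_bounds(self):
        cohort = generate_cohort(default_config(n_participants=1000, seed=3))
        age = cohort["age"].dropna()
        assert age.between(35, 80).all()

    def test_adjusted_slope_recovers_generative_truth(self):
        cfg = with_exposure_slope(
            default_config(n_participants=5000, seed=21, missingness=False),
            "glucose", -50.0)
        cohort = generate_cohort(cfg)
        fit = smf.ols(
            "glucose ~ ndvi + C(sex) + C(income) + C(race) + C(ethnicity)"
            " + age + C(education)", data=cohort).fit()
        assert abs(fit.params["ndvi"] - (-50.0)) < 3 * fit.bse["ndvi"]

    def test_confounding_is_visible(self):
        # omitting L must shift the crude exposure slope substantially
        cfg = with_exposure_slope(
            default_config(n_participants=5000, seed=22, missingness=False),
            "glucose", -34.0)
        cohort = generate_cohort(cfg)
        crude = smf.ols("glucose ~ ndvi", data=cohort).fit().params["ndvi"]
        assert abs(crude - (-34.0)) / 34.0 >= 0.20

    def test_invalid_probabilities_rejected(self):
        spec = degenerate_confounders()
        spec.probabilities["sex"] = {"male": 0.7, "female": 0.2}
        cfg = SyntheticConfig(
            n_participants=10, seed=0, confounders=spec,
            exposure_model=ExposureModel(), outcome_models={},
            mets_mode="logistic",
        )
        with pytest.raises(ConfigurationError, match="sum"):
            cfg.validate()

    def test_negative_sd_rejected(self):
        cfg = SyntheticConfig(
            n_participants=10, seed=0, confounders=degenerate_confounders(),
            exposure_model=ExposureModel(noise_sd=-0.1), outcome_models={},
            mets_mode="logistic",
        )
        with pytest.raises(ConfigurationError, match="SD"):
            cfg.validate()


class TestInjectMissingness:
    def test_zero_rates_identity(self, small_cohort):
        out = inject_missingness(small_cohort, {"glucose": 0.0}, seed=1)
        pd.testing.assert_frame_equal(out, small_cohort)

    def test_rate_one_blanks_field(self, small_cohort):
        out = inject_missingness(small_cohort, {"glucose": 1.0}, seed=1)
        assert out["glucose"].isna().all()
        assert out["sbp"].notna().all()

    def test_binomial_fraction(self):
        cohort = generate_cohort(default_config(n_participants=10_000, seed=5,
                                                missingness=False))
        out = inject_missingness(cohort, {"ndvi": 0.1}, seed=9)
        frac = out["ndvi"].isna().mean()
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 10_000)

    def test_rate_out_of_range(self, small_cohort):
        with pytest.raises(ConfigurationError):
            inject_missingness(small_cohort, {"ndvi": 1.5}, seed=1)

    def test_unknown_field(self, small_cohort):
        with pytest.raises(SchemaError):
            inject_missingness(small_cohort, {"nope": 0.1}, seed=1)


class TestTrueRD:
    def test_linear_closed_form(self):
        cfg = with_exposure_slope(default_config(seed=0), "glucose", 2.0)
        assert float(true_rd(cfg, "glucose", 0.5, 0.0)) == pytest.approx(1.0)

    def test_null_contrast(self):
        cfg = default_config(seed=0)
        for outcome in ("glucose", "mets"):
            assert float(true_rd(cfg, outcome, 0.3, 0.3)) == 0.0

    def test_interaction_stratum_slope(self):
        cfg = with_exposure_slope(default_config(seed=0), "glucose", -50.0,
                                  Interaction("sex", {"female": -30.0}))
        assert float(true_rd(cfg, "glucose", 0.4, 0.0, stratum="female")) \
            == pytest.approx(-80.0 * 0.4)
        assert float(true_rd(cfg, "glucose", 0.4, 0.0, stratum="male")) \
            == pytest.approx(-50.0 * 0.4)

    def test_logistic_enumeration(self):
        # intercept -1, slope 1, one binary confounder at P = 0.5 with
        # coefficient 1: RD(1 vs 0) = 0.5[s(0)-s(-1)] + 0.5[s(1)-s(0)]
        models = {"mets": OutcomeModel("binomial", -1.0, 1.0,
                                       {"sex": {"female": 1.0}}, None, 0.0)}
        cfg = SyntheticConfig(
            n_participants=10, seed=0,
            confounders=degenerate_confounders(sex_p=0.5),
            exposure_model=ExposureModel(), outcome_models=models,
            mets_mode="logistic",
        )
        expected = 0.5 * (expit(0) - expit(-1)) + 0.5 * (expit(1) - expit(0))
        result = true_rd(cfg, "mets", 1.0, 0.0, n_draws=200_000, mc_seed=3)
        assert result.mc_se > 0
        # the two confounder cells happen to give identical differences
        # (logistic symmetry), so the MC SE is ~0; keep a float-level floor
        assert abs(result.value - expected) < max(4 * result.mc_se, 1e-12)
        assert expected == pytest.approx(0.2311, abs=5e-4)

    def test_mc_se_shrinks_with_draws(self):
        cfg = default_config(seed=0, mets_mode="logistic")
        small = true_rd(cfg, "mets", 0.35, -0.08, n_draws=10_000, mc_seed=1)
        large = true_rd(cfg, "mets", 0.35, -0.08, n_draws=160_000, mc_seed=1)
        assert large.mc_se < small.mc_se / 2

    def test_derived_mets_rd_is_bounded(self):
        cfg = default_config(seed=0)
        result = true_rd(cfg, "mets", 0.35, -0.08, n_draws=20_000, mc_seed=2)
        assert -1.0 <= result.value <= 1.0
        assert result.mc_se > 0

    def test_unknown_outcome(self):
        with pytest.raises(SchemaError):
            true_rd(default_config(seed=0), "nope", 0.3, 0.0)
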