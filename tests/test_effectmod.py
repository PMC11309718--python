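import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greencomp.cohort import add_age_group, intervention_grid
from greencomp.effectmod import (
    StratumRDEstimate,
    bootstrap_stratum_rds,
    cochran_q,
    fit_interaction_model,
    heterogeneity_by_level,
    max_level_summary,
    partial_intervention_rd,
)
from greencomp.errors import (
    ConfigurationError,
    EmptyStratumError,
    HeterogeneityError,
    SingularDesignError,
)
from greencomp.gformula import OutcomeModelSpec, fit_outcome_model
from greencomp.synthetic import (
    Interaction,
    default_config,
    generate_cohort,
    with_exposure_slope,
)


def interaction_cohort(n=1200, seed=17, gamma=-40.0, modifier="sex",
                       stratum="female"):
    cfg = with_exposure_slope(
        default_config(n_participants=n, seed=seed, missingness=False),
        "glucose", -50.0, Interaction(modifier, {stratum: gamma}))
    return cfg, generate_cohort(cfg)


class TestInteractionModel:
    def test_binary_modifier_adds_one_product_column(self, small_cohort):
        base = fit_outcome_model(small_cohort, OutcomeModelSpec("glucose"))
        inter = fit_interaction_model(small_cohort, OutcomeModelSpec("glucose"), "sex")
        added = set(inter.param_names) - set(base.param_names)
        assert added == {"ndvi:C(sex)[T.female]"}

    def test_income_modifier_adds_two_product_columns(self, small_cohort):
        inter = fit_interaction_model(small_cohort, OutcomeModelSpec("glucose"), "income")
        products = [n for n in inter.param_names if n.startswith("ndvi:")]
        assert len(products) == 2

    def test_age_dichotomy_boundary(self):
        import pandas as pd

        frame = pd.DataFrame({"age": [64.9, 65.0]})
        out = add_age_group(frame)
        assert list(out["age65"].astype(object)) == ["lt65", "ge65"]

    def test_null_interaction_recovered(self):
        _, cohort = interaction_cohort(gamma=0.0, seed=23)
        fit = fit_interaction_model(cohort, OutcomeModelSpec("glucose"), "sex")
        j = fit.param_names.index("ndvi:C(sex)[T.female]")
        assert abs(fit.params[j]) < 3 * fit.bse[j]

    def test_constant_modifier_is_singular(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["ethnicity"] = "non_hispanic"
        with pytest.raises(SingularDesignError):
            fit_interaction_model(cohort, OutcomeModelSpec("glucose"), "ethnicity")

    def test_existing_interaction_rejected(self, small_cohort):
        spec = OutcomeModelSpec("glucose", interaction="sex")
        with pytest.raises(ConfigurationError):
            fit_interaction_model(small_cohort, spec, "ethnicity")


class TestPartialIntervention:
    def test_closed_form_stratum_slopes(self):
        _, cohort = interaction_cohort(gamma=-40.0)
        fit = fit_interaction_model(cohort, OutcomeModelSpec("glucose"), "sex")
        beta = fit.coefficients["ndvi"]
        gamma = fit.coefficients["ndvi:C(sex)[T.female]"]
        grid = intervention_grid(cohort["ndvi"])
        for level in (grid.levels[0], grid.levels[-1]):
            male = partial_intervention_rd(fit, cohort, "sex", "male",
                                           level, grid.reference)
            female = partial_intervention_rd(fit, cohort, "sex", "female",
                                             level, grid.reference)
            da = level - grid.reference
            assert male.rd == pytest.approx(beta * da, abs=1e-9)
            assert female.rd == pytest.approx((beta + gamma) * da, abs=1e-9)

    def test_zeroed_interaction_gives_identical_strata(self):
        _, cohort = interaction_cohort(gamma=-40.0)
        fit = fit_interaction_model(cohort, OutcomeModelSpec("glucose"), "sex")
        j = fit.param_names.index("ndvi:C(sex)[T.female]")
        fit.params[j] = 0.0  # construct a model with exactly no interaction
        grid = intervention_grid(cohort["ndvi"])
        for level in grid.levels:
            male = partial_intervention_rd(fit, cohort, "sex", "male",
                                           level, grid.reference)
            female = partial_intervention_rd(fit, cohort, "sex", "female",
                                             level, grid.reference)
            assert male.rd == pytest.approx(female.rd, abs=1e-9)

    def test_empty_stratum_raises(self):
        _, cohort = interaction_cohort()
        fit = fit_interaction_model(cohort, OutcomeModelSpec("glucose"), "sex")
        males = cohort[cohort["sex"] == "male"].reset_index(drop=True)
        with pytest.raises(EmptyStratumError, match="female"):
            partial_intervention_rd(fit, males, "sex", "female", 0.3, 0.0)

    def test_model_without_interaction_rejected(self, small_cohort):
        fit = fit_outcome_model(small_cohort, OutcomeModelSpec("glucose"))
        with pytest.raises(ConfigurationError):
            partial_intervention_rd(fit, small_cohort, "sex", "female", 0.3, 0.0)


class TestBootstrapStratumRDs:
    def test_structure_and_se(self):
        _, cohort = interaction_cohort(n=800)
        grid = intervention_grid(cohort["ndvi"])
        ests = bootstrap_stratum_rds(cohort, OutcomeModelSpec("glucose"),
                                     "sex", grid, n_boot=80, seed=5)
        assert len(ests) == 2 * 10  # strata x levels
        for e in ests:
            assert e.se > 0
            assert e.ci_low <= e.ci_high

    def test_determinism(self):
        _, cohort = interaction_cohort(n=600)
        grid = intervention_grid(cohort["ndvi"])
        spec = OutcomeModelSpec("glucose")
        a = bootstrap_stratum_rds(cohort, spec, "sex", grid, n_boot=40, seed=8)
        b = bootstrap_stratum_rds(cohort, spec, "sex", grid, n_boot=40, seed=8)
        assert [(x.rd, x.se, x.ci_low) for x in a] == [(x.rd, x.se, x.ci_low) for x in b]


class TestCochranQ:
    def est(self, stratum, rd, se, level=0.3):
        return StratumRDEstimate(outcome="glucose", modifier="sex",
                                 stratum=stratum, level=level, reference=0.0,
                                 rd=rd, se=se)

    def test_hand_worked_example(self):
        res = cochran_q([self.est("male", 1.0, 0.5), self.est("female", 3.0, 0.5)])
        assert res.Q == pytest.approx(8.0, abs=1e-12)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.004678, abs=5e-6)
        assert res.significant

    def test_identical_strata_give_zero(self):
        res = cochran_q([self.est("male", 2.0, 0.4), self.est("female", 2.0, 0.4)])
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_single_stratum_errors(self):
        with pytest.raises(HeterogeneityError):
            cochran_q([self.est("male", 1.0, 0.5)])

    def test_zero_se_errors(self):
        with pytest.raises(HeterogeneityError, match="degenerate"):
            cochran_q([self.est("male", 1.0, 0.0), self.est("female", 2.0, 0.5)])

    def test_se_cap_excludes_stratum(self):
        ests = [self.est("a", 1.0, 0.5), self.est("b", 3.0, 0.5),
                self.est("c", 10.0, 1e6)]
        res = cochran_q(ests, se_cap=100.0)
        assert res.excluded_strata == ("c",)
        assert res.n_strata == 2
        assert res.Q == pytest.approx(8.0, abs=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-50, 50, allow_nan=False),
           st.permutations(["male", "female", "x"]))
    def test_shift_and_order_invariance(self, shift, order):
        base = {"male": (1.0, 0.5), "female": (3.0, 0.8), "x": (2.0, 0.3)}
        plain = cochran_q([self.est(s, base[s][0], base[s][1]) for s in base])
        moved = cochran_q([self.est(s, base[s][0] + shift, base[s][1])
                           for s in order])
        assert moved.Q == pytest.approx(plain.Q, rel=1e-9, abs=1e-9)

    def test_per_level_grouping_and_max_summary(self):
        ests = [self.est("male", 1.0, 0.5, level=0.1),
                self.est("female", 1.2, 0.5, level=0.1),
                self.est("male", 1.0, 0.5, level=0.4),
                self.est("female", 3.0, 0.5, level=0.4)]
        results = heterogeneity_by_level(ests)
        assert len(results) == 2
        top = max_level_summary(results)
        assert top.level == 0.4
        assert top.Q == pytest.approx(8.0, abs=1e-9)


class TestPowerMonotonicity:
    def test_mean_q_increases_with_gamma(self):
        """Stronger generative interactions must produce larger Q on
        average (3-point gamma ladder, fixed seeds)."""
        mean_q = []
        for gamma in (0.0, -40.0, -120.0):
            qs = []
            for rep in range(6):
                _, cohort = interaction_cohort(n=700, seed=100 + rep, gamma=gamma)
                grid = intervention_grid(cohort["ndvi"])
                ests = bootstrap_stratum_rds(cohort, OutcomeModelSpec("glucose"),
                                             "sex", grid, n_boot=120,
                                             seed=200 + rep)
                qs.append(max_level_summary(heterogeneity_by_level(ests)).Q)
            mean_q.append(np.mean(qs))
        assert mean_q[0] < mean_q[1] < mean_q[2]
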