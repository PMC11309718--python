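"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the g-computation analysis assumes:
a continuous residential greenness exposure (NDVI) confounded by
demographics, nine continuous metabolic biomarkers generated from linear
models with known exposure slopes, an optional exposure-by-modifier
interaction, binary metabolic syndrome (derived from the simulated
biomarker components by default), and seeded MCAR missingness.

Because the generating coefficients are known, :func:`true_rd` returns the
exact causal risk difference for any simulated intervention, which the
estimation modules are tested against.

Ages are centered at 55 years inside every linear predictor, so intercepts
are interpretable as the expected value for a 55-year-old in all reference
categories at NDVI = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .cohort import (
    AGE_GROUP_COLUMN,
    AGE_GROUP_LEVELS,
    CATEGORICAL_CONFOUNDERS,
    CONTINUOUS_OUTCOMES,
    EXPOSURE,
    SCHEMA_COLUMNS,
    add_age_group,
    classify_metabolic_syndrome_frame,
)
from .errors import ConfigurationError, SchemaError

AGE_CENTER = 55.0

# Coefficient containers use nested dicts: categorical confounders map
# category -> additive offset (reference category implicitly 0); the key
# "age" maps to a per-year slope applied to (age - 55).
Coefficients = dict[str, "dict[str, float] | float"]


@dataclass(frozen=True)
class AgeSpec:
    mean: float = 57.0
    sd: float = 12.0
    lower: float = 35.0
    upper: float = 80.0


@dataclass(frozen=True)
class ConfounderSpec:
    """Marginal distributions of the confounders.

    Categories are sampled independently by default;
    ``income_given_hispanic`` optionally replaces the marginal income
    probabilities for Hispanic participants (an ethnicity-income
    dependence hook)."""

    probabilities: dict[str, dict[str, float]] = field(default_factory=dict)
    age: AgeSpec = field(default_factory=AgeSpec)
    income_given_hispanic: dict[str, float] | None = None

    def validate(self) -> None:
        for col, levels in CATEGORICAL_CONFOUNDERS.items():
            probs = self.probabilities.get(col)
            if probs is None:
                raise ConfigurationError(f"missing category probabilities for {col!r}")
            unknown = set(probs) - set(levels)
            if unknown:
                raise ConfigurationError(f"unknown categories for {col!r}: {sorted(unknown)}")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"category probabilities for {col!r} sum to {total!r}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"negative probability for {col!r}")
        if self.income_given_hispanic is not None:
            total = sum(self.income_given_hispanic.values())
            if abs(total - 1.0) > 1e-12:
                raise ConfigurationError("income_given_hispanic must sum to 1")
        if self.age.sd < 0:
            raise ConfigurationError("age SD must be >= 0")
        if not (self.age.lower < self.age.upper):
            raise ConfigurationError("age bounds must satisfy lower < upper")


@dataclass(frozen=True)
class ExposureModel:
    """NDVI = intercept + sum of confounder offsets + truncated Gaussian
    noise, truncated to the physical range [-1, 1]."""

    intercept: float = 0.17
    coefficients: Coefficients = field(default_factory=dict)
    noise_sd: float = 0.06

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("exposure noise SD must be >= 0")


@dataclass(frozen=True)
class Interaction:
    """Exposure-by-modifier interaction: per non-reference stratum, the
    additional exposure slope gamma (outcome units per NDVI unit)."""

    modifier: str
    gammas: dict[str, float]


@dataclass(frozen=True)
class OutcomeModel:
    family: str  # "gaussian" | "binomial"
    intercept: float
    exposure_slope: float  # beta_A: outcome units per NDVI unit
    coefficients: Coefficients = field(default_factory=dict)
    interaction: Interaction | None = None
    noise_sd: float = 0.0

    def validate(self, name: str) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ConfigurationError(f"{name}: unknown family {self.family!r}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"{name}: noise SD must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    n_participants: int
    seed: int
    confounders: ConfounderSpec
    exposure_model: ExposureModel
    outcome_models: dict[str, OutcomeModel]
    missingness_rates: dict[str, float] = field(default_factory=dict)
    # "derived": classify metabolic syndrome from the simulated biomarker
    # components (mirrors how the indicator is constructed from measured
    # biomarkers); "logistic": draw it from the outcome model named "mets".
    mets_mode: str = "derived"

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        self.confounders.validate()
        self.exposure_model.validate()
        for name, model in self.outcome_models.items():
            model.validate(name)
        for fld, rate in self.missingness_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ConfigurationError(f"missingness rate for {fld!r} outside [0, 1]")
        if self.mets_mode not in ("derived", "logistic"):
            raise ConfigurationError(f"unknown mets_mode {self.mets_mode!r}")
        if self.mets_mode == "logistic" and "mets" not in self.outcome_models:
            raise ConfigurationError("mets_mode='logistic' requires an outcome model 'mets'")


# ---------------------------------------------------------------------------
# Defaults: a cohort resembling the study population the pipeline targets —
# n in the hundreds, NDVI centered ~0.17 with SD ~0.07, visible confounding
# (socioeconomic covariates push NDVI down and adverse biomarkers up).
# Confounder-exposure strengths are not identified by any published table
# and are deliberate choices; see the methods note.
# ---------------------------------------------------------------------------

DEFAULT_PROBABILITIES = {
    "sex": {"male": 0.44, "female": 0.56},
    "income": {"ge55k": 0.492, "30to55k": 0.26, "le30k": 0.248},
    "race": {"white": 0.708, "black": 0.05, "asian": 0.10, "nhpi": 0.01,
             "aian": 0.05, "other": 0.082},
    "ethnicity": {"non_hispanic": 0.58, "hispanic": 0.42},
    "education": {"hs_plus": 0.905, "lt_hs": 0.095},
}

DEFAULT_EXPOSURE = ExposureModel(
    intercept=0.17,
    coefficients={
        "income": {"30to55k": -0.03, "le30k": -0.06},
        "ethnicity": {"hispanic": -0.05},
        "education": {"lt_hs": -0.03},
        "sex": {"female": 0.01},
        "age": 0.001,
    },
    noise_sd=0.06,
)


def _default_outcome(intercept, slope, sd, coefficients=None):
    return OutcomeModel("gaussian", intercept, slope, dict(coefficients or {}), None, sd)


DEFAULT_OUTCOME_MODELS: dict[str, OutcomeModel] = {
    # intercepts ~ reference-category means; exposure slopes chosen so the
    # max-vs-min contrast (about 0.44 NDVI units) lands on the same order
    # as the analysis this emulates.
    "glucose": _default_outcome(100.0, -34.0, 25.0, {
        "income": {"30to55k": 4.0, "le30k": 8.0},
        "ethnicity": {"hispanic": 6.0},
        "education": {"lt_hs": 5.0},
        "sex": {"female": -4.0},
        "age": 0.4,
    }),
    "total_cholesterol": _default_outcome(198.0, 30.0, 35.0, {
        "income": {"30to55k": 2.0, "le30k": 4.0},
        "sex": {"female": 5.0},
        "age": 0.5,
    }),
    "ldl": _default_outcome(115.0, 26.0, 30.0, {
        "income": {"30to55k": 2.0, "le30k": 4.0},
        "age": 0.3,
    }),
    "hdl": _default_outcome(52.0, -10.0, 14.0, {
        "sex": {"female": 9.0},
        "ethnicity": {"hispanic": -3.0},
    }),
    "triglycerides": _default_outcome(115.0, 79.0, 60.0, {
        "income": {"30to55k": 6.0, "le30k": 12.0},
        "ethnicity": {"hispanic": 15.0},
        "sex": {"female": -10.0},
        "age": 0.5,
    }),
    "hba1c": _default_outcome(5.6, -0.9, 0.55, {
        "ethnicity": {"hispanic": 0.2},
        "income": {"30to55k": 0.05, "le30k": 0.12},
        "age": 0.01,
    }),
    "sbp": _default_outcome(120.0, -5.0, 13.0, {
        "sex": {"female": -4.0},
        "age": 0.45,
    }),
    "dbp": _default_outcome(75.0, 1.0, 9.0, {
        "sex": {"female": -2.0},
        "age": 0.1,
    }),
    "waist": _default_outcome(96.0, 1.0, 13.0, {
        "sex": {"female": -10.0},
        "income": {"30to55k": 1.0, "le30k": 2.0},
        "age": 0.1,
    }),
    # Used only when mets_mode="logistic".
    "mets": OutcomeModel("binomial", -1.55, -0.8, {
        "income": {"30to55k": 0.2, "le30k": 0.4},
        "ethnicity": {"hispanic": 0.3},
        "age": 0.03,
    }, None, 0.0),
}

# Small uniform MCAR rates across exposure, confounders and biomarkers,
# chosen so listwise retention on the full schema sits near 92%.
DEFAULT_MISSINGNESS = {
    f: 0.005
    for f in (EXPOSURE,) + tuple(CATEGORICAL_CONFOUNDERS) + ("age",) + CONTINUOUS_OUTCOMES
}


def default_config(n_participants: int = 602, seed: int = 0, *,
                   missingness: bool = True, mets_mode: str = "derived") -> SyntheticConfig:
    """Study-scale default configuration (n = 602 recruited)."""
    return SyntheticConfig(
        n_participants=n_participants,
        seed=seed,
        confounders=ConfounderSpec(probabilities={k: dict(v) for k, v in DEFAULT_PROBABILITIES.items()}),
        exposure_model=DEFAULT_EXPOSURE,
        outcome_models=dict(DEFAULT_OUTCOME_MODELS),
        missingness_rates=dict(DEFAULT_MISSINGNESS) if missingness else {},
        mets_mode=mets_mode,
    )


def with_exposure_slope(config: SyntheticConfig, outcome: str, slope: float,
                        interaction: Interaction | None = None) -> SyntheticConfig:
    """Convenience: a copy of ``config`` with one outcome's exposure slope
    (and optionally its interaction) replaced."""
    if outcome not in config.outcome_models:
        raise SchemaError(f"unknown outcome {outcome!r}")
    models = dict(config.outcome_models)
    models[outcome] = replace(models[outcome], exposure_slope=slope, interaction=interaction)
    return replace(config, outcome_models=models)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _linear_predictor(frame: pd.DataFrame, intercept: float, coefficients: Coefficients) -> np.ndarray:
    lp = np.full(len(frame), float(intercept))
    for col, coef in coefficients.items():
        if col == "age":
            lp += float(coef) * (frame["age"].to_numpy(dtype=float) - AGE_CENTER)
        else:
            if col not in frame.columns:
                raise SchemaError(f"coefficient references unknown column {col!r}")
            vals = frame[col].astype(object).to_numpy()
            for category, offset in coef.items():
                lp += float(offset) * (vals == category)
    return lp


def _interaction_slopes(frame: pd.DataFrame, interaction: Interaction | None) -> np.ndarray:
    """Per-row additional exposure slope from the interaction (0 without one)."""
    if interaction is None:
        return np.zeros(len(frame))
    col = interaction.modifier
    work = frame
    if col == AGE_GROUP_COLUMN and col not in frame.columns:
        work = add_age_group(frame)
    if col not in work.columns:
        raise SchemaError(f"interaction modifier {col!r} not a cohort column")
    vals = work[col].astype(object).to_numpy()
    extra = np.zeros(len(work))
    for category, gamma in interaction.gammas.items():
        extra += float(gamma) * (vals == category)
    return extra


def _sample_confounders(spec: ConfounderSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    out = {}
    for col, levels in CATEGORICAL_CONFOUNDERS.items():
        if col == "income" and spec.income_given_hispanic is not None:
            continue
        probs = spec.probabilities[col]
        cats = list(levels)
        p = np.array([probs.get(c, 0.0) for c in cats])
        out[col] = pd.Categorical(rng.choice(cats, size=n, p=p), categories=cats)
    if spec.income_given_hispanic is not None:
        cats = list(CATEGORICAL_CONFOUNDERS["income"])
        marg = np.array([spec.probabilities["income"].get(c, 0.0) for c in cats])
        cond = np.array([spec.income_given_hispanic.get(c, 0.0) for c in cats])
        hispanic = np.asarray(out["ethnicity"]) == "hispanic"
        draw = np.empty(n, dtype=object)
        u_marg = rng.choice(cats, size=n, p=marg)
        u_cond = rng.choice(cats, size=n, p=cond)
        draw[~hispanic] = u_marg[~hispanic]
        draw[hispanic] = u_cond[hispanic]
        out["income"] = pd.Categorical(draw, categories=cats)
    a = spec.age
    if a.sd == 0:
        age = np.full(n, float(np.clip(a.mean, a.lower, a.upper)))
    else:
        lo, hi = (a.lower - a.mean) / a.sd, (a.upper - a.mean) / a.sd
        age = truncnorm.rvs(lo, hi, loc=a.mean, scale=a.sd, size=n, random_state=rng)
    out["age"] = age
    return pd.DataFrame(out)


def _sample_exposure(frame: pd.DataFrame, model: ExposureModel, rng: np.random.Generator) -> np.ndarray:
    lp = _linear_predictor(frame, model.intercept, model.coefficients)
    if model.noise_sd == 0:
        return np.clip(lp, -1.0, 1.0)
    lo = (-1.0 - lp) / model.noise_sd
    hi = (1.0 - lp) / model.noise_sd
    return truncnorm.rvs(lo, hi, loc=lp, scale=model.noise_sd, random_state=rng)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a cohort table following the fixed schema.

    Fully reproducible: the seed is expanded into independent child streams
    for confounders, exposure, outcome noise, and missingness, so e.g.
    changing a missingness rate does not perturb the generated biomarkers.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_conf, rng_expo, rng_out, rng_miss = (np.random.default_rng(s) for s in ss.spawn(4))

    n = config.n_participants
    frame = _sample_confounders(config.confounders, n, rng_conf)
    frame[EXPOSURE] = _sample_exposure(frame, config.exposure_model, rng_expo)

    a = frame[EXPOSURE].to_numpy()
    for name in CONTINUOUS_OUTCOMES:
        model = config.outcome_models.get(name)
        if model is None:
            frame[name] = np.nan
            continue
        slope = model.exposure_slope + _interaction_slopes(frame, model.interaction)
        mu = _linear_predictor(frame, model.intercept, model.coefficients) + slope * a
        noise = rng_out.normal(0.0, model.noise_sd, size=n) if model.noise_sd > 0 else 0.0
        frame[name] = mu + noise

    if config.mets_mode == "derived":
        needed = ("waist", "triglycerides", "hdl", "sbp", "dbp", "glucose")
        absent = [c for c in needed if config.outcome_models.get(c) is None]
        if absent:
            raise ConfigurationError(
                f"mets_mode='derived' requires component models for {absent}"
            )
        frame["mets"] = classify_metabolic_syndrome_frame(frame)["mets"]
    else:
        model = config.outcome_models["mets"]
        slope = model.exposure_slope + _interaction_slopes(frame, model.interaction)
        p = _expit(_linear_predictor(frame, model.intercept, model.coefficients) + slope * a)
        frame["mets"] = (rng_out.uniform(size=n) < p).astype(float)

    frame = frame[list(SCHEMA_COLUMNS)]
    if config.missingness_rates:
        frame = inject_missingness(frame, config.missingness_rates,
                                   int(ss.spawn(1)[0].generate_state(1)[0] % 2**31))
    return frame


def inject_missingness(cohort: pd.DataFrame, rates: dict[str, float], seed: int) -> pd.DataFrame:
    """Independently blank each field with its MCAR rate; seeded."""
    for fld, rate in rates.items():
        if fld not in cohort.columns:
            raise SchemaError(f"unknown field {fld!r} in missingness rates")
        if not (0.0 <= rate <= 1.0):
            raise ConfigurationError(f"missingness rate for {fld!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    # iterate in column order for a stable draw sequence
    for fld in cohort.columns:
        rate = rates.get(fld, 0.0)
        if rate == 0.0:
            continue
        mask = rng.uniform(size=len(out)) < rate
        if isinstance(out[fld].dtype, pd.CategoricalDtype):
            col = out[fld].copy()
            col[mask] = np.nan
            out[fld] = col
        else:
            out[fld] = out[fld].astype(float).mask(mask)
    return out


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueRD:
    """Ground-truth causal risk difference.  ``mc_se`` is 0 for exact
    (closed-form) values and the Monte-Carlo standard error otherwise."""

    value: float
    mc_se: float = 0.0
    n_draws: int = 0

    def __float__(self):
        return float(self.value)


def _stratum_mask(frame: pd.DataFrame, modifier: str, stratum) -> np.ndarray:
    work = frame
    if modifier == AGE_GROUP_COLUMN and modifier not in frame.columns:
        work = add_age_group(frame)
    if modifier not in work.columns:
        raise SchemaError(f"unknown modifier {modifier!r}")
    if modifier == AGE_GROUP_COLUMN and stratum not in AGE_GROUP_LEVELS:
        raise SchemaError(f"unknown age stratum {stratum!r}")
    return work[modifier].astype(object).to_numpy() == stratum


def true_rd(config: SyntheticConfig, outcome: str, level: float, ref: float,
            stratum=None, *, n_draws: int = 100_000, mc_seed: int = 0) -> TrueRD:
    """Exact (continuous) or Monte-Carlo (binary) ground-truth RD for the
    intervention ``level`` vs ``ref``.

    ``stratum`` is a modifier category (e.g. ``"female"`` or ``"ge65"``)
    when the outcome model carries an interaction; the returned contrast is
    then the stratum-specific RD.  For continuous outcomes with no
    interaction the result is exactly ``beta_A * (level - ref)``.
    """
    if outcome == "mets" and config.mets_mode == "derived":
        return _true_rd_mets_derived(config, level, ref, stratum, n_draws, mc_seed)
    model = config.outcome_models.get(outcome)
    if model is None:
        raise SchemaError(f"unknown outcome {outcome!r}")
    if level == ref:
        return TrueRD(0.0)

    if model.family == "gaussian":
        slope = model.exposure_slope
        inter = model.interaction
        if inter is not None:
            if stratum is not None:
                slope += inter.gammas.get(stratum, 0.0)
            else:
                # population RD averages the stratum slopes over prevalence
                probs = _modifier_prevalence(config, inter.modifier, n_draws, mc_seed)
                slope += sum(p * g for s, g in inter.gammas.items()
                             for cat, p in probs.items() if cat == s)
        return TrueRD(slope * (level - ref))

    # binomial: standardize over the confounder distribution by simulation
    rng = np.random.default_rng(mc_seed)
    frame = _sample_confounders(config.confounders, n_draws, rng)
    if stratum is not None and model.interaction is not None:
        keep = _stratum_mask(frame, model.interaction.modifier, stratum)
        frame = frame.loc[keep].reset_index(drop=True)
    slope = model.exposure_slope + _interaction_slopes(frame, model.interaction)
    base = _linear_predictor(frame, model.intercept, model.coefficients)
    diff = _expit(base + slope * level) - _expit(base + slope * ref)
    return TrueRD(float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(len(diff))), len(diff))


def _modifier_prevalence(config, modifier, n_draws, seed):
    if modifier in CATEGORICAL_CONFOUNDERS:
        return dict(config.confounders.probabilities[modifier])
    # age dichotomy: prevalence from the truncated-normal age model
    rng = np.random.default_rng(seed)
    frame = _sample_confounders(config.confounders, max(n_draws, 10_000), rng)
    ge = float((frame["age"] >= 65.0).mean())
    return {"ge65": ge, "lt65": 1.0 - ge}


def _true_rd_mets_derived(config, level, ref, stratum, n_draws, mc_seed):
    """Metabolic syndrome under mets_mode='derived': simulate the component
    biomarkers at both exposure levels with shared noise and classify."""
    if level == ref:
        return TrueRD(0.0)
    ss = np.random.SeedSequence(mc_seed)
    rng_conf, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    frame = _sample_confounders(config.confounders, n_draws, rng_conf)

    components = ("waist", "triglycerides", "hdl", "sbp", "dbp", "glucose")
    interactions = [config.outcome_models[c].interaction for c in components
                    if config.outcome_models.get(c) is not None]
    if stratum is not None:
        mods = {i.modifier for i in interactions if i is not None}
        if not mods:
            raise ConfigurationError(
                "stratum-specific mets RD requires an interaction on a component model"
            )
        keep = _stratum_mask(frame, next(iter(mods)), stratum)
        frame = frame.loc[keep].reset_index(drop=True)

    def biomarkers_at(a_value):
        out = frame.copy()
        for name in components:
            model = config.outcome_models[name]
            slope = model.exposure_slope + _interaction_slopes(frame, model.interaction)
            mu = _linear_predictor(frame, model.intercept, model.coefficients) + slope * a_value
            out[name] = mu + noise[name]
        return out

    noise = {
        name: (rng_noise.normal(0.0, config.outcome_models[name].noise_sd, size=len(frame))
               if config.outcome_models[name].noise_sd > 0 else 0.0)
        for name in components
    }
    m1 = classify_metabolic_syndrome_frame(biomarkers_at(level))["mets"].to_numpy()
    m0 = classify_metabolic_syndrome_frame(biomarkers_at(ref))["mets"].to_numpy()
    diff = m1 - m0
    return TrueRD(float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(len(diff))), len(diff))


# ---------------------------------------------------------------------------
# Config file I/O (YAML)
# ---------------------------------------------------------------------------


def config_from_yaml(path) -> SyntheticConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SyntheticConfig:
    conf = raw.get("confounders", {})
    age = AgeSpec(**conf.get("age", {}))
    spec = ConfounderSpec(
        probabilities=conf.get("probabilities", {k: dict(v) for k, v in DEFAULT_PROBABILITIES.items()}),
        age=age,
        income_given_hispanic=conf.get("income_given_hispanic"),
    )
    expo = raw.get("exposure_model")
    exposure = ExposureModel(**expo) if expo else DEFAULT_EXPOSURE
    models = {}
    for name, m in raw.get("outcome_models", {}).items():
        inter = m.pop("interaction", None)
        if inter is not None:
            inter = Interaction(modifier=inter["modifier"], gammas=dict(inter["gammas"]))
        models[name] = OutcomeModel(interaction=inter, **m)
    if not models:
        models = dict(DEFAULT_OUTCOME_MODELS)
    return SyntheticConfig(
        n_participants=int(raw["n_participants"]),
        seed=int(raw.get("seed", 0)),
        confounders=spec,
        exposure_model=exposure,
        outcome_models=models,
        missingness_rates=dict(raw.get("missingness_rates", {})),
        mets_mode=raw.get("mets_mode", "derived"),
    )
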