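"""Cohort schema, complete-case filtering, metabolic syndrome classification,
and the intervention grid.

The cohort is a plain :class:`pandas.DataFrame` with a fixed, documented
column set: one continuous residential greenness exposure (NDVI, unitless,
physically constrained to [-1, 1]), six confounders, nine continuous
metabolic biomarkers, and one binary metabolic syndrome indicator.

The intervention grid is the set of exposure levels at which counterfactual
outcomes are simulated: the empirical minimum of NDVI is the reference
("unexposed") level, and the ten intervention levels are the nine deciles
(p10..p90) plus the empirical maximum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ClassificationError,
    DegenerateDistributionError,
    SchemaError,
)

# ---------------------------------------------------------------------------
# Fixed schema.  The first category of each confounder is the dummy-coding
# reference (the largest group in the source population: male, income
# >= $55k, White, non-Hispanic, high school or more).
# ---------------------------------------------------------------------------

EXPOSURE = "ndvi"

SEX_LEVELS = ("male", "female")
INCOME_LEVELS = ("ge55k", "30to55k", "le30k")
RACE_LEVELS = ("white", "black", "asian", "nhpi", "aian", "other")
ETHNICITY_LEVELS = ("non_hispanic", "hispanic")
EDUCATION_LEVELS = ("hs_plus", "lt_hs")
AGE_GROUP_LEVELS = ("lt65", "ge65")

CATEGORICAL_CONFOUNDERS: dict[str, tuple[str, ...]] = {
    "sex": SEX_LEVELS,
    "income": INCOME_LEVELS,
    "race": RACE_LEVELS,
    "ethnicity": ETHNICITY_LEVELS,
    "education": EDUCATION_LEVELS,
}

CONFOUNDERS = ("sex", "income", "race", "ethnicity", "age", "education")

CONTINUOUS_OUTCOMES = (
    "glucose",            # fasting plasma glucose, mg/dl
    "total_cholesterol",  # mg/dl
    "ldl",                # LDL cholesterol, mg/dl
    "hdl",                # HDL cholesterol, mg/dl
    "triglycerides",      # mg/dl
    "hba1c",              # hemoglobin A1c, %
    "sbp",                # systolic blood pressure, mmHg
    "dbp",                # diastolic blood pressure, mmHg
    "waist",              # waist circumference, cm
)
BINARY_OUTCOMES = ("mets",)  # metabolic syndrome, 0/1
OUTCOMES = CONTINUOUS_OUTCOMES + BINARY_OUTCOMES

SCHEMA_COLUMNS = (EXPOSURE,) + CONFOUNDERS + OUTCOMES

# Modifier name -> cohort column used for stratification.  "age65" is the
# derived dichotomy at 65 years (>= 65 vs < 65).
MODIFIERS = ("sex", "ethnicity", "income", "age65")
AGE_GROUP_COLUMN = "age65"
AGE_CUTOFF = 65.0


def outcome_family(outcome: str) -> str:
    """Return the GLM family name for an outcome column."""
    if outcome in CONTINUOUS_OUTCOMES:
        return "gaussian"
    if outcome in BINARY_OUTCOMES:
        return "binomial"
    raise SchemaError(f"unknown outcome {outcome!r}")


def add_age_group(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the ``age65`` dichotomy column added.

    A participant aged exactly 65.0 falls in the ``ge65`` stratum; 64.9
    falls in ``lt65``.  Missing ages stay missing.
    """
    out = cohort.copy()
    age = pd.to_numeric(out["age"], errors="coerce")
    grp = np.where(age >= AGE_CUTOFF, "ge65", "lt65")
    cat = pd.Categorical(grp, categories=list(AGE_GROUP_LEVELS))
    cat = pd.Series(cat, index=out.index).where(age.notna())
    out[AGE_GROUP_COLUMN] = pd.Categorical(cat, categories=list(AGE_GROUP_LEVELS))
    return out


def validate_schema(cohort: pd.DataFrame, required: tuple[str, ...] = SCHEMA_COLUMNS) -> None:
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort is missing schema column(s): {missing}")


# ---------------------------------------------------------------------------
# Complete-case filtering
# ---------------------------------------------------------------------------


@dataclass
class CompleteCaseReport:
    """Tally of listwise complete-case exclusion.

    ``retention_pct`` is 100 * n_retained / n_input, the quantity analyses
    report as "x% retention".
    """

    n_input: int
    n_retained: int
    retention_pct: float
    missing_by_field: dict[str, int] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "retention_pct": self.retention_pct,
                "missing_by_field": self.missing_by_field,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def complete_case_filter(
    cohort: pd.DataFrame,
    required_fields: tuple[str, ...] | list[str] | None = None,
) -> tuple[pd.DataFrame, CompleteCaseReport]:
    """Listwise-delete rows missing any required field.

    Parameters
    ----------
    cohort : DataFrame following the cohort schema.
    required_fields : fields that must be non-missing; defaults to the full
        schema (exposure + confounders + all ten outcomes), matching a
        single analytic sample shared by every outcome model.

    Returns the retained rows (original row order, index reset) and a
    :class:`CompleteCaseReport`.  Idempotent: filtering a filtered cohort
    retains everything.
    """
    if required_fields is None:
        required_fields = SCHEMA_COLUMNS
    required_fields = tuple(required_fields)
    unknown = [f for f in required_fields if f not in cohort.columns]
    if unknown:
        raise SchemaError(f"unknown required field(s): {unknown}")

    sub = cohort[list(required_fields)]
    keep = sub.notna().all(axis=1)
    n_input = len(cohort)
    n_retained = int(keep.sum())
    retention = 100.0 * n_retained / n_input if n_input else float("nan")
    report = CompleteCaseReport(
        n_input=n_input,
        n_retained=n_retained,
        retention_pct=retention,
        missing_by_field={f: int(sub[f].isna().sum()) for f in required_fields},
    )
    return cohort.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------


def save_cohort(cohort: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a cohort CSV with the fixed header, plus a JSON provenance
    sidecar (``<path>.provenance.json``) recording at least the seed."""
    validate_schema(cohort)
    cohort.to_csv(path, index=False)
    if provenance is not None:
        with open(f"{path}.provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)


def load_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV and restore schema dtypes (categorical confounders
    with the full fixed level sets, numeric exposure/outcomes)."""
    df = pd.read_csv(path)
    validate_schema(df)
    for col, levels in CATEGORICAL_CONFOUNDERS.items():
        bad = set(df[col].dropna().unique()) - set(levels)
        if bad:
            raise SchemaError(f"unknown categories in {col!r}: {sorted(bad)}")
        df[col] = pd.Categorical(df[col], categories=list(levels))
    for col in (EXPOSURE, "age") + OUTCOMES:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    return df


# ---------------------------------------------------------------------------
# Metabolic syndrome classification
# ---------------------------------------------------------------------------

# Five ATP-III style criteria.  Boundary semantics matter and are applied
# literally: waist and HDL comparisons are STRICT ("more than" / "less
# than"); triglycerides, blood pressure and glucose are WEAK (">=").
WAIST_CUTOFF = {"male": 102.0, "female": 88.0}    # cm, strict >
HDL_CUTOFF = {"male": 40.0, "female": 50.0}       # mg/dl, strict <
TG_CUTOFF = 150.0       # mg/dl, >=
SBP_CUTOFF = 130.0      # mmHg, >=
DBP_CUTOFF = 80.0       # mmHg, >=
GLUCOSE_CUTOFF = 110.0  # mg/dl, >=


def classify_metabolic_syndrome(
    waist_cm: float,
    sex: str,
    triglycerides: float,
    hdl: float,
    sbp: float,
    dbp: float,
    glucose: float,
) -> tuple[int, int]:
    """Classify one participant: returns ``(positive, criteria_met)``.

    Positive (metabolic syndrome present) iff at least three of the five
    criteria are met: elevated waist circumference (> 102 cm men, > 88 cm
    women), elevated triglycerides (>= 150 mg/dl), low HDL (< 40 men,
    < 50 women), hypertension (SBP >= 130 or DBP >= 80 mmHg), impaired
    fasting glucose (>= 110 mg/dl).
    """
    vals = (waist_cm, triglycerides, hdl, sbp, dbp, glucose)
    if sex is None or (isinstance(sex, float) and np.isnan(sex)) or pd.isna(sex):
        raise ClassificationError("sex is missing")
    if any(v is None or pd.isna(v) for v in vals):
        raise ClassificationError(
            "metabolic syndrome classification requires all seven inputs; "
            "complete-case filter first"
        )
    if sex not in SEX_LEVELS:
        raise SchemaError(f"unknown sex category {sex!r}")
    met = classify_metabolic_syndrome_frame(
        pd.DataFrame(
            {
                "waist": [waist_cm],
                "sex": [sex],
                "triglycerides": [triglycerides],
                "hdl": [hdl],
                "sbp": [sbp],
                "dbp": [dbp],
                "glucose": [glucose],
            }
        )
    )
    return int(met["mets"].iloc[0]), int(met["criteria_met"].iloc[0])


def classify_metabolic_syndrome_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification; returns a frame with ``mets`` (0/1) and
    ``criteria_met`` (0-5) aligned to the input index.

    Rows with any missing component get missing outputs rather than an
    error, so the result can feed the complete-case filter downstream.
    """
    validate_schema(cohort, ("waist", "sex", "triglycerides", "hdl", "sbp", "dbp", "glucose"))
    sex = cohort["sex"].astype(object)
    male = sex == "male"
    female = sex == "female"
    waist = pd.to_numeric(cohort["waist"])
    tg = pd.to_numeric(cohort["triglycerides"])
    hdl = pd.to_numeric(cohort["hdl"])
    sbp = pd.to_numeric(cohort["sbp"])
    dbp = pd.to_numeric(cohort["dbp"])
    glu = pd.to_numeric(cohort["glucose"])

    c_waist = (male & (waist > WAIST_CUTOFF["male"])) | (female & (waist > WAIST_CUTOFF["female"]))
    c_tg = tg >= TG_CUTOFF
    c_hdl = (male & (hdl < HDL_CUTOFF["male"])) | (female & (hdl < HDL_CUTOFF["female"]))
    c_bp = (sbp >= SBP_CUTOFF) | (dbp >= DBP_CUTOFF)
    c_glu = glu >= GLUCOSE_CUTOFF

    n_met = sum(c.astype(float) for c in (c_waist, c_tg, c_hdl, c_bp, c_glu))
    complete = (
        waist.notna() & tg.notna() & hdl.notna() & sbp.notna() & dbp.notna()
        & glu.notna() & (male | female)
    )
    out = pd.DataFrame(index=cohort.index)
    out["criteria_met"] = n_met.where(complete)
    out["mets"] = (n_met >= 3).astype(float).where(complete)
    return out


# ---------------------------------------------------------------------------
# Intervention grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterventionGrid:
    """Reference exposure (empirical minimum) plus ten intervention levels:
    the nine deciles p10..p90 and the empirical maximum, non-decreasing."""

    reference: float
    levels: tuple[float, ...]

    def __post_init__(self):
        if len(self.levels) != 10:
            raise ValueError(f"expected 10 intervention levels, got {len(self.levels)}")
        if any(l < self.reference for l in self.levels):
            raise ValueError("every intervention level must be >= the reference")
        if any(b < a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("intervention levels must be non-decreasing")

    @property
    def labels(self) -> tuple[str, ...]:
        return ("p10", "p20", "p30", "p40", "p50", "p60", "p70", "p80", "p90", "max")

    def __iter__(self):
        return iter(self.levels)

    def describe(self) -> str:
        lv = ", ".join(f"{l:.3f}" for l in self.levels)
        return f"reference {self.reference:.3f}; levels {lv}"


def intervention_grid(exposures) -> InterventionGrid:
    """Build the decile intervention grid from observed exposures.

    Deciles use linear interpolation between order statistics
    (Hyndman-Fan type 7, the numpy/R default).  The grid is computed once
    on the analysis sample and held fixed thereafter, including inside
    bootstrap resamples: the interventions are fixed policy levels.
    """
    x = np.asarray(pd.to_numeric(pd.Series(exposures), errors="raise"), dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise DegenerateDistributionError("need at least two exposure values")
    if np.unique(x).size < 2:
        raise DegenerateDistributionError(
            "all exposure values are identical; decile grid is degenerate"
        )
    deciles = np.quantile(x, np.arange(0.1, 1.0, 0.1), method="linear")
    levels = tuple(float(v) for v in deciles) + (float(x.max()),)
    return InterventionGrid(reference=float(x.min()), levels=levels)
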