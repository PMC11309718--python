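"""Effect modification via partial interventions and Cochran Q tests.

A partial intervention targets a single modifier stratum (for instance,
participants aged 65 or older): stratum members are simulated to receive
the intervention exposure level while everyone else keeps their observed
NDVI.  The outcome model carries an exposure-by-modifier interaction so
strata can have different exposure effects.  Stratum-specific RDs are
averaged over stratum members only, and homogeneity of the RDs across
strata is tested per intervention level with an inverse-variance-weighted
Cochran Q statistic (chi-square with K - 1 degrees of freedom), using
bootstrap standard deviations of the stratum RDs as standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cohort import (
    AGE_GROUP_COLUMN,
    AGE_GROUP_LEVELS,
    CATEGORICAL_CONFOUNDERS,
    EXPOSURE,
    InterventionGrid,
)
from .errors import (
    ConfigurationError,
    EmptyStratumError,
    HeterogeneityError,
    SchemaError,
)
from .gformula import (
    FittedOutcomeModel,
    OutcomeModelSpec,
    _mean_response,
    affine_exposure_designs,
    bootstrap_statistics,
    build_design,
    fit_outcome_model,
    percentile_ci,
)

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


def modifier_strata(modifier: str) -> tuple[str, ...]:
    if modifier == AGE_GROUP_COLUMN:
        return AGE_GROUP_LEVELS
    if modifier in CATEGORICAL_CONFOUNDERS:
        return CATEGORICAL_CONFOUNDERS[modifier]
    raise SchemaError(f"unknown modifier {modifier!r}")


def fit_interaction_model(cohort: pd.DataFrame, spec: OutcomeModelSpec,
                          modifier: str) -> FittedOutcomeModel:
    """Refit the outcome model with exposure-by-modifier product terms
    added to all main effects."""
    if spec.interaction is not None:
        raise ConfigurationError("spec already declares an interaction")
    modifier_strata(modifier)  # validates the name
    return fit_outcome_model(cohort, replace(spec, interaction=modifier))


@dataclass
class StratumRDEstimate:
    outcome: str
    modifier: str
    stratum: str
    level: float
    reference: float
    rd: float
    se: float = float("nan")      # bootstrap SD of the stratum RD
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_bootstrap: int = 0
    n_failed: int = 0


def _stratum_mask(cohort: pd.DataFrame, model: FittedOutcomeModel,
                  modifier: str, stratum: str) -> np.ndarray:
    from .gformula import prepare_model_frame

    mf = prepare_model_frame(cohort, model.spec, require_outcome=False)
    if modifier not in mf.columns:
        raise SchemaError(f"modifier {modifier!r} not available in the cohort")
    mask = mf[modifier].astype(object).to_numpy() == stratum
    if not mask.any():
        raise EmptyStratumError(f"stratum {stratum!r} of {modifier!r} is empty")
    return mask


def partial_intervention_rd(model: FittedOutcomeModel, cohort: pd.DataFrame,
                            modifier: str, stratum: str, level: float,
                            reference: float) -> StratumRDEstimate:
    """Stratum-specific RD under a partial intervention.

    Builds the full counterfactual cohort — stratum members at ``level``
    (resp. ``reference``), everyone else at their observed exposure — and
    contrasts the mean prediction over stratum members.  Because the model
    has no cross-participant terms, other participants' exposures do not
    enter the stratum summary; the construction is kept explicit anyway
    because it is the intervention being simulated.
    """
    if model.spec.interaction != modifier:
        raise ConfigurationError(
            f"model must include the exposure x {modifier} interaction"
        )
    mask = _stratum_mask(cohort, model, modifier, stratum)

    def stratum_mean(a_value: float) -> float:
        cf = cohort.copy()
        exposed = cf[EXPOSURE].to_numpy(dtype=float).copy()
        exposed[mask] = a_value
        cf[EXPOSURE] = exposed
        return float(model.predict(cf)[mask].mean())

    rd = 0.0 if level == reference else stratum_mean(level) - stratum_mean(reference)
    return StratumRDEstimate(
        outcome=model.spec.outcome, modifier=modifier, stratum=str(stratum),
        level=float(level), reference=float(reference), rd=rd,
    )


def bootstrap_stratum_rds(cohort: pd.DataFrame, spec: OutcomeModelSpec,
                          modifier: str, grid: InterventionGrid,
                          n_boot: int = 1000, seed: int = 0) -> list[StratumRDEstimate]:
    """Stratum RDs at every grid level with bootstrap SDs and percentile
    95% CIs.  One resampling pass serves every (stratum, level) cell, so
    the heterogeneity test compares estimates from a common resample
    stream."""
    model = fit_interaction_model(cohort, spec, modifier)
    y, X, _, _ = build_design(cohort, replace(spec, interaction=modifier))
    strata = [s for s in modifier_strata(modifier)
              if (_try_mask(cohort, model, modifier, s) is not None)]
    if len(strata) < 2:
        raise EmptyStratumError(
            f"modifier {modifier!r} has fewer than two non-empty strata"
        )
    masks = {s: _stratum_mask(cohort, model, modifier, s) for s in strata}

    # exposure enters linearly, so the counterfactual linear predictor of a
    # stratum member under A = v is (X0 @ beta) + (D @ beta) * v; only
    # stratum members enter the stratum summary, and everyone else keeping
    # their observed exposure contributes nothing to it
    X0, D = affine_exposure_designs(model, cohort)
    ref = float(grid.reference)
    cells = [(s, lv) for s in strata for lv in grid.levels]

    def stat_fn(beta, counts):
        u = X0 @ beta
        d = D @ beta
        out = np.empty(len(cells))
        for j, (s, lv) in enumerate(cells):
            m = masks[s]
            w = counts[m]
            denom = w.sum()
            if denom == 0:
                out[j] = np.nan
                continue
            if model.family == "gaussian":
                out[j] = (w @ d[m]) * (lv - ref) / denom
            else:
                mu1 = _mean_response(u[m] + d[m] * lv, model.family)
                mu0 = _mean_response(u[m] + d[m] * ref, model.family)
                out[j] = (w @ mu1 - w @ mu0) / denom
        return out

    draws, n_failed = bootstrap_statistics(X, y, model.family, stat_fn, n_boot, seed)
    points = stat_fn(model.params, np.ones(len(cohort)))
    estimates = []
    for j, (s, lv) in enumerate(cells):
        point = StratumRDEstimate(
            outcome=model.spec.outcome, modifier=modifier, stratum=str(s),
            level=float(lv), reference=ref, rd=float(points[j]),
        )
        cell = draws[:, j]
        cell = cell[~np.isnan(cell)]
        lo, hi = percentile_ci(cell)
        estimates.append(replace(
            point,
            se=float(np.std(cell, ddof=1)), ci_low=lo, ci_high=hi,
            n_bootstrap=int(cell.size), n_failed=n_failed,
        ))
    return estimates


def _try_mask(cohort, model, modifier, stratum):
    try:
        return _stratum_mask(cohort, model, modifier, stratum)
    except EmptyStratumError:
        return None


# ---------------------------------------------------------------------------
# Cochran Q
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneityResult:
    outcome: str
    modifier: str
    level: float
    Q: float
    df: int
    p_value: float
    significant: bool
    n_strata: int
    excluded_strata: tuple[str, ...] = ()


def cochran_q(estimates: list[StratumRDEstimate], *,
              se_cap: float | None = None,
              alpha: float = SIGNIFICANCE_LEVEL) -> HeterogeneityResult:
    """Inverse-variance Cochran Q test of RD homogeneity across strata.

    With weights w_k = 1/se_k^2 and weighted mean Rbar,
    Q = sum_k w_k (rd_k - Rbar)^2 is referred to chi-square with K - 1
    degrees of freedom.  Strata with se above ``se_cap`` are excluded
    (their weight is effectively zero) and logged; a stratum with se = 0
    is a degenerate weight and an error.
    """
    if not estimates:
        raise HeterogeneityError("no stratum estimates supplied")
    keys = {(e.outcome, e.modifier, e.level) for e in estimates}
    if len(keys) != 1:
        raise HeterogeneityError(
            "estimates must share one (outcome, modifier, level); got " + repr(sorted(keys))
        )
    outcome, modifier, level = next(iter(keys))

    excluded = []
    usable = []
    for e in estimates:
        if not np.isfinite(e.se) or e.se == 0:
            raise HeterogeneityError(
                f"stratum {e.stratum!r} has degenerate se = {e.se!r}"
            )
        if se_cap is not None and e.se > se_cap:
            excluded.append(e.stratum)
            continue
        usable.append(e)
    if excluded:
        logger.info("Cochran Q for %s/%s at %.3f excludes strata %s (se above cap)",
                    outcome, modifier, level, excluded)
    if len(usable) < 2:
        raise HeterogeneityError("Cochran Q needs at least two usable strata")

    rd = np.array([e.rd for e in usable])
    w = 1.0 / np.array([e.se for e in usable]) ** 2
    rbar = float(np.sum(w * rd) / np.sum(w))
    Q = float(np.sum(w * (rd - rbar) ** 2))
    df = len(usable) - 1
    p = float(chi2.sf(Q, df))
    return HeterogeneityResult(
        outcome=outcome, modifier=modifier, level=float(level),
        Q=Q, df=df, p_value=p, significant=p < alpha,
        n_strata=len(usable), excluded_strata=tuple(excluded),
    )


def heterogeneity_by_level(estimates: list[StratumRDEstimate], **kwargs) -> list[HeterogeneityResult]:
    """One Cochran Q test per intervention level (grouping the stratum
    estimates of one outcome/modifier pair)."""
    frame = {}
    for e in estimates:
        frame.setdefault((e.outcome, e.modifier, e.level), []).append(e)
    return [cochran_q(group, **kwargs) for group in frame.values()]


def max_level_summary(results: list[HeterogeneityResult]) -> HeterogeneityResult:
    """Convenience: the Q result at the highest tested level."""
    if not results:
        raise HeterogeneityError("no heterogeneity results")
    return max(results, key=lambda r: r.level)


def stratum_estimates_to_frame(estimates: list[StratumRDEstimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])


def heterogeneity_to_frame(results: list[HeterogeneityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = dict(vars(r))
        d["excluded_strata"] = ";".join(d["excluded_strata"])
        rows.append(d)
    return pd.DataFrame(rows)
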