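"""Parametric g-computation core.

The estimand is the standardized (marginal) mean outcome under a simulated
intervention that sets every participant's NDVI exposure to a fixed level
``a`` while confounders keep their observed values:

    E[Y^a] = sum_l E[Y | A = a, L = l] * Pr[L = l]

estimated by fitting an outcome regression (Gaussian-identity GLM for
continuous biomarkers, binomial-logit for metabolic syndrome), predicting
every participant's outcome with exposure overwritten by ``a``, and
averaging the predictions over the empirical confounder distribution.
The risk difference (RD) contrasts an intervention level against the
reference level (the empirical exposure minimum).

Confidence intervals are percentile bootstrap: participants are resampled
with replacement, the outcome model refit, and the RDs recomputed at the
*fixed* intervention grid; the 2.5th/97.5th percentiles of the draws form
the 95% CI.  The point estimate always comes from the full sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .cohort import (
    AGE_GROUP_COLUMN,
    CATEGORICAL_CONFOUNDERS,
    CONFOUNDERS,
    EXPOSURE,
    OUTCOMES as _KNOWN_OUTCOMES,
    InterventionGrid,
    add_age_group,
    outcome_family,
)
from .errors import (
    BootstrapError,
    ConfigurationError,
    ConvergenceError,
    SchemaError,
    SingularDesignError,
)

logger = logging.getLogger(__name__)

MAX_FAILED_REFIT_FRACTION = 0.1


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Specification of one outcome regression.

    ``family`` defaults to the family matching the outcome (gaussian for
    the nine biomarkers, binomial for metabolic syndrome).  ``interaction``
    names a modifier (sex, ethnicity, income, or the age-65 dichotomy
    ``age65``) whose product with exposure enters the model in addition to
    all main effects.
    """

    outcome: str
    family: str | None = None
    confounders: tuple[str, ...] = CONFOUNDERS
    interaction: str | None = None

    def resolved_family(self) -> str:
        fam = self.family or outcome_family(self.outcome)
        if fam not in ("gaussian", "binomial"):
            raise ConfigurationError(f"unknown family {fam!r}")
        declared = outcome_family(self.outcome) if self.outcome in _KNOWN_OUTCOMES else fam
        if self.family is not None and self.outcome in _KNOWN_OUTCOMES and self.family != declared:
            raise ConfigurationError(
                f"family {self.family!r} does not match outcome {self.outcome!r} ({declared})"
            )
        return fam

    def modifier_column(self) -> str | None:
        return self.interaction

    def formula_rhs(self) -> str:
        terms = [EXPOSURE]
        for conf in self.confounders:
            terms.append("age" if conf == "age" else f"C({conf})")
        if self.interaction is not None:
            mod = self.interaction
            if mod == AGE_GROUP_COLUMN:
                terms.append(f"C({AGE_GROUP_COLUMN})")
            elif mod not in self.confounders:
                terms.append(f"C({mod})")
            terms.append(f"{EXPOSURE}:C({mod})")
        return " + ".join(terms)


@dataclass
class FittedOutcomeModel:
    """A fitted outcome regression plus everything needed to predict on
    counterfactual data (design metadata and coefficient vector)."""

    spec: OutcomeModelSpec
    family: str
    params: np.ndarray
    param_names: list[str]
    bse: np.ndarray
    n_obs: int
    converged: bool
    design_info: patsy.DesignInfo = field(repr=False)

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names)

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        X = _design_for_prediction(self, cohort)
        return _mean_response(X @ self.params, self.family)


def _mean_response(lp: np.ndarray, family: str) -> np.ndarray:
    return expit(lp) if family == "binomial" else lp


def prepare_model_frame(cohort: pd.DataFrame, spec: OutcomeModelSpec,
                        require_outcome: bool = True) -> pd.DataFrame:
    """Coerce the columns a spec uses to their schema dtypes (categoricals
    with the full fixed level sets, numerics as float) and derive the
    age-65 dichotomy when the spec needs it."""
    needed = [EXPOSURE, *spec.confounders]
    mod = spec.modifier_column()
    df = cohort.copy()
    if mod == AGE_GROUP_COLUMN:
        if "age" not in df.columns and AGE_GROUP_COLUMN not in df.columns:
            raise SchemaError("age (or age65) column required for the age-65 modifier")
        if AGE_GROUP_COLUMN not in df.columns:
            df = add_age_group(df)
        needed.append(AGE_GROUP_COLUMN)
    elif mod is not None:
        needed.append(mod)
    if require_outcome:
        needed.append(spec.outcome)
    missing_cols = [c for c in dict.fromkeys(needed) if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"cohort is missing column(s) {missing_cols}")

    out = df[list(dict.fromkeys(needed))].copy()
    for col in out.columns:
        if col in CATEGORICAL_CONFOUNDERS:
            out[col] = pd.Categorical(out[col].astype(object),
                                      categories=list(CATEGORICAL_CONFOUNDERS[col]))
        elif col != AGE_GROUP_COLUMN:
            out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise SchemaError(
            f"missing values in {bad}; run the complete-case filter before modelling"
        )
    return out


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank >= X.shape[1]:
        return
    zero = [n for j, n in enumerate(names) if not np.any(X[:, j] != 0)]
    if zero:
        raise SingularDesignError(zero)
    # name columns eliminated by pivoted QR
    from scipy.linalg import qr

    _, _, piv = qr(X, mode="economic", pivoting=True)
    dropped = [names[j] for j in piv[rank:]]
    raise SingularDesignError(dropped)


def build_design(cohort: pd.DataFrame, spec: OutcomeModelSpec,
                 check_rank: bool = True):
    """Return (y, X, design_info, param_names) for a spec on a cohort.

    ``check_rank=False`` skips the singular-design guard; used for
    bootstrap-resample refits, where a resample that lost an entire rare
    category is handled by pseudo-inverse fitting (the lost category's
    coefficient never enters that resample's statistics)."""
    mf = prepare_model_frame(cohort, spec, require_outcome=True)
    y, X = patsy.dmatrices(f"{spec.outcome} ~ {spec.formula_rhs()}", data=mf,
                           return_type="dataframe")
    names = list(X.columns)
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    if check_rank:
        _check_rank(Xa, names)
    return ya, Xa, X.design_info, names


def _design_for_prediction(model: FittedOutcomeModel, cohort: pd.DataFrame) -> np.ndarray:
    mf = prepare_model_frame(cohort, model.spec, require_outcome=False)
    (X,) = patsy.build_design_matrices([model.design_info], mf, return_type="dataframe")
    return np.asarray(X, dtype=float)


def fit_outcome_model(cohort: pd.DataFrame, spec: OutcomeModelSpec,
                      require_convergence: bool = False) -> FittedOutcomeModel:
    """Maximum-likelihood GLM fit of the outcome regression.

    Gaussian-identity fits are deterministic (closed form); binomial-logit
    fits are IRLS with the convergence flag preserved.  A rank-deficient
    design raises :class:`SingularDesignError` naming the offending
    column(s) (e.g. an empty category level).
    """
    y, X, design_info, names = build_design(cohort, spec)
    family = spec.resolved_family()
    if X.shape[0] <= X.shape[1]:
        raise ConfigurationError(
            f"n = {X.shape[0]} rows cannot identify {X.shape[1]} design columns"
        )
    fam = sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()
    res = sm.GLM(y, X, family=fam).fit(maxiter=200)
    converged = bool(getattr(res, "converged", True)) if family == "binomial" else True
    if not converged:
        logger.warning("logit fit for %s did not converge", spec.outcome)
        if require_convergence:
            raise ConvergenceError(f"logit fit for {spec.outcome} did not converge")
    return FittedOutcomeModel(
        spec=spec, family=family,
        params=np.asarray(res.params, dtype=float),
        param_names=names,
        bse=np.asarray(res.bse, dtype=float),
        n_obs=int(X.shape[0]), converged=converged,
        design_info=design_info,
    )


def predict_counterfactual(model: FittedOutcomeModel, cohort: pd.DataFrame,
                           level: float) -> np.ndarray:
    """Per-participant predicted mean outcome with exposure overwritten by
    ``level`` and confounders kept at observed values (response scale)."""
    cf = cohort.copy()
    cf[EXPOSURE] = float(level)
    return model.predict(cf)


def g_compute_rd(model: FittedOutcomeModel, cohort: pd.DataFrame,
                 level: float, reference: float) -> float:
    """Standardized risk difference: mean counterfactual prediction at
    ``level`` minus at ``reference``, averaged over the empirical
    confounder distribution."""
    if level == reference:
        return 0.0
    mu1 = predict_counterfactual(model, cohort, level)
    mu0 = predict_counterfactual(model, cohort, reference)
    return float(mu1.mean() - mu0.mean())


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


@dataclass
class RDEstimate:
    outcome: str
    level: float
    reference: float
    rd: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_bootstrap: int = 0
    n_failed: int = 0
    bootstrap_draws: np.ndarray | None = field(default=None, repr=False)


def _refit_beta(X: np.ndarray, y: np.ndarray, counts: np.ndarray, family: str) -> np.ndarray:
    """Fit a GLM on the bootstrap resample encoded as per-row counts.

    A resample drawn with replacement is represented by how many times
    each original row appears; frequency-weighted fits are then exactly
    the fits on the expanded resample."""
    if family == "gaussian":
        Xw = X * counts[:, None]
        XtX = Xw.T @ X
        Xty = Xw.T @ y
        try:
            c, low = cho_factor(XtX)
            return cho_solve((c, low), Xty)
        except np.linalg.LinAlgError:
            pass
        # A resample can miss an entire rare category, leaving its dummy
        # column empty.  That coefficient is unidentified but also carries
        # zero weight in every count-weighted statistic computed from the
        # resample, so the minimum-norm solution is exact for those
        # statistics.
        w = np.sqrt(counts)
        beta, _, rank, _ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
        return beta
    res = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=counts).fit(maxiter=100)
    if not bool(getattr(res, "converged", True)):
        raise ConvergenceError("bootstrap logit refit did not converge")
    return np.asarray(res.params, dtype=float)


def _resample_counts(n: int, rng: np.random.Generator,
                     cluster_codes: np.ndarray | None) -> np.ndarray:
    if cluster_codes is None:
        idx = rng.integers(0, n, size=n)
        return np.bincount(idx, minlength=n).astype(float)
    n_clusters = int(cluster_codes.max()) + 1
    drawn = rng.integers(0, n_clusters, size=n_clusters)
    per_cluster = np.bincount(drawn, minlength=n_clusters).astype(float)
    return per_cluster[cluster_codes]


def bootstrap_statistics(X, y, family, stat_fn, n_boot, seed, *,
                         cluster_codes=None,
                         max_fail_frac=MAX_FAILED_REFIT_FRACTION):
    """Generic participant-resampling bootstrap around a GLM refit.

    ``stat_fn(beta, counts)`` maps a refit coefficient vector and the
    resample's row counts to a statistic vector.  Failed refits (singular
    or non-convergent) are dropped and counted; more than ``max_fail_frac``
    failures is a hard error.  Returns (draws, n_failed).
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    draws = []
    n_failed = 0
    for _ in range(n_boot):
        counts = _resample_counts(n, rng, cluster_codes)
        try:
            beta = _refit_beta(X, y, counts, family)
        except (np.linalg.LinAlgError, ConvergenceError, ValueError):
            n_failed += 1
            continue
        draws.append(stat_fn(beta, counts))
    if n_failed > max_fail_frac * n_boot:
        raise BootstrapError(
            f"{n_failed}/{n_boot} bootstrap refits failed (> {max_fail_frac:.0%})"
        )
    if n_failed:
        logger.info("dropped %d failed bootstrap refits of %d", n_failed, n_boot)
    return np.asarray(draws, dtype=float), n_failed


def affine_exposure_designs(model: FittedOutcomeModel, cohort: pd.DataFrame):
    """Decompose the design as X(e) = X0 + D * e[:, None] for a per-row
    exposure vector ``e``.

    Exact because exposure enters the model linearly (the main term and
    any exposure-by-modifier products are linear in A; all other columns
    are constant in A), so counterfactual linear predictors are
    ``X0 @ beta + (D @ beta) * e`` without rebuilding designs."""
    cf0 = cohort.copy()
    cf0[EXPOSURE] = 0.0
    cf1 = cohort.copy()
    cf1[EXPOSURE] = 1.0
    X0 = _design_for_prediction(model, cf0)
    D = _design_for_prediction(model, cf1) - X0
    return X0, D


def percentile_ci(draws: np.ndarray, level: float = 95.0) -> tuple[float, float]:
    lo = (100.0 - level) / 2.0
    q = np.percentile(draws, [lo, 100.0 - lo])
    return float(q[0]), float(q[1])


def bootstrap_rds(cohort: pd.DataFrame, spec: OutcomeModelSpec, grid: InterventionGrid,
                  n_boot: int = 1000, seed: int = 0, *, keep_draws: bool = False,
                  cluster: str | None = None) -> list[RDEstimate]:
    """Point RDs from the full sample plus percentile-bootstrap 95% CIs at
    every level of the fixed intervention grid.

    The grid never changes across resamples (the interventions are fixed
    policy levels).  ``cluster`` optionally names a cluster-id column for a
    cluster bootstrap; the default resamples participants i.i.d.
    """
    model = fit_outcome_model(cohort, spec)
    y, X, _, _ = build_design(cohort, spec)
    levels = list(grid.levels)
    X0, D = affine_exposure_designs(model, cohort)
    ref = float(grid.reference)
    n = X.shape[0]

    cluster_codes = None
    if cluster is not None:
        if cluster not in cohort.columns:
            raise SchemaError(f"unknown cluster column {cluster!r}")
        cluster_codes = pd.factorize(cohort[cluster])[0]

    def stat_fn(beta, counts):
        u = X0 @ beta
        d = D @ beta
        if model.family == "gaussian":
            slope = counts @ d / n
            return np.array([slope * (lv - ref) for lv in levels])
        mu_ref = counts @ _mean_response(u + d * ref, model.family) / n
        return np.array(
            [counts @ _mean_response(u + d * lv, model.family) / n - mu_ref
             for lv in levels]
        )

    draws, n_failed = bootstrap_statistics(X, y, model.family, stat_fn, n_boot, seed,
                                           cluster_codes=cluster_codes)
    points = stat_fn(model.params, np.ones(n))
    estimates = []
    for k, level in enumerate(levels):
        point = float(points[k])
        level_draws = draws[:, k]
        lo, hi = percentile_ci(level_draws)
        estimates.append(RDEstimate(
            outcome=spec.outcome, level=float(level), reference=float(grid.reference),
            rd=point, ci_low=lo, ci_high=hi,
            n_bootstrap=int(draws.shape[0]), n_failed=n_failed,
            bootstrap_draws=level_draws.copy() if keep_draws else None,
        ))
    return estimates


def rd_point_estimates(model: FittedOutcomeModel, cohort: pd.DataFrame,
                       grid: InterventionGrid) -> list[RDEstimate]:
    """Full-sample point RDs at every grid level (no bootstrap)."""
    return [
        RDEstimate(outcome=model.spec.outcome, level=float(level),
                   reference=float(grid.reference),
                   rd=g_compute_rd(model, cohort, level, grid.reference))
        for level in grid.levels
    ]


def estimates_to_frame(estimates: list[RDEstimate], engine: str = "glm") -> pd.DataFrame:
    """Tidy RD table: one row per (outcome, level)."""
    return pd.DataFrame(
        {
            "outcome": [e.outcome for e in estimates],
            "level": [e.level for e in estimates],
            "reference": [e.reference for e in estimates],
            "rd": [e.rd for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "n_boot": [e.n_bootstrap for e in estimates],
            "engine": engine,
        }
    )
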