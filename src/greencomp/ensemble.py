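"""Super-learner sensitivity arm.

A cross-validated stacking ensemble over four learners — main-terms GLM,
random forest, elastic net (mixing 0.5, penalty by inner CV), and gradient
boosted trees — combined by non-negative least squares on out-of-fold
predictions, with the weights normalized to the probability simplex.
The ensemble replaces the GLM as the prediction engine inside the same
g-computation and bootstrap machinery; by construction, forcing weight 1
onto the GLM learner reproduces the main analysis exactly.

This arm checks sensitivity to outcome-model misspecification.  Note that
singly robust estimators combined with machine learning are known to
underperform doubly robust alternatives in bias and CI coverage; the
ensemble here is a model-fit comparison, not the headline estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy.optimize import nnls
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import ElasticNetCV, LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier, XGBRegressor

from .cohort import EXPOSURE, InterventionGrid
from .errors import BootstrapError, ConfigurationError
from .gformula import (
    OutcomeModelSpec,
    RDEstimate,
    build_design,
    percentile_ci,
    prepare_model_frame,
)

logger = logging.getLogger(__name__)

LEARNER_NAMES = ("glm", "random_forest", "elastic_net", "xgboost")

# Conventional fixed hyperparameters; recorded in the provenance sidecar.
DEFAULT_LEARNER_PARAMS = {
    "rf_n_estimators": 500,
    "rf_min_samples_leaf": 5,
    "xgb_n_estimators": 200,
    "xgb_max_depth": 3,
    "xgb_learning_rate": 0.1,
    "enet_l1_ratio": 0.5,
    "enet_n_alphas": 50,
    "folds": 10,
}

# Reduced settings for quick pipelines; same library, smaller trees.
DESK_SCALE_LEARNER_PARAMS = {
    **DEFAULT_LEARNER_PARAMS,
    "rf_n_estimators": 100,
    "xgb_n_estimators": 60,
    "enet_n_alphas": 20,
}


def _clip_probs(p):
    return np.clip(p, 1e-12, 1 - 1e-12)


class _Learner:
    name: str

    def __init__(self, family: str, params: dict, seed: int):
        self.family = family
        self.params = params
        self.seed = int(seed) % 2**31

    def fit(self, X, y):  # pragma: no cover - interface
        raise NotImplementedError

    def predict(self, fitted, X):
        if self.family == "binomial":
            return _clip_probs(fitted.predict_proba(X)[:, 1])
        return fitted.predict(X)


class _GLMLearner(_Learner):
    """Main-terms GLM on the identical design matrix as the main analysis,
    so a degenerate weight vector reduces the ensemble to it exactly."""

    name = "glm"

    def fit(self, X, y):
        fam = sm.families.Binomial() if self.family == "binomial" else sm.families.Gaussian()
        return sm.GLM(y, X, family=fam).fit(maxiter=200)

    def predict(self, fitted, X):
        mu = np.asarray(fitted.predict(X), dtype=float)
        return _clip_probs(mu) if self.family == "binomial" else mu


class _RandomForestLearner(_Learner):
    name = "random_forest"

    def fit(self, X, y):
        kw = dict(
            n_estimators=self.params["rf_n_estimators"],
            min_samples_leaf=self.params["rf_min_samples_leaf"],
            random_state=self.seed, n_jobs=1,
        )
        if self.family == "binomial":
            model = RandomForestClassifier(**kw)
            return model.fit(X, y.astype(int))
        return RandomForestRegressor(**kw).fit(X, y)


class _ElasticNetLearner(_Learner):
    name = "elastic_net"

    def fit(self, X, y):
        if self.family == "binomial":
            model = make_pipeline(
                StandardScaler(),
                LogisticRegressionCV(
                    Cs=10, cv=5, solver="saga",
                    l1_ratios=[self.params["enet_l1_ratio"]],
                    scoring="neg_log_loss", use_legacy_attributes=False,
                    max_iter=5000, random_state=self.seed,
                ),
            )
            return model.fit(X, y.astype(int))
        model = make_pipeline(
            StandardScaler(),
            ElasticNetCV(
                l1_ratio=self.params["enet_l1_ratio"],
                alphas=self.params["enet_n_alphas"],
                cv=5, random_state=self.seed, max_iter=5000,
            ),
        )
        return model.fit(X, y)


class _XGBoostLearner(_Learner):
    name = "xgboost"

    def fit(self, X, y):
        kw = dict(
            n_estimators=self.params["xgb_n_estimators"],
            max_depth=self.params["xgb_max_depth"],
            learning_rate=self.params["xgb_learning_rate"],
            random_state=self.seed, n_jobs=1, verbosity=0, tree_method="hist",
        )
        if self.family == "binomial":
            return XGBClassifier(eval_metric="logloss", **kw).fit(X, y.astype(int))
        return XGBRegressor(**kw).fit(X, y)


_LEARNER_CLASSES = {
    "glm": _GLMLearner,
    "random_forest": _RandomForestLearner,
    "elastic_net": _ElasticNetLearner,
    "xgboost": _XGBoostLearner,
}


@dataclass
class SuperLearnerFit:
    """Fitted stacking ensemble.

    ``weights`` live on the probability simplex (non-negative, summing to
    one) and minimize cross-validated risk of the weighted out-of-fold
    predictions.  ``cv_risks`` are per-learner CV mean squared error
    (gaussian) or CV mean negative log-likelihood (binomial).
    """

    spec: OutcomeModelSpec
    family: str
    learners: tuple[str, ...]
    weights: np.ndarray
    cv_risks: dict[str, float]
    ensemble_cv_risk: float
    folds: int
    seed: int
    dropped: tuple[str, ...] = ()
    _fitted: dict = field(default_factory=dict, repr=False)
    _learner_objs: dict = field(default_factory=dict, repr=False)
    design_info: patsy.DesignInfo | None = field(default=None, repr=False)

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        mf = prepare_model_frame(cohort, self.spec, require_outcome=False)
        (X,) = patsy.build_design_matrices([self.design_info], mf, return_type="dataframe")
        X = np.asarray(X, dtype=float)
        preds = np.column_stack([
            self._learner_objs[name].predict(self._fitted[name], X)
            for name in self.learners
        ])
        return preds @ self.weights


def _risk(y, pred, family):
    if family == "binomial":
        p = _clip_probs(pred)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))
    return float(np.mean((y - pred) ** 2))


def fit_super_learner(cohort: pd.DataFrame, spec: OutcomeModelSpec, seed: int = 0, *,
                      folds: int = 10, learner_params: dict | None = None,
                      learners: tuple[str, ...] = LEARNER_NAMES,
                      check_rank: bool = True) -> SuperLearnerFit:
    """Fit the stacking ensemble with V-fold cross-validation.

    Out-of-fold predictions are computed for every learner (folds are
    stratified by the outcome for binomial families); meta-weights come
    from non-negative least squares of the outcome on the out-of-fold
    prediction matrix, normalized to sum to one; finally every learner is
    refit on the full data.  A learner that fails in any fold is dropped
    with a warning and the weights renormalized; all learners failing is a
    hard error.
    """
    if not learners:
        raise ConfigurationError("learner library is empty")
    params = {**DEFAULT_LEARNER_PARAMS, **(learner_params or {})}
    folds = int((learner_params or {}).get("folds", folds))
    y, X, design_info, _ = build_design(cohort, spec, check_rank=check_rank)
    family = spec.resolved_family()
    seed = int(seed) % 2**31

    if family == "binomial":
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = list(splitter.split(X, y.astype(int)))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = list(splitter.split(X))

    learner_objs = {name: _LEARNER_CLASSES[name](family, params, seed + i)
                    for i, name in enumerate(learners)}
    oof = {name: np.full(len(y), np.nan) for name in learners}
    dropped: list[str] = []
    for name, learner in learner_objs.items():
        try:
            for train, test in split_iter:
                fitted = learner.fit(X[train], y[train])
                oof[name][test] = learner.predict(fitted, X[test])
        except Exception as exc:  # noqa: BLE001 - any learner failure drops it
            warnings.warn(f"learner {name!r} failed during CV and was dropped: {exc}",
                          stacklevel=2)
            dropped.append(name)

    kept = tuple(n for n in learners if n not in dropped)
    if not kept:
        raise ConfigurationError("all super-learner candidates failed")

    cv_risks = {name: _risk(y, oof[name], family) for name in kept}
    P = np.column_stack([oof[name] for name in kept])
    w, _ = nnls(P, y)
    if w.sum() <= 0:
        w = np.zeros(len(kept))
        w[int(np.argmin([cv_risks[n] for n in kept]))] = 1.0
    else:
        w = w / w.sum()
    ensemble_risk = _risk(y, P @ w, family)

    fitted_full = {name: learner_objs[name].fit(X, y) for name in kept}
    return SuperLearnerFit(
        spec=spec, family=family, learners=kept, weights=w,
        cv_risks=cv_risks, ensemble_cv_risk=ensemble_risk,
        folds=folds, seed=seed, dropped=tuple(dropped),
        _fitted=fitted_full, _learner_objs=learner_objs, design_info=design_info,
    )


def sl_g_compute_rd(fit: SuperLearnerFit, cohort: pd.DataFrame,
                    level: float, reference: float) -> float:
    """Standardized RD with the ensemble as the prediction engine."""
    if level == reference:
        return 0.0
    cf1 = cohort.copy()
    cf1[EXPOSURE] = float(level)
    cf0 = cohort.copy()
    cf0[EXPOSURE] = float(reference)
    return float(fit.predict(cf1).mean() - fit.predict(cf0).mean())


def sl_point_rds(fit: SuperLearnerFit, cohort: pd.DataFrame,
                 grid: InterventionGrid) -> list[RDEstimate]:
    return [
        RDEstimate(outcome=fit.spec.outcome, level=float(level),
                   reference=float(grid.reference),
                   rd=sl_g_compute_rd(fit, cohort, level, grid.reference))
        for level in grid.levels
    ]


def sl_gcompute_rds(cohort: pd.DataFrame, spec: OutcomeModelSpec, grid: InterventionGrid,
                    n_boot: int = 1000, seed: int = 0, *,
                    folds: int = 10, learner_params: dict | None = None,
                    learners: tuple[str, ...] = LEARNER_NAMES,
                    refit_weights: bool = True, keep_draws: bool = False,
                    max_fail_frac: float = 0.1) -> list[RDEstimate]:
    """Ensemble analogue of :func:`greencomp.gformula.bootstrap_rds`.

    Point RDs come from the full-sample super learner; each bootstrap
    iteration resamples participants, repeats the entire super-learner fit
    (cross-validation, meta-weights, refits) on the resample, and
    recomputes RDs at the fixed grid.  ``refit_weights=False`` is an
    approximate fast mode that reuses the full-sample meta-weights and
    only refits the learners per draw.
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    full = fit_super_learner(cohort, spec, seed, folds=folds,
                             learner_params=learner_params, learners=learners)
    points = sl_point_rds(full, cohort, grid)

    ss = np.random.SeedSequence(int(seed) % 2**31)
    rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_boot)]
    n = len(cohort)
    draws = []
    n_failed = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resample = cohort.iloc[idx].reset_index(drop=True)
        try:
            if refit_weights:
                fit_b = fit_super_learner(resample, spec, child_seeds[b], folds=folds,
                                          learner_params=learner_params, learners=learners,
                                          check_rank=False)
            else:
                fit_b = _refit_learners_fixed_weights(full, resample, spec, child_seeds[b],
                                                      learner_params)
            draws.append([sl_g_compute_rd(fit_b, resample, lv, grid.reference)
                          for lv in grid.levels])
        except Exception as exc:  # noqa: BLE001
            logger.info("super-learner bootstrap draw %d failed: %s", b, exc)
            n_failed += 1
    if n_failed > max_fail_frac * n_boot:
        raise BootstrapError(f"{n_failed}/{n_boot} super-learner bootstrap refits failed")
    draws = np.asarray(draws, dtype=float)

    estimates = []
    for k, est in enumerate(points):
        cell = draws[:, k]
        lo, hi = percentile_ci(cell)
        estimates.append(RDEstimate(
            outcome=est.outcome, level=est.level, reference=est.reference, rd=est.rd,
            ci_low=lo, ci_high=hi, n_bootstrap=int(cell.size), n_failed=n_failed,
            bootstrap_draws=cell.copy() if keep_draws else None,
        ))
    return estimates


def _refit_learners_fixed_weights(full: SuperLearnerFit, cohort, spec, seed, learner_params):
    params = {**DEFAULT_LEARNER_PARAMS, **(learner_params or {})}
    y, X, design_info, _ = build_design(cohort, spec, check_rank=False)
    objs = {name: _LEARNER_CLASSES[name](full.family, params, seed + i)
            for i, name in enumerate(full.learners)}
    fitted = {name: objs[name].fit(X, y) for name in full.learners}
    return SuperLearnerFit(
        spec=spec, family=full.family, learners=full.learners,
        weights=full.weights, cv_risks=dict(full.cv_risks),
        ensemble_cv_risk=full.ensemble_cv_risk, folds=full.folds, seed=seed,
        dropped=full.dropped, _fitted=fitted, _learner_objs=objs,
        design_info=design_info,
    )
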