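# Methods

## Estimand and estimator

`greencomp` estimates the effect of simulated interventions on a continuous
residential greenness exposure — NDVI (normalized difference vegetation
index, unitless, physically in [-1, 1]) — on metabolic biomarkers, by
parametric g-computation (standardization). For an intervention that sets
every participant's exposure to a fixed level *a*, the standardized mean
outcome is

    E[Y^a] = Σ_l E[Y | A = a, L = l] · Pr[L = l],

estimated by (i) fitting an outcome regression of Y on A and the
confounder vector L, (ii) predicting each participant's outcome with A
overwritten by *a* and L kept at its observed value, and (iii) averaging
the predictions — i.e. standardizing over the empirical confounder
distribution. The risk difference (RD) contrasts an intervention level
against the reference level.

The intervention grid is derived from the observed exposure distribution:
the empirical minimum is the reference ("unexposed") level and the ten
intervention levels are the nine deciles p10..p90 plus the empirical
maximum. Deciles use linear interpolation between order statistics
(Hyndman–Fan type 7, the numpy and R default); the estimator is isolated
in one function so it can be swapped. The grid is computed once on the
analysis sample and held fixed everywhere afterwards — including inside
bootstrap resamples — because the interventions are fixed policy levels;
re-deriving them per resample would change the estimand.

Outcome regressions are GLMs: Gaussian with identity link for the nine
continuous biomarkers (fasting glucose, total/LDL/HDL cholesterol,
triglycerides in mg/dl; hemoglobin A1c in %; SBP/DBP in mmHg; waist
circumference in cm), binomial with logit link for binary metabolic
syndrome. Confounders are sex, income (3 categories), race (6),
ethnicity (2), education (2), and age entered linearly (no spline by
default, keeping the main model a plain main-terms GLM). Dummy coding uses
the largest groups as references: male, income ≥ $55k, White,
non-Hispanic, high school or more; the coding is configurable.

Causal interpretation rests on exchangeability (no unmeasured confounding
given L), positivity, and consistency; none of these are testable from the
data and the package does not claim them for any particular application.

## Confidence intervals

Percentile bootstrap: participants are resampled i.i.d. with replacement
(same n), the outcome model is refit on each resample, RDs are recomputed
at the fixed grid, and the 2.5th/97.5th percentiles of the draws form the
95% CI. 1000 iterations by default. The point estimate always comes from
the full sample, never from resamples. Percentile intervals were chosen
over normal-approximation or BCa as the simplest bootstrap interval; the
interval computation is a single small function (`percentile_ci`) and is
pluggable.

Implementation note: a resample is represented by per-row multiplicities,
and refits are frequency-weighted — weighted normal equations for the
Gaussian family, `freq_weights` IRLS for the binomial — which is exactly
the fit on the expanded resample at a fraction of the cost. Because
exposure enters every model linearly, the counterfactual design matrix is
affine in the exposure vector (X(e) = X0 + D·e), so per-draw RDs need two
matrix–vector products rather than rebuilt design matrices. A resample
that loses an entire rare category (e.g. a small race group) leaves that
dummy coefficient unidentified; since rows of the lost category have zero
multiplicity, the coefficient carries zero weight in every statistic of
that resample, and the minimum-norm (pseudo-inverse) solution is exact for
those statistics. Binomial refits that fail to converge are dropped and
counted; more than 10% failures aborts with an error. Recruitment in the
kind of study this emulates is often geographically clustered; the default
bootstrap nevertheless resamples participants (matching the analysis it
implements), with an optional cluster-id column for a cluster bootstrap,
flagged as a robustness toggle.

## Effect modification and heterogeneity

Modifiers: sex, ethnicity, income, and age dichotomized at 65 years (65.0
falls in the ≥ 65 stratum). The outcome model gains exposure×modifier
product terms on top of all main effects. A *partial* intervention sets
A = a for members of one modifier stratum while everyone else keeps their
observed exposure; the stratum RD is the mean predicted outcome over
stratum members under the level minus under the reference. For models
without cross-participant terms, the exposures of non-members cannot
enter the stratum summary; the full counterfactual construction is kept
explicit anyway because it *is* the intervention being simulated.

Homogeneity of stratum RDs is tested per intervention level with Cochran's
Q: with weights w_k = 1/se_k², weighted mean R̄ = Σw_k·rd_k / Σw_k,

    Q = Σ_k w_k (rd_k − R̄)²  ~  χ²(K − 1) under homogeneity,

significant at p < 0.05. Standard errors are bootstrap standard deviations
of the stratum RDs, all strata computed from a common resample stream.
One test per (outcome, modifier, level); a max-level summary convenience
is provided, and no multiplicity correction is applied by default (a
single 0.05 threshold per test), with a correction left to the caller.
A stratum with se = 0 is a degenerate weight and an error; strata with se
above a configurable cap are excluded (their weight is effectively zero)
and logged.

With dummy-coded interactions the stratum slopes are estimated from
nearly disjoint parts of the data, so the independence assumption behind
Q is a good approximation; the type-I error simulation in the test suite
confirms the nominal 5% level.

## Metabolic syndrome classification

Positive iff at least three of five criteria hold. Boundary semantics are
deliberate and asymmetric: waist circumference (> 102 cm men, > 88 cm
women) and HDL (< 40 men, < 50 women) are strict inequalities;
triglycerides (≥ 150 mg/dl), blood pressure (SBP ≥ 130 or DBP ≥ 80 mmHg)
and fasting glucose (≥ 110 mg/dl) are weak. Rows exactly at a threshold
flip classification depending on the criterion, so the comparisons are
pinned by an exhaustive boundary truth table in the tests.

## Complete-case filtering

Listwise deletion across exposure, all confounders and all requested
outcomes, producing a single analytic sample shared by every outcome model
(a per-outcome option exists but is experimental). The report records
per-field missing counts and the retention percentage. Missing-data
handling assumes the missingness is ignorable; no imputation is offered.

## Super-learner sensitivity arm

A stacking ensemble over four learners — main-terms GLM, random forest,
elastic net, gradient boosted trees — combined by 10-fold cross-validated
stacking: out-of-fold predictions per learner (folds stratified by outcome
for the binary family), meta-weights by non-negative least squares of the
outcome on the out-of-fold prediction matrix, normalized to the
probability simplex (the de facto standard meta-learner), then all
learners refit on the full data. CV risk is mean squared error (Gaussian)
or mean negative log-likelihood (binomial). The GLM learner uses the
identical design matrix and fitting routine as the main analysis, so
forcing weight 1 onto it reproduces the main RDs exactly — a property the
tests assert. A learner failing in any CV fold is dropped with a warning
and the weights renormalized.

Hyperparameters are fixed at conventional defaults and recorded in the
provenance sidecar: random forest 500 trees with min leaf 5; boosting 200
rounds, depth 3, learning rate 0.1; elastic-net mixing 0.5 with penalty by
inner 5-fold CV. A desk-scale profile (100 trees, 60 rounds) serves quick
pipelines. Bootstrap CIs for the ensemble repeat the *entire*
super-learner fit inside each iteration (statistically correct, slow); a
fast mode reuses the full-sample meta-weights and refits only the
learners, flagged approximate. Singly robust estimators paired with
machine learning are known to underperform doubly robust estimators in
bias, variance and CI coverage; this arm is a model-misspecification
sensitivity check, not the headline estimator, and doubly robust
estimation (TMLE/AIPW) is out of scope.

## Synthetic cohorts and ground truth

The generator emulates the schema and statistical structure the analysis
assumes: categorical confounders sampled from configurable marginals
(independently by default, with an optional ethnicity→income dependence
hook, since no joint distribution is published for the population this
mirrors); age from a truncated normal on [35, 80] (mean 57, SD 12);
exposure as a truncated Gaussian on the physical NDVI range [-1, 1] whose
mean is a linear function of the confounders; continuous biomarkers from
linear models with known exposure slopes β_A, optional exposure×modifier
interaction slopes γ, and Gaussian noise. Ages are centered at 55 inside
every linear predictor so intercepts read as reference-participant means.
Binary metabolic syndrome is, by default, *derived* from the simulated
biomarker components through the same classifier used on real data
(mirroring how the indicator is constructed in practice); a direct
logistic mode is also supported. Missingness is MCAR per field, with
default per-field rates of 0.005 chosen so listwise retention at n = 602
sits near 92%, the scale of attrition typical of clinical cohorts of this
size.

Default magnitudes target the study scale this package was built around:
NDVI mean ≈ 0.17, SD ≈ 0.07; glucose slope −34 mg/dl per NDVI unit
(≈ −15 mg/dl over the ~0.44 max-vs-minimum contrast), with the other
biomarker slopes on the same order. Confounder→exposure coefficients are
not identified by any published quantity; they are deliberate choices set
so confounding is clearly visible — omitting L shifts the crude glucose
slope by well over the 20% documentation floor (about 70% at the
defaults) — and should be treated as arbitrary.

`true_rd` returns the exact causal RD implied by the generating model:
closed form (β_A + γ·1[stratum])·(a − a₀) for continuous outcomes, and
common-random-number Monte Carlo over ≥ 10⁵ confounder draws (with its
Monte-Carlo standard error) for metabolic syndrome, where no closed form
exists. For derived MetS the Monte Carlo simulates the component
biomarkers at both exposure levels with shared noise and classifies both.

What passing tests do and do not show: the generator is linear,
homoscedastic, MCAR, and spatially structureless. Recovery and calibration
results therefore validate the estimation machinery under a correctly
specified model; they say nothing about nonlinear exposure response,
heteroscedastic biomarkers, informative missingness, spatial clustering,
or measurement error in real NDVI exposure.

## Numerical choices and degenerate inputs

- Gaussian fits are closed-form (deterministic); logit fits are IRLS with
  up to 200 iterations and a preserved convergence flag.
- Rank-deficient designs raise an error naming the offending columns
  (e.g. an empty category level) rather than silently dropping them.
- A degenerate exposure distribution (all values equal, or fewer than two
  values) cannot produce a grid and is an error.
- RD at the reference level is exactly 0 by construction, not by
  cancellation.
- One run seed expands into independent child seeds per stage (cohort,
  each outcome's bootstrap, each effect-modification bootstrap, folds) via
  hashed spawn keys, so stages re-run in isolation reproduce exactly and
  the whole result bundle is byte-identical under a repeated seed.

## Problem sizes used in the checks

The test suite's statistical checks run at n = 2000 participants with 500
bootstrap iterations over 200 replicates (bootstrap coverage and null
calibration), 500 replicates at n = 800 with 200 iterations (Cochran Q
type-I error), 100 replicates at n = 2000 (parameter recovery), and
n = 2000 with 10-fold CV at desk-scale tree counts (super-learner
properties). The acceptance script runs the full pipeline once at the
study scale of 602 recruited participants with 1000 bootstrap iterations.

## Known limitations

- Cross-sectional, static exposure only; no longitudinal g-formula.
- Bootstrap ignores recruitment clustering unless a cluster column is
  supplied.
- Binary-outcome RDs are reported as probability differences.
- No multiplicity correction across the outcome × modifier × level lattice
  by default.
- The super-learner arm inherits the singly-robust caveat above.
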