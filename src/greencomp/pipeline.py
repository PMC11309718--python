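"""End-to-end pipeline: cohort (synthetic or user CSV) -> complete-case
filter -> intervention grid -> main GLM g-computation with bootstrap CIs ->
partial-intervention effect modification with Cochran Q -> optional
super-learner arm -> tidy CSV outputs plus a JSON provenance sidecar.

The single run seed is expanded into independent child seeds for the
cohort, each outcome's bootstrap, each effect-modification bootstrap, and
the super learner, so any stage can be re-run in isolation reproducibly
and the whole result bundle is byte-identical under a repeated seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CATEGORICAL_CONFOUNDERS,
    EXPOSURE,
    MODIFIERS,
    OUTCOMES,
    SCHEMA_COLUMNS,
    complete_case_filter,
    intervention_grid,
    load_cohort,
)
from .effectmod import (
    bootstrap_stratum_rds,
    heterogeneity_by_level,
    heterogeneity_to_frame,
    stratum_estimates_to_frame,
)
from .ensemble import DESK_SCALE_LEARNER_PARAMS, sl_gcompute_rds
from .errors import ConfigurationError, PipelineStageError
from .gformula import OutcomeModelSpec, RDEstimate, bootstrap_rds, estimates_to_frame
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` / ``cohort_csv`` selects the input mode.
    ``engine`` chooses the prediction engine(s): the main GLM analysis,
    the super-learner sensitivity arm, or both.
    """

    synthetic: SyntheticConfig | None = None
    cohort_csv: str | None = None
    outcomes: tuple[str, ...] = OUTCOMES
    modifiers: tuple[str, ...] = MODIFIERS
    n_boot: int = 1000
    effectmod_n_boot: int | None = None   # defaults to n_boot
    sl_n_boot: int | None = None          # defaults to n_boot
    seed: int = 0
    engine: str = "glm"                   # glm | superlearner | both
    output_dir: str = "greencomp_out"
    learner_params: dict = field(default_factory=lambda: dict(DESK_SCALE_LEARNER_PARAMS))

    def validate(self) -> None:
        if (self.synthetic is None) == (self.cohort_csv is None):
            raise ConfigurationError("exactly one of synthetic / cohort_csv must be set")
        if not self.outcomes:
            raise ConfigurationError("at least one outcome is required")
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ConfigurationError(f"unknown outcome(s): {sorted(unknown)}")
        unknown = set(self.modifiers) - set(MODIFIERS)
        if unknown:
            raise ConfigurationError(f"unknown modifier(s): {sorted(unknown)}")
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        if self.engine not in ("glm", "superlearner", "both"):
            raise ConfigurationError(f"unknown engine {self.engine!r}")


def _child_seed(ss: np.random.SeedSequence, *key) -> int:
    # stable across processes (no reliance on PYTHONHASHSEED)
    import zlib

    spawn_key = tuple(zlib.crc32(str(k).encode()) for k in key)
    child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=spawn_key)
    return int(child.generate_state(1)[0] % 2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write the result bundle.

    Outputs in ``config.output_dir``: ``rd_glm.csv``,
    ``stratified_rds.csv``, ``heterogeneity.csv``,
    ``complete_case_report.json``, ``provenance.json``, optionally
    ``rd_superlearner.csv``, and ``run.log``.  Any stage error aborts with
    a stage-named message and removes partial outputs.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("greencomp")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "setup"
    t0 = time.time()
    try:
        ss = np.random.SeedSequence(config.seed)
        results: dict = {}

        stage = "cohort"
        if config.synthetic is not None:
            cohort = generate_cohort(config.synthetic)
        else:
            cohort = load_cohort(config.cohort_csv)
        logger.info("stage cohort: %d rows (%.1fs)", len(cohort), time.time() - t0)

        stage = "complete_case"
        required = (EXPOSURE,) + tuple(c for c in SCHEMA_COLUMNS if c in
                                       ("sex", "income", "race", "ethnicity", "age", "education")) \
            + tuple(config.outcomes)
        analysis, report = complete_case_filter(cohort, required)
        path = outdir / "complete_case_report.json"
        report.to_json(path)
        written.append(path)
        results["complete_case_report"] = report
        results["cohort"] = analysis
        logger.info("stage complete_case: retained %d/%d (%.1f%%)",
                    report.n_retained, report.n_input, report.retention_pct)

        stage = "grid"
        grid = intervention_grid(analysis[EXPOSURE])
        results["grid"] = grid
        logger.info("stage grid: %s", grid.describe())

        glm_estimates: list[RDEstimate] = []
        if config.engine in ("glm", "both"):
            stage = "gformula"
            for outcome in config.outcomes:
                spec = OutcomeModelSpec(outcome=outcome)
                glm_estimates.extend(bootstrap_rds(
                    analysis, spec, grid, n_boot=config.n_boot,
                    seed=_child_seed(ss, "boot", outcome),
                ))
            frame = estimates_to_frame(glm_estimates, engine="glm")
            path = outdir / "rd_glm.csv"
            frame.to_csv(path, index=False)
            written.append(path)
            results["rd_glm"] = frame

            stage = "effectmod"
            strat_rows, het_rows = [], []
            em_boot = config.effectmod_n_boot or config.n_boot
            for outcome in config.outcomes:
                spec = OutcomeModelSpec(outcome=outcome)
                for modifier in config.modifiers:
                    ests = bootstrap_stratum_rds(
                        analysis, spec, modifier, grid, n_boot=em_boot,
                        seed=_child_seed(ss, "effectmod", outcome, modifier),
                    )
                    strat_rows.append(stratum_estimates_to_frame(ests))
                    het_rows.append(heterogeneity_to_frame(heterogeneity_by_level(ests)))
            if strat_rows:
                strat = pd.concat(strat_rows, ignore_index=True)
                het = pd.concat(het_rows, ignore_index=True)
                for name, frame_ in (("stratified_rds.csv", strat), ("heterogeneity.csv", het)):
                    path = outdir / name
                    frame_.to_csv(path, index=False)
                    written.append(path)
                results["stratified_rds"] = strat
                results["heterogeneity"] = het

        if config.engine in ("superlearner", "both"):
            stage = "superlearner"
            sl_estimates: list[RDEstimate] = []
            for outcome in config.outcomes:
                spec = OutcomeModelSpec(outcome=outcome)
                sl_estimates.extend(sl_gcompute_rds(
                    analysis, spec, grid,
                    n_boot=config.sl_n_boot or config.n_boot,
                    seed=_child_seed(ss, "superlearner", outcome),
                    learner_params=config.learner_params,
                ))
            frame = estimates_to_frame(sl_estimates, engine="superlearner")
            path = outdir / "rd_superlearner.csv"
            frame.to_csv(path, index=False)
            written.append(path)
            results["rd_superlearner"] = frame

        stage = "provenance"
        prov = {
            "package_version": __version__,
            "seed": config.seed,
            "n_boot": config.n_boot,
            "engine": config.engine,
            "outcomes": list(config.outcomes),
            "modifiers": list(config.modifiers),
            "grid": {"reference": grid.reference, "levels": list(grid.levels)},
            "reference_categories": {k: v[0] for k, v in CATEGORICAL_CONFOUNDERS.items()},
            "failed_refits": {
                "glm": int(max((e.n_failed for e in glm_estimates), default=0)),
            },
            "learner_params": config.learner_params if config.engine != "glm" else None,
            "n_input": report.n_input,
            "n_analysis": report.n_retained,
        }
        path = outdir / "provenance.json"
        with open(path, "w") as fh:
            json.dump(prov, fh, indent=2, sort_keys=True)
        written.append(path)
        results["provenance"] = prov

        stage = "validate_outputs"
        for path in written:
            if path.suffix == ".csv":
                pd.read_csv(path)  # round-trip check
        logger.info("pipeline complete in %.1fs", time.time() - t0)
        return results
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineStageError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def make_rd_table(estimates: list[RDEstimate]) -> pd.DataFrame:
    """Human-readable RD table: one row per (outcome, level), sorted by
    outcome then level, with ``"rd (ci_low, ci_high)"`` to 2 decimals."""
    if not estimates:
        raise ConfigurationError("no estimates to tabulate")
    rows = sorted(estimates, key=lambda e: (e.outcome, e.level))
    return pd.DataFrame(
        {
            "outcome": [e.outcome for e in rows],
            "level": [e.level for e in rows],
            "rd_95ci": [f"{e.rd:.2f} ({e.ci_low:.2f}, {e.ci_high:.2f})" for e in rows],
        }
    )
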