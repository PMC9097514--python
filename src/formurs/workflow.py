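"""End-to-end formulation-optimization workflow.

``run_paper_workflow`` chains the pipeline stages — per-response model
fit, ANOVA with lack-of-fit, five-fold cross-validation, test-set Q²,
desirability-based multi-response optimization and inverse size
targeting — into one reproducible report.  Stages are logged to stderr;
a missing test table skips the Q² stage with a notice instead of
failing; any stage error aborts with the stage name and cause.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import datasets
from .design_space import DesignTable
from .desirability import DesirabilitySpec, inverse_target, optimize_mro
from .response_surface import (FittedModel, ModelSpec, anova, fit_ols,
                               kfold_cv, stepwise_select, test_set_q2)

__all__ = ["PipelineConfig", "WorkflowError", "run_paper_workflow",
           "default_goals", "report_to_json"]

log = logging.getLogger("formurs.workflow")


class WorkflowError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


_KNOWN_KEYS = {"responses", "mode", "term_sets", "goals", "grid", "seed",
               "cv_folds", "size_targets", "q2_method"}


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_paper_workflow`.

    ``mode`` is "fixed" (fit the reported term sets verbatim) or
    "stepwise" (re-select terms from the full quadratic candidate set).
    ``goals`` defaults to: minimize size and PDI, maximize ZP and EE,
    with bounds set to each response's observed training range.
    """

    responses: tuple[str, ...] = datasets.RESPONSES
    mode: str = "fixed"
    term_sets: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(datasets.REPORTED_TERM_SETS))
    goals: Sequence[DesirabilitySpec] | None = None
    grid: int = 41
    seed: int = 0
    cv_folds: int = 5
    size_targets: tuple[float, ...] = (100.0, 200.0)
    q2_method: str = "correlation"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "stepwise"):
            raise ValueError("mode must be 'fixed' or 'stepwise'")
        if self.mode == "fixed":
            missing = [r for r in self.responses if r not in self.term_sets]
            if missing:
                raise ValueError(f"fixed mode lacks term sets for {missing}")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PipelineConfig":
        unknown = set(payload) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**payload)


def default_goals(train: DesignTable) -> list[DesirabilitySpec]:
    """Minimize size/PDI, maximize ZP/EE; bounds = observed training ranges."""
    goals = []
    for resp, goal in (("size", "minimize"), ("PDI", "minimize"),
                       ("ZP", "maximize"), ("EE", "maximize")):
        y = train.response(resp)
        lo, hi = float(y.min()), float(y.max())
        bounds = (hi, lo) if goal == "minimize" else (lo, hi)
        goals.append(DesirabilitySpec(resp, goal, bounds))
    return goals


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise WorkflowError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("fit")
def _fit_models(train: DesignTable, config: PipelineConfig) -> dict[str, FittedModel]:
    models = {}
    for resp in config.responses:
        if config.mode == "fixed":
            spec = ModelSpec.from_strings(resp, config.term_sets[resp])
        else:
            spec = stepwise_select(train, resp)
        models[resp] = fit_ols(train, spec)
    return models


def run_paper_workflow(config: PipelineConfig,
                       train: DesignTable | None = None,
                       test: DesignTable | None = None,
                       descriptor_stage=None) -> dict:
    """Run fit -> ANOVA -> CV -> Q2 -> MRO -> inverse targets; return the report.

    ``train`` defaults to the packaged 17-run training design; pass
    ``test=None`` explicitly with ``skip_test=True`` semantics by
    loading no test table — the Q² stage is then skipped and logged.
    The report is a plain JSON-serializable dict with no timestamps, so
    re-running an identical configuration reproduces it byte for byte.
    """
    if train is None:
        train = datasets.load_training_design()
        if test is None:
            test = datasets.load_test_design()

    models = _fit_models(train, config)

    report: dict = {"config": {"mode": config.mode, "grid": config.grid,
                               "seed": config.seed, "cv_folds": config.cv_folds,
                               "q2_method": config.q2_method},
                    "models": {}}

    for resp, fitted in models.items():
        tbl = _stage("anova")(anova)(fitted, train)
        model_row = tbl.row("model")
        cv = _stage("cv")(kfold_cv)(train, fitted.spec, k=config.cv_folds,
                                    seed=config.seed)
        entry = {
            "terms": fitted.spec.labels,
            "coefficients_coded": fitted.coefficients,
            "coefficients_raw": fitted.raw_coefficients(),
            "r2": fitted.r2,
            "anova": {
                "rows": json.loads(tbl.table.to_json(orient="records")),
                "model_F": None if np.isnan(model_row["F"]) else float(model_row["F"]),
                "model_p": None if np.isnan(model_row["p"]) else float(model_row["p"]),
            },
            "cv_rmse": cv,
        }
        if test is not None:
            entry["q2_test"] = _stage("q2")(test_set_q2)(fitted, test,
                                                         method=config.q2_method)
        report["models"][resp] = entry
    if test is None:
        log.info("no test table: Q2 stage skipped")
        report["q2_skipped"] = True

    goals = config.goals if config.goals is not None else default_goals(train)
    mro = _stage("mro")(optimize_mro)(models, goals, grid=config.grid)
    report["optimum"] = {
        "settings_raw": mro.argmax_raw,
        "settings_coded": mro.argmax_coded,
        "overall_desirability": mro.overall_D,
        "per_response": {r: {"predicted": p, "d": d}
                         for r, (p, d) in mro.per_response.items()},
    }

    report["size_targets"] = {}
    for target in config.size_targets:
        res = _stage("inverse_target")(inverse_target)(
            models, ("size", target), ("PDI", "minimize"), grid=config.grid)
        report["size_targets"][str(int(target))] = {
            "settings_raw": res.settings_raw,
            "predicted_size": res.predicted_primary,
            "predicted_PDI": res.predicted_secondary,
            "feasible": res.feasible,
        }

    if descriptor_stage is not None:
        report["descriptor_screen"] = _stage("screen")(descriptor_stage)()
    return report


def report_to_json(report: dict, path=None) -> str:
    text = json.dumps(report, indent=1, sort_keys=True, default=float)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
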