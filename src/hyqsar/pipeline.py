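"""Experiment-grid orchestration.

Runs the full comparative design: every (descriptor subset x learner x split
x task) scenario on one dataset, with per-scenario seeds derived stably from
the root seed so adding scenarios never perturbs existing ones. Summaries
count the scenarios where hybrid (combined) subsets strictly outperform both
of their parent subsets, and extract the best model per task.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemio import DescriptorTable
from .feature_select import DescriptorSubset
from .qsar_harness import (
    DiscretizationRule,
    EvaluationReport,
    LearnerSpec,
    SplitSpec,
    evaluate_classification,
    evaluate_regression,
    split_dataset,
    train_predict,
)

__all__ = ["ExperimentConfig", "run_experiment", "summarize_reports"]

logger = logging.getLogger("hyqsar")


@dataclass
class ExperimentConfig:
    """One dataset's experiment grid."""

    table: DescriptorTable                    # numeric target attached
    subsets: list[DescriptorSubset]
    learners: list[LearnerSpec]
    splits: list[float]                       # training fractions
    tasks: list[str] = field(default_factory=lambda: ["regression"])
    classification_rule: Optional[DiscretizationRule] = None
    dataset_name: str = "dataset"
    root_seed: int = 0
    output_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if not (self.subsets and self.learners and self.splits and self.tasks):
            raise ValueError("need at least one subset, learner, split and task")
        for t in self.tasks:
            if t not in ("regression", "classification"):
                raise ValueError(f"unknown task {t!r}")
        if "classification" in self.tasks and self.classification_rule is None:
            raise ValueError("classification tasks need a discretization rule")


def _scenario_seed(root: int, key: str) -> int:
    return (root + zlib.crc32(key.encode("utf-8"))) % (2**31)


def _run_scenario(config: ExperimentConfig, subset: DescriptorSubset,
                  learner: LearnerSpec, split_fraction: float, task: str
                  ) -> EvaluationReport:
    key = f"{subset.name}|{learner.family}|{split_fraction}|{task}"
    seed = _scenario_seed(config.root_seed, key)
    sub = config.table.subset(subset.descriptors)
    spec = LearnerSpec(**{**learner.__dict__, "seed": seed})

    if task == "regression":
        split = SplitSpec(split_fraction, stratified=False, seed=seed)
        train, test = split_dataset(sub, split)
        pred = train_predict(train, test, spec, task="regression")
        metrics = evaluate_regression(pred, test.target.to_numpy(dtype=float),
                                      float(train.target.mean()))
    else:
        rule = config.classification_rule
        labels = pd.Series(rule.apply(sub.target.to_numpy(dtype=float)),
                           index=sub.values.index, name=rule.property_name)
        sub = sub.with_target(labels, rule.property_name)
        split = SplitSpec(split_fraction, stratified=True, seed=seed)
        train, test = split_dataset(sub, split)
        class_order = rule.class_labels()
        probs, class_order = train_predict(train, test, spec,
                                           task="classification",
                                           class_order=class_order)
        y_train = np.asarray(pd.Series(train.target).astype(str))
        freq = np.array([np.mean(y_train == c) for c in class_order])
        metrics = evaluate_classification(probs.to_numpy(), test.target,
                                          freq, class_order)
    logger.info("scenario %s | seed %d | %s", key, seed,
                {k: v for k, v in metrics.items() if k != "confusion_matrix"})
    return EvaluationReport(task=task, subset=subset.name,
                            learner=learner.family, split=split_fraction,
                            metrics=metrics, dataset=config.dataset_name,
                            seed=seed)


def run_experiment(config: ExperimentConfig) -> tuple[list[EvaluationReport], dict]:
    """Run the full grid; a failing scenario is logged and skipped, not fatal.

    Returns (reports, summary). The summary counts, per task, the scenarios
    (learner x split) in which each combined subset strictly outperforms both
    of its parents on the primary metric (CC for regression, %CC for
    classification).
    """
    reports: list[EvaluationReport] = []
    failures: list[dict] = []
    for subset in config.subsets:
        for learner in config.learners:
            for fraction in config.splits:
                for task in config.tasks:
                    try:
                        reports.append(_run_scenario(config, subset, learner,
                                                     fraction, task))
                    except Exception as exc:  # scenario-local failure
                        key = f"{subset.name}|{learner.family}|{fraction}|{task}"
                        logger.warning("scenario %s failed: %s", key, exc)
                        failures.append({"scenario": key, "error": str(exc)})
    summary = _combined_wins(config, reports)
    summary["n_reports"] = len(reports)
    summary["failures"] = failures
    if config.output_dir is not None:
        _write_artifacts(config, reports, summary)
    return reports, summary


def _primary_metric(report: EvaluationReport) -> float:
    return report.metrics["CC"] if report.task == "regression" else report.metrics["%CC"]


def _combined_wins(config: ExperimentConfig, reports: list[EvaluationReport]) -> dict:
    by_key = {(r.subset, r.learner, r.split, r.task): r for r in reports}
    parents = {s.name: s.parents for s in config.subsets if s.provenance == "combined"}
    wins: dict[str, dict[str, int]] = {}
    for task in config.tasks:
        w = total = 0
        for name, (pa, pb) in parents.items():
            for learner in config.learners:
                for fraction in config.splits:
                    combined = by_key.get((name, learner.family, fraction, task))
                    a = by_key.get((pa, learner.family, fraction, task))
                    b = by_key.get((pb, learner.family, fraction, task))
                    if combined is None or a is None or b is None:
                        continue
                    total += 1
                    if (_primary_metric(combined) > _primary_metric(a)
                            and _primary_metric(combined) > _primary_metric(b)):
                        w += 1
        wins[task] = {"combined_wins": w, "comparable_scenarios": total}
    return {"hybridization": wins}


def _write_artifacts(config: ExperimentConfig, reports, summary) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)
    for i, r in enumerate(reports):
        with open(out / "reports" / f"scenario_{i:03d}.json", "w", encoding="utf-8") as fh:
            json.dump(r.flat(), fh, indent=1)
    flat, _best = summarize_reports(reports)
    flat.to_csv(out / "summary.csv", index=False)
    with open(out / "run.json", "w", encoding="utf-8") as fh:
        json.dump({"root_seed": config.root_seed, "summary": summary}, fh, indent=1)


def summarize_reports(reports: Sequence[EvaluationReport]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten all reports to one row per scenario and extract the best model
    per (dataset, task): best regression by CC, best classification by %CC,
    ties broken by lower RRSE then input order."""
    if not reports:
        raise ValueError("no reports to summarize")
    flat = pd.DataFrame([r.flat() for r in reports])
    best_rows = []
    for (dataset, task), group in flat.groupby(["dataset", "task"], sort=False):
        metric = "CC" if task == "regression" else "%CC"
        g = group.reset_index()  # keep input order for the final tie-break
        order = sorted(range(len(g)),
                       key=lambda i: (-g.loc[i, metric], g.loc[i, "RRSE"], i))
        best_rows.append(g.loc[order[0]].drop(labels="index"))
    best = pd.DataFrame(best_rows).reset_index(drop=True)
    return flat, best
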