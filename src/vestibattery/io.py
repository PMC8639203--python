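"""Cohort CSV schema, pipeline configuration and end-to-end orchestration.

Cohorts are RFC-4180 CSV (UTF-8, "." decimal): one row per patient,
header from :data:`~vestibattery.cohort.COHORT_COLUMNS`, empty cell =
missing, ``true_diagnosis`` one of PPPD/CDA/UVH/UD/OTHER and
``cus_present`` True/False/empty. Machine reports are JSON; the human
summary is markdown.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import algorithms, comparison, roc
from .cohort import COHORT_COLUMNS, complete_case_mask, generate_cohort, load_params
from .instruments import ScoreValidationError, validate_scores
from .reference import BATTERY_THRESHOLDS

__all__ = ["PipelineConfig", "read_cohort", "write_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)

_LABELS = {"PPPD", "CDA", "UVH", "UD", "OTHER"}
_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


class PipelineConfig(BaseModel):
    """Validated configuration for the full pipeline; round-trips via JSON/YAML."""

    seed: int = 0
    scale: float = Field(default=1.0, gt=0)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    thresholds: Optional[dict[str, float]] = None  # overrides skip ROC derivation
    combinator: Literal["ANY", "ALL"] = "ANY"
    missing_policy: Literal["complete_required", "missing_negative"] = "complete_required"
    auc_ci_method: Literal["delong", "bootstrap"] = "delong"
    outdir: str = "results"
    params_file: Optional[str] = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.model_validate(yaml.safe_load(text))
        return cls.model_validate(json.loads(text))

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=2), encoding="utf-8")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV (missing as empty cells, deterministic layout)."""
    cohort.to_csv(path, index=False, float_format="%.10g")


def read_cohort(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Every row passes questionnaire range/additivity validation; in strict
    mode a malformed row aborts with its row number, otherwise it is
    dropped with a warning. Unknown columns are rejected in strict mode.
    """
    df = pd.read_csv(path, dtype={"id": str, "true_diagnosis": str, "cus_present": str})
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        if strict:
            raise ValueError(f"unknown columns: {unknown}")
        logger.warning("ignoring unknown columns: %s", unknown)
        df = df.drop(columns=unknown)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    for c in missing_cols:
        df[c] = np.nan
    cus = df["cus_present"].astype(str).str.strip().str.lower().map(_BOOL_MAP)
    df["cus_present"] = pd.array(cus, dtype="boolean")
    for col in COHORT_COLUMNS:
        if col in ("id", "true_diagnosis", "cus_present"):
            continue
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)

    bad_rows = []
    for idx, row in df.iterrows():
        problem = None
        if row["true_diagnosis"] not in _LABELS:
            problem = f"unknown diagnosis {row['true_diagnosis']!r}"
        else:
            try:
                validate_scores(row)
            except ScoreValidationError as exc:
                problem = str(exc)
        if problem:
            if strict:
                raise ValueError(f"row {idx + 2}: {problem}")  # +2: header + 1-based
            logger.warning("skipping row %d: %s", idx + 2, problem)
            bad_rows.append(idx)
    if bad_rows:
        df = df.drop(index=bad_rows).reset_index(drop=True)
    logger.info("read %d records from %s (%d rejected)", len(df), path, len(bad_rows))
    return df[COHORT_COLUMNS]


def _comparison_json(results, shortlist) -> dict:
    return {
        "shortlist": shortlist,
        "items": [
            {
                "item": r.item, "H": r.H, "df": r.df, "p_kw": r.p_kw,
                "significant_overall": r.significant_overall,
                "pairwise": {
                    f"{a}-{b}": {"z": z, "p_adjusted": p}
                    for (a, b), (z, p) in r.pairwise.items()
                },
                "significant_pairs": sorted(f"{a}-{b}" for a, b in r.significant_pairs),
            }
            for r in results
        ],
    }


def _comparison_markdown(results, shortlist) -> str:
    lines = [
        "# Group comparison (Kruskal–Wallis across PPPD/CDA/UVH/UD)",
        "",
        "| Item | H | df | p | Significant pairs (Dunn–Bonferroni) |",
        "|---|---|---|---|---|",
    ]
    for r in results:
        pairs = ", ".join(sorted(f"{a} vs {b}" for a, b in r.significant_pairs)) or "-"
        lines.append(f"| {r.item} | {r.H:.3f} | {r.df} | {r.p_kw:.4g} | {pairs} |")
    lines += ["", f"Battery shortlist: {', '.join(shortlist) or '(none)'}", ""]
    return "\n".join(lines)


def _evaluation_markdown(reports: dict[int, algorithms.EvaluationReport]) -> str:
    lines = ["# Sequential algorithm evaluation", ""]
    for number, rep in sorted(reports.items()):
        lines += [
            f"## {rep.algorithm}",
            "",
            f"Evaluated {rep.n_evaluated} complete-case patients "
            f"({rep.n_excluded_incomplete} excluded).",
            "",
            rep.confusion.to_markdown(),
            "",
            "Per-class recall (%): "
            + ", ".join(f"{d} {v}" for d, v in rep.per_class_recall.items()),
            f"Overall accuracy excluding UD: {rep.overall_accuracy_excl_UD}%",
            "",
        ]
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, compare, derive thresholds, evaluate all six algorithms.

    Writes cohort.csv, comparison.json/.md, roc_<item>.csv, battery.json,
    evaluation.json and summary.md to ``config.outdir`` and returns the
    report bundle as a dict. Fully deterministic given the seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage: simulate (seed=%d, scale=%g)", config.seed, config.scale)
    params = load_params(config.params_file) if config.params_file else None
    cohort = generate_cohort(params, seed=config.seed, scale=config.scale)
    write_cohort(cohort, outdir / "cohort.csv")

    logger.info("stage: group comparison")
    results, shortlist = comparison.compare_all_items(cohort, alpha=config.alpha)
    (outdir / "comparison.json").write_text(
        json.dumps(_comparison_json(results, shortlist), indent=2)
    )
    (outdir / "comparison.md").write_text(_comparison_markdown(results, shortlist))

    battery_summary: dict = {}
    if config.thresholds is not None:
        logger.info("stage: thresholds (overridden; ROC derivation skipped)")
        thresholds = dict(BATTERY_THRESHOLDS)
        thresholds.update(config.thresholds)
    else:
        logger.info("stage: ROC threshold derivation")
        battery = roc.derive_battery(cohort, ci_method=config.auc_ci_method)
        thresholds = {item: ra.youden_threshold for item, ra in battery.items()}
        for item, ra in battery.items():
            pd.DataFrame(
                ra.points, columns=["threshold", "sensitivity", "specificity"]
            ).to_csv(outdir / f"roc_{item}.csv", index=False)
            battery_summary[item] = {
                "target_disease": ra.target_disease,
                "orientation": ra.orientation,
                "auc": ra.auc,
                "auc_ci_95": list(ra.auc_ci_95),
                "youden_threshold": ra.youden_threshold,
                "youden_sensitivity": ra.youden_sensitivity,
                "youden_specificity": ra.youden_specificity,
            }
        (outdir / "battery.json").write_text(json.dumps(battery_summary, indent=2))

    logger.info("stage: algorithm evaluation")
    blocks = algorithms.build_blocks(thresholds, combinator=config.combinator)
    algos = algorithms.enumerate_algorithms(blocks)
    reports = {
        n: algorithms.evaluate(a, cohort, missing_policy=config.missing_policy)
        for n, a in algos.items()
    }
    evaluation = {
        str(n): {
            "per_class_recall": rep.per_class_recall,
            "overall_accuracy_excl_UD": rep.overall_accuracy_excl_UD,
            "n_evaluated": rep.n_evaluated,
            "confusion": {
                str(t): {str(p): int(v) for p, v in row.items()}
                for t, row in rep.confusion.to_dict(orient="index").items()
            },
        }
        for n, rep in reports.items()
    }
    (outdir / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
    (outdir / "summary.md").write_text(
        _comparison_markdown(results, shortlist) + "\n" + _evaluation_markdown(reports)
    )
    return {
        "cohort_n": len(cohort),
        "complete_case_n": int(complete_case_mask(cohort).sum()),
        "shortlist": shortlist,
        "thresholds": thresholds,
        "battery": battery_summary,
        "evaluation": evaluation,
    }
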