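"""Sequential threshold-rule classifiers for chronic vestibular syndromes.

Three disease rule-blocks are assembled from the derived battery:

* PPPD — total NPQ score and visual-stimulation NPQ score at/above their
  thresholds;
* UVH — CP% at/above its threshold, or catch-up saccades present on the
  vHIT;
* CDA — HADS anxiety score at/above its threshold, or age below its
  threshold (CDA patients are younger).

The six algorithms are the 3! orderings of these blocks; a patient is
assigned the disease of the first positive block, and undifferentiated
dizziness (UD) if none fires. Evaluation restricts to complete-case
records, reports a confusion matrix and per-class recall, and the
overall accuracy over patients whose true diagnosis is PPPD, UVH or CDA
(UD-true patients are excluded from the overall figure, as they can
only be "diagnosed" by exclusion).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Any, Literal, Mapping, Optional

import numpy as np
import pandas as pd

from .cohort import REQUIRED_ITEMS, complete_case_mask
from .instruments import is_missing
from .reference import ALGORITHM_ORDERS, BATTERY_THRESHOLDS

__all__ = [
    "Criterion",
    "RuleBlock",
    "DiagnosticAlgorithm",
    "EvaluationReport",
    "build_blocks",
    "default_blocks",
    "enumerate_algorithms",
    "classify",
    "evaluate",
    "aggregate_overall",
    "IncompleteRecordError",
]

DISEASES = ("PPPD", "CDA", "UVH", "UD")
Direction = Literal["ge", "lt", "is_true"]
Combinator = Literal["ANY", "ALL"]


class IncompleteRecordError(ValueError):
    """A required battery item is missing under the complete_required policy."""


@dataclass(frozen=True)
class Criterion:
    """A single threshold test on one item.

    ``ge``: positive when value >= threshold; ``lt``: positive when
    value < threshold; ``is_true``: positive when the boolean item is
    true (missing counts as false — e.g. no vHIT performed means no
    catch-up saccades observed).
    """

    item: str
    direction: Direction
    threshold: float = float("nan")

    def is_met(self, record: Mapping[str, Any]) -> bool:
        v = record.get(self.item)
        if self.direction == "is_true":
            return bool(v) if not is_missing(v) else False
        if is_missing(v):
            return False
        if self.direction == "ge":
            return float(v) >= self.threshold
        if self.direction == "lt":
            return float(v) < self.threshold
        raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class RuleBlock:
    """One disease's criteria, combined with OR (``ANY``) or AND (``ALL``)."""

    disease: str
    criteria: tuple[Criterion, ...]
    combinator: Combinator = "ANY"

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValueError("a rule block needs at least one criterion")

    def is_positive(self, record: Mapping[str, Any]) -> bool:
        met = (c.is_met(record) for c in self.criteria)
        return any(met) if self.combinator == "ANY" else all(met)


@dataclass(frozen=True)
class DiagnosticAlgorithm:
    """An ordered permutation of the three disease blocks; fallback UD."""

    name: str
    blocks: tuple[RuleBlock, ...]
    fallback: str = "UD"

    def __post_init__(self) -> None:
        diseases = [b.disease for b in self.blocks]
        if len(set(diseases)) != len(diseases):
            raise ValueError("each disease may appear in only one block")


@dataclass
class EvaluationReport:
    """Accuracy summary of one algorithm on a labeled cohort."""

    algorithm: str
    confusion: pd.DataFrame  # rows: true, columns: predicted
    per_class_recall: dict[str, float]  # percent
    overall_accuracy_excl_UD: float  # percent
    n_evaluated: int
    n_excluded_incomplete: int


def build_blocks(
    battery: Mapping[str, Any],
    combinator: Combinator = "ANY",
) -> tuple[RuleBlock, RuleBlock, RuleBlock]:
    """Assemble the PPPD, UVH and CDA rule blocks from derived thresholds.

    ``battery`` maps item name to either a threshold (float) or a
    :class:`~vestibattery.roc.RocAnalysis` (its ``youden_threshold`` is
    used). All five battery items must be present.
    """
    def thr(item: str) -> float:
        entry = battery[item]
        t = getattr(entry, "youden_threshold", entry)
        return float(t)

    missing = [i for i in BATTERY_THRESHOLDS if i not in battery]
    if missing:
        raise KeyError(f"battery is missing entries for {missing}")
    pppd = RuleBlock(
        "PPPD",
        (
            Criterion("NPQ_total", "ge", thr("NPQ_total")),
            Criterion("NPQ_visual", "ge", thr("NPQ_visual")),
        ),
        combinator,
    )
    uvh = RuleBlock(
        "UVH",
        (
            Criterion("CP_percent", "ge", thr("CP_percent")),
            Criterion("cus_present", "is_true"),
        ),
        combinator,
    )
    cda = RuleBlock(
        "CDA",
        (
            Criterion("HADS_anxiety", "ge", thr("HADS_anxiety")),
            Criterion("age", "lt", thr("age")),
        ),
        combinator,
    )
    return pppd, uvh, cda


def default_blocks(combinator: Combinator = "ANY") -> tuple[RuleBlock, ...]:
    """Rule blocks at the published thresholds (CP% 19.8, NPQ 33.5/10.5,
    HADS-A 8.5, age 48.5)."""
    return build_blocks(BATTERY_THRESHOLDS, combinator)


def enumerate_algorithms(
    blocks: tuple[RuleBlock, RuleBlock, RuleBlock],
) -> dict[int, DiagnosticAlgorithm]:
    """All six orderings, numbered by the conventional scheme:

    1 PPPD-UVH-CDA, 2 PPPD-CDA-UVH, 3 UVH-PPPD-CDA, 4 UVH-CDA-PPPD,
    5 CDA-PPPD-UVH, 6 CDA-UVH-PPPD (1-2 diagnose PPPD first, 3-4 UVH
    first, 5-6 CDA first).
    """
    by_disease = {b.disease: b for b in blocks}
    if set(by_disease) != {"PPPD", "UVH", "CDA"}:
        raise ValueError("expected exactly one block each for PPPD, UVH and CDA")
    out: dict[int, DiagnosticAlgorithm] = {}
    for number, order in ALGORITHM_ORDERS.items():
        out[number] = DiagnosticAlgorithm(
            name=f"Algorithm {number}",
            blocks=tuple(by_disease[d] for d in order),
        )
    assert len(out) == len(list(permutations("abc")))
    return out


MissingPolicy = Literal["complete_required", "missing_negative"]


def classify(
    record: Mapping[str, Any],
    algorithm: DiagnosticAlgorithm,
    missing_policy: MissingPolicy = "complete_required",
) -> str:
    """Sequentially evaluate the blocks; first positive wins, else UD.

    Under ``complete_required`` a record missing any required battery
    item raises :class:`IncompleteRecordError` (such patients are
    excluded from evaluation); under ``missing_negative`` missing values
    simply fail their criteria.
    """
    if missing_policy == "complete_required":
        absent = [i for i in REQUIRED_ITEMS if is_missing(record.get(i))]
        if absent:
            raise IncompleteRecordError(f"missing required items: {absent}")
    for block in algorithm.blocks:
        if block.is_positive(record):
            return block.disease
    return algorithm.fallback


def evaluate(
    algorithm: DiagnosticAlgorithm,
    cohort: pd.DataFrame,
    missing_policy: MissingPolicy = "complete_required",
) -> EvaluationReport:
    """Classify a labeled cohort and summarize diagnostic accuracy.

    Only the four major diagnoses enter; under ``complete_required`` the
    cohort is first restricted to complete-case records. The overall
    accuracy is computed over patients whose true label is PPPD, UVH or
    CDA (UD recall is still reported separately).
    """
    df = cohort[cohort["true_diagnosis"].isin(DISEASES)]
    n_before = len(df)
    if missing_policy == "complete_required":
        df = df[complete_case_mask(df)]
    if df.empty:
        raise ValueError("no evaluable records")
    preds = [classify(row, algorithm, missing_policy="missing_negative")
             for row in df.to_dict("records")]
    truth = df["true_diagnosis"].to_numpy()
    confusion = pd.crosstab(
        pd.Categorical(truth, categories=DISEASES),
        pd.Categorical(preds, categories=DISEASES),
        rownames=["true"], colnames=["predicted"], dropna=False,
    )
    recall = {
        d: (100.0 * confusion.loc[d, d] / confusion.loc[d].sum())
        if confusion.loc[d].sum() else float("nan")
        for d in DISEASES
    }
    correct = {d: int(confusion.loc[d, d]) for d in ("PPPD", "UVH", "CDA")}
    totals = {d: int(confusion.loc[d].sum()) for d in ("PPPD", "UVH", "CDA")}
    return EvaluationReport(
        algorithm=algorithm.name,
        confusion=confusion,
        per_class_recall={d: float(round(r, 1)) for d, r in recall.items()},
        overall_accuracy_excl_UD=aggregate_overall(correct, totals),
        n_evaluated=len(df),
        n_excluded_incomplete=n_before - len(df),
    )


def aggregate_overall(
    per_class_correct: Mapping[str, int],
    per_class_n: Mapping[str, int],
    exclude: str = "UD",
) -> float:
    """Pooled accuracy 100 x sum(correct) / sum(n) over the non-excluded
    classes, rounded to one decimal."""
    num = den = 0
    for cls, n in per_class_n.items():
        if cls == exclude:
            continue
        c = per_class_correct.get(cls, 0)
        if c < 0 or n < 0 or c > n:
            raise ValueError(f"invalid counts for class {cls}: {c}/{n}")
        num += c
        den += n
    if den == 0:
        raise ValueError("no patients in the non-excluded classes")
    return round(100.0 * num / den, 1)


def recalls_to_counts(recalls: Mapping[str, float], sizes: Mapping[str, int]) -> dict[str, int]:
    """Convert per-class recall percentages to integer correct counts
    (nearest integer), for re-aggregating published accuracy figures."""
    return {d: int(round(recalls[d] / 100.0 * sizes[d])) for d in recalls}
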