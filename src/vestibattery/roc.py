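"""ROC curves, AUC with DeLong confidence intervals, and Youden cutpoints.

One-vs-rest ROC analysis for each battery item. Candidate thresholds
are midpoints between adjacent distinct observed scores (plus infinite
endpoints), which is why questionnaire and age cutpoints come out as
half-integers. The operating point maximizing the Youden index
J = sensitivity + specificity - 1 is adopted as the diagnostic
threshold. AUC is the Mann–Whitney concordance probability
(concordant pairs + half the ties, over all target x rest pairs); its
95% CI uses DeLong's placement-value variance estimate, with a
stratified bootstrap available as an alternative.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocAnalysis",
    "roc_points",
    "auc",
    "auc_ci",
    "youden_threshold",
    "derive_battery",
    "BATTERY_TARGETS",
]

Orientation = Literal["greater_indicates_target", "less_indicates_target"]

#: battery item -> (target disease, orientation); age points the other
#: way because CDA patients are markedly younger than UVH/UD patients.
BATTERY_TARGETS: dict[str, tuple[str, Orientation]] = {
    "CP_percent": ("UVH", "greater_indicates_target"),
    "NPQ_total": ("PPPD", "greater_indicates_target"),
    "NPQ_visual": ("PPPD", "greater_indicates_target"),
    "HADS_anxiety": ("CDA", "greater_indicates_target"),
    "age": ("CDA", "less_indicates_target"),
}


@dataclass
class RocAnalysis:
    """Full ROC summary for one item against a one-vs-rest target."""

    target_disease: str
    item: str
    orientation: Orientation
    points: list[tuple[float, float, float]]  # (threshold, sensitivity, specificity)
    auc: float
    auc_ci_95: tuple[float, float]
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float

    @property
    def J(self) -> float:
        return self.youden_sensitivity + self.youden_specificity - 1.0


def _prepare(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if np.any(np.isnan(s)):
        raise ValueError("scores must be non-missing")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return s, y


def _oriented(s: np.ndarray, orientation: Orientation) -> np.ndarray:
    if orientation == "greater_indicates_target":
        return s
    if orientation == "less_indicates_target":
        return -s
    raise ValueError(f"unknown orientation {orientation!r}")


def roc_points(
    scores: Sequence[float],
    labels: Sequence[bool],
    orientation: Orientation = "greater_indicates_target",
) -> list[tuple[float, float, float]]:
    """All ROC operating points as (threshold, sensitivity, specificity).

    A patient is called positive when the score is on the disease side of
    the threshold: ``score >= t`` under the greater orientation,
    ``score < t`` under the less orientation (midpoint thresholds make the
    boundary unobservable either way). Candidate thresholds are midpoints
    of adjacent distinct observed values plus -inf/+inf.
    """
    s, y = _prepare(scores, labels)
    so = _oriented(s, orientation)
    uniq = np.unique(so)
    internal = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    points = []
    for t in internal:
        sens = float(np.mean(so[y] >= t))
        spec = float(np.mean(so[~y] < t))
        thr = float(t) if orientation == "greater_indicates_target" else float(-t)
        points.append((thr, sens, spec))
    return points


def auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    orientation: Orientation = "greater_indicates_target",
) -> float:
    """AUC as the Mann–Whitney concordance probability.

    (number of target/rest pairs ranked correctly + 0.5 x ties) divided
    by n_target x n_rest; identical to the trapezoidal area under
    :func:`roc_points`.
    """
    s, y = _prepare(scores, labels)
    so = _oriented(s, orientation)
    ranks = stats.rankdata(so)
    n_t = int(y.sum())
    n_r = y.size - n_t
    return float((ranks[y].sum() - n_t * (n_t + 1) / 2.0) / (n_t * n_r))


def _placements(so: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tgt, rest = so[y], so[~y]
    psi = (tgt[:, None] > rest[None, :]).astype(float)
    psi += 0.5 * (tgt[:, None] == rest[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


def auc_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    orientation: Orientation = "greater_indicates_target",
    method: Literal["delong", "bootstrap"] = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% confidence interval for the AUC, truncated to [0, 1].

    DeLong's method uses the empirical variance of the per-observation
    placement values; the bootstrap alternative resamples each class
    separately and takes percentile limits.
    """
    s, y = _prepare(scores, labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("each class needs at least two members for a CI")
    so = _oriented(s, orientation)
    if method == "delong":
        v10, v01 = _placements(so, y)
        a = float(v10.mean())
        var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
        half = 1.959963984540054 * np.sqrt(var)
        return (float(max(0.0, a - half)), float(min(1.0, a + half)))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        tgt, rest = so[y], so[~y]
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            t = rng.choice(tgt, size=tgt.size, replace=True)
            r = rng.choice(rest, size=rest.size, replace=True)
            ranks = stats.rankdata(np.concatenate([t, r]))
            aucs[b] = (ranks[: t.size].sum() - t.size * (t.size + 1) / 2.0) / (t.size * r.size)
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        return (max(0.0, float(lo)), min(1.0, float(hi)))
    raise ValueError(f"unknown method {method!r}")


def youden_threshold(
    points: Sequence[tuple[float, float, float]],
) -> tuple[float, float, float, float]:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties are broken in favour of higher sensitivity, then the smaller
    |threshold| side of the candidate list (for finite thresholds, the
    lower one under the greater orientation). Returns
    ``(threshold, sensitivity, specificity, J)``.
    """
    if not points:
        raise ValueError("no ROC points supplied")
    best = None
    for thr, sens, spec in points:
        j = sens + spec - 1.0
        key = (j, sens, -thr if np.isfinite(thr) else -np.inf)
        if best is None or key > best[0]:
            best = (key, (thr, sens, spec, j))
    return best[1]


def analyze_item(
    scores: Sequence[float],
    labels: Sequence[bool],
    item: str,
    target_disease: str,
    orientation: Orientation,
    ci_method: Literal["delong", "bootstrap"] = "delong",
) -> RocAnalysis:
    """Run the full ROC/AUC/Youden analysis for one item."""
    pts = roc_points(scores, labels, orientation)
    thr, sens, spec, _ = youden_threshold(pts)
    return RocAnalysis(
        target_disease=target_disease,
        item=item,
        orientation=orientation,
        points=pts,
        auc=auc(scores, labels, orientation),
        auc_ci_95=auc_ci(scores, labels, orientation, method=ci_method),
        youden_threshold=thr,
        youden_sensitivity=sens,
        youden_specificity=spec,
    )


def derive_battery(
    cohort: pd.DataFrame,
    complete_case: bool = False,
    ci_method: Literal["delong", "bootstrap"] = "delong",
) -> dict[str, RocAnalysis]:
    """ROC analyses for the five battery items against their target disease.

    One-vs-rest labels within the four-diagnosis cohort (the "other"
    stratum is excluded). By default each item uses its available cases;
    ``complete_case=True`` restricts every item to records with all
    required battery items observed.
    """
    from .cohort import DISEASES, complete_case_mask

    df = cohort[cohort["true_diagnosis"].isin(DISEASES)]
    if complete_case:
        df = df[complete_case_mask(df)]
    out: dict[str, RocAnalysis] = {}
    for item, (disease, orientation) in BATTERY_TARGETS.items():
        sub = df[df[item].notna()]
        labels = (sub["true_diagnosis"] == disease).to_numpy()
        out[item] = analyze_item(
            sub[item].to_numpy(dtype=float), labels, item, disease, orientation, ci_method
        )
    return out
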