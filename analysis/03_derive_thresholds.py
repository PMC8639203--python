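#!/usr/bin/env python
"""Derive ROC/Youden thresholds for the five battery items.

For each item (CP% vs UVH; NPQ total and visual-stimulation scores vs
PPPD; HADS anxiety and age vs CDA, age pointing downward) the script
reports AUC with its DeLong 95% CI and the Youden-optimal threshold
with sensitivity/specificity, writes per-item ROC tables
(results/roc_<item>.csv) and results/battery.json.
"""
import json
from pathlib import Path

import pandas as pd

from vestibattery.io import read_cohort
from vestibattery.reference import BATTERY_THRESHOLDS
from vestibattery.roc import derive_battery

OUT = Path("results")


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    battery = derive_battery(cohort)
    summary = {}
    for item, ra in battery.items():
        pd.DataFrame(ra.points, columns=["threshold", "sensitivity", "specificity"]).to_csv(
            OUT / f"roc_{item}.csv", index=False
        )
        summary[item] = {
            "target_disease": ra.target_disease,
            "orientation": ra.orientation,
            "auc": round(ra.auc, 3),
            "auc_ci_95": [round(v, 3) for v in ra.auc_ci_95],
            "youden_threshold": ra.youden_threshold,
            "sensitivity_percent": round(100 * ra.youden_sensitivity, 1),
            "specificity_percent": round(100 * ra.youden_specificity, 1),
        }
        print(
            f"{item} -> {ra.target_disease}: AUC {ra.auc:.3f} "
            f"({ra.auc_ci_95[0]:.3f}-{ra.auc_ci_95[1]:.3f}), "
            f"threshold {ra.youden_threshold:g} "
            f"(published {BATTERY_THRESHOLDS[item]:g}), "
            f"sens {100 * ra.youden_sensitivity:.1f}% spec {100 * ra.youden_specificity:.1f}%"
        )
    (OUT / "battery.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
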