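#!/usr/bin/env python
"""Screen every battery item across the four diagnoses.

Kruskal–Wallis per item, Dunn–Bonferroni post-hoc for the significant
ones, plus the vHIT sub-cohort two-sample tests (Mann–Whitney on gains
and asymmetry, Fisher exact on catch-up saccades and low gain). Writes
results/comparison.json and a readable markdown table; prints the
battery shortlist that feeds the ROC stage.
"""
import json
from pathlib import Path

from vestibattery.comparison import compare_all_items, fisher_exact_2x2, mann_whitney
from vestibattery.io import _comparison_json, _comparison_markdown, read_cohort

OUT = Path("results")


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    results, shortlist = compare_all_items(cohort)
    (OUT / "comparison.json").write_text(json.dumps(_comparison_json(results, shortlist), indent=2))
    (OUT / "comparison.md").write_text(_comparison_markdown(results, shortlist))

    sig = [r for r in results if r.significant_overall]
    print(f"Kruskal–Wallis significant items: {len(sig)} of {len(results)}")
    print("battery shortlist (>=1 significant Dunn pair):", ", ".join(shortlist))

    vhit = cohort[cohort["vhit_gain_better"].notna()]
    pppd = vhit[vhit["true_diagnosis"] == "PPPD"]
    uvh = vhit[vhit["true_diagnosis"] == "UVH"]
    print(f"\nvHIT sub-cohort: PPPD n={len(pppd)}, UVH n={len(uvh)}")
    for col in ("vhit_gain_better", "vhit_gain_worse", "vhit_ar"):
        _, p = mann_whitney(pppd[col], uvh[col])
        print(f"  {col}: Mann–Whitney p = {p:.3f}")
    cus = (int(pppd["cus_present"].sum()), int((~pppd["cus_present"].astype(bool)).sum()),
           int(uvh["cus_present"].sum()), int((~uvh["cus_present"].astype(bool)).sum()))
    print(f"  catch-up saccades {cus}: Fisher p = {fisher_exact_2x2(*cus):.3f}")


if __name__ == "__main__":
    main()
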