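"""Published reference values from the underlying clinical study.

A single-centre retrospective cohort of 231 patients with chronic
vestibular syndromes (symptoms > 3 months) underpins this package: four
major diagnoses — persistent postural-perceptual dizziness (PPPD, n=92),
chronic dizziness due to anxiety (CDA, n=44), unilateral vestibular
hypofunction (UVH, n=31) and undifferentiated dizziness (UD, n=37) —
plus 27 patients with other conditions. These constants are the study's
reported group sizes, vHIT contingency tables, ROC-derived thresholds
and per-algorithm accuracies; the pipeline uses them as fixed inputs
(e.g. simulator targets, default rule thresholds) and as expectations in
regression checks.
"""
from __future__ import annotations

DISEASES = ("PPPD", "CDA", "UVH", "UD")
ALL_STRATA = DISEASES + ("OTHER",)

GROUP_SIZES = {"PPPD": 92, "CDA": 44, "UVH": 31, "UD": 37, "OTHER": 27}
TOTAL_PATIENTS = 231

#: reported complete-case cohort size for the algorithm analysis
COMPLETE_CASE_N = 118

#: vHIT sub-cohort 2x2 tables as (a, b, c, d) = (PPPD+, PPPD-, UVH+, UVH-)
VHIT_CUS_TABLE = (1, 55, 3, 3)        # catch-up saccades present
VHIT_LOW_GAIN_TABLE = (7, 49, 2, 4)   # worse-side gain < 0.6

#: Youden-optimal thresholds reported for the five battery items
BATTERY_THRESHOLDS = {
    "CP_percent": 19.8,     # >= -> UVH
    "NPQ_visual": 10.5,     # >= -> PPPD
    "NPQ_total": 33.5,      # >= -> PPPD
    "HADS_anxiety": 8.5,    # >= -> CDA
    "age": 48.5,            # <  -> CDA (CDA patients are younger)
}

#: reported AUC and 95% CI per battery item (one-vs-rest)
BATTERY_AUC = {
    "CP_percent": (0.832, (0.736, 0.927)),
    "NPQ_visual": (0.770, (0.684, 0.855)),
    "NPQ_total": (0.739, (0.648, 0.830)),
    "HADS_anxiety": (0.657, (0.550, 0.765)),
    "age": (0.678, (0.586, 0.770)),
}

#: algorithm number -> ordered disease blocks (fallback is always UD)
ALGORITHM_ORDERS = {
    1: ("PPPD", "UVH", "CDA"),
    2: ("PPPD", "CDA", "UVH"),
    3: ("UVH", "PPPD", "CDA"),
    4: ("UVH", "CDA", "PPPD"),
    5: ("CDA", "PPPD", "UVH"),
    6: ("CDA", "UVH", "PPPD"),
}

#: reported per-class recall (%) per algorithm on the complete-case cohort
REPORTED_RECALLS = {
    1: {"PPPD": 80.0, "UVH": 85.7, "CDA": 36.8},
    2: {"PPPD": 80.0, "UVH": 71.4, "CDA": 42.1},
    3: {"PPPD": 55.7, "UVH": 92.9, "CDA": 36.8},
    4: {"PPPD": 14.3, "UVH": 92.9, "CDA": 68.4},
    5: {"PPPD": 24.3, "UVH": 71.4, "CDA": 84.2},
    6: {"PPPD": 14.3, "UVH": 78.6, "CDA": 84.2},
}

#: reported overall accuracy (%) excluding UD, per algorithm
REPORTED_OVERALL = {1: 72.8, 2: 71.8, 3: 57.3, 4: 35.0, 5: 41.7, 6: 35.9}

#: complete-case class sizes reconstructed from the reported figures
#: ("10 of the 19 patients with CDA", 118 complete cases, integer correct
#: counts); together with REPORTED_RECALLS these reproduce every value in
#: REPORTED_OVERALL exactly at one-decimal rounding.
RECONSTRUCTED_SIZES = {"PPPD": 70, "UVH": 14, "CDA": 19, "UD": 15}
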