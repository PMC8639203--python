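# Methods

## The diagnostic problem and the pipeline

Chronic vestibular syndromes (symptoms > 3 months) are dominated by four
diagnoses — PPPD, CDA, UVH and UD — which in the reference cohort of 231
patients covered 204 patients (88%); the remaining 27 ("other": bilateral
vestibulopathy, presbyvestibulopathy, central lesions, …) are carried as
an excluded stratum. The pipeline has four stages, each usable on any
cohort table with the documented CSV schema:

1. screen every demographic/questionnaire/vestibular item for group
   differences (Kruskal–Wallis, then Dunn–Bonferroni pairwise z-tests for
   omnibus-significant items);
2. for each shortlisted item, build a one-vs-rest ROC curve against its
   target diagnosis and adopt the Youden-optimal cutpoint;
3. assemble three disease rule blocks (PPPD, UVH, CDA) from the
   thresholds and enumerate the six sequential orderings with UD
   fallback;
4. classify the complete-case subset and report per-class recall and the
   overall accuracy excluding UD-true patients.

Nonparametric tests are used throughout because questionnaire scores are
bounded integers with heavy ties and the caloric/VEMP ratios are
markedly non-normal; tie corrections are applied in both the
Kruskal–Wallis and Dunn statistics for the same reason. Significance is
two-sided at α = 0.05, with Bonferroni correction only across the six
group pairs within an item (not across items — the screen is a
shortlisting device, not a confirmatory family).

## Instrument-level quantities

The caloric formulas are the standard Jongkees forms on the four maximum
slow-phase velocities (right/left × warm/cool):
CP% = |(Rw+Rc) − (Lw+Lc)| / total × 100 with the weaker ear reported,
and DP% = |(Rw+Lc) − (Lw+Rc)| / total × 100 on the right- vs
left-beating totals. Both are reported as absolute percentages with a
side/direction label; whether the underlying study averaged signed or
absolute values is not recoverable from its summary tables, and the
absolute convention matches its non-negative group means. All
abnormality cut-offs use strict comparisons (CP% > 20, |IAAR| > 33.3,
VOR-DP > 12; vHIT worse-side gain < 0.6), so a value exactly at the
boundary is normal.

Questionnaire structure is enforced, not assumed: HADS total =
anxiety + depression (each subscale 0–21), NPQ total = upright +
movement + visual (each factor 0–24), DHI total = physical + emotional +
functional. The DHI subscale maxima (28/36/36, items scored 0/2/4)
follow the standard 25-item instrument. Missing values are first-class
throughout: any field may be absent, derived flags propagate
missingness, and only the operations whose preconditions demand data
raise errors.

## The synthetic cohort generator

**What it emulates.** Group sizes 92/44/31/37 + 27; for every group ×
item cell a clipped normal draw at the published mean/SD with
type-appropriate rounding (integers for age and HADS/NPQ items, even
integers for DHI items, continuous ratios elsewhere); per-cell
available-case counts enforced exactly by a seeded missingness mask;
questionnaire totals computed by summation from drawn subscales (so
additivity always holds; matching the published total means exactly
instead would break it); CP% realized by constructing a four-irrigation
response quadruple with the target asymmetry and a random warm/cool
split, so the Jongkees formula round-trips exactly; a vHIT sub-cohort of
56 PPPD and 6 UVH patients with clipped-normal gains (worse ≤ better
enforced by ordering the pair), the asymmetry ratio computed from the
gains, and catch-up saccades drawn Bernoulli(1/56) and Bernoulli(3/6).
The low-gain flag is not drawn: it is derived as worse-side gain < 0.6,
and the gain distributions already imply rates (≈ 0.12 PPPD, ≈ 0.41 UVH)
consistent with the published 7/56 and 2/6. The "other" stratum carries
only age and is excluded from every analysis.

**Missingness model.** The mask is drawn per test/questionnaire block
(a patient who lacks the NPQ lacks all three factors) — which is exactly
what the published per-item counts imply, since they are identical
within each block — and independently across blocks. Real missingness
is likely positively correlated across tests (patients lost early miss
several batteries), so the generator's complete-case count
(~90–95 at the study's sizes) runs below the study's 118; the
complete-case count is therefore treated as an emergent property, never
forced.

**What it does not emulate.** Within-patient correlation between items
(only the structural sums correlate; the study reports only marginal
moments), longitudinal visits, and exact moment-matching near instrument
boundaries: clipping a normal at a nearby bound shifts its mean (worst
for DP% in PPPD and the posturography Romberg ratio in UD), which is
accepted and tested at a 3-standard-error tolerance rather than
re-standardized. Passing tests therefore show that the pipeline recovers
the structure this generator encodes — marginal group separations at the
study's sample sizes — not that it would behave identically on real,
correlated patient data. The vHIT better-side gain SD of 1.53 for PPPD
is taken verbatim from the published table even though it is implausibly
large for a VOR gain (gains are clipped to [0.01, 2]); it only widens
that sub-cohort's spread.

**Determinism.** One master seed spawns named sub-streams (value draws,
caloric quadruples, vHIT sub-cohort, missingness), so the cohort CSV is
byte-identical across runs and each stage is independently reproducible.
A `scale` factor multiplies all group sizes and per-cell counts for
convergence studies.

## Statistical components

* **Kruskal–Wallis** is delegated to scipy (tie-corrected H, chi-square
  p with k−1 df). The test suite checks the chi-square p against an
  exhaustive permutation null on a small fixture.
* **Dunn post-hoc** is implemented directly (no maintained dependency
  ships it): pooled midranks, variance
  (N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ), two-sided normal p
  multiplied by the number of pairs and capped at 1.
* **Fisher exact** (two-sided) is hypergeometric enumeration: the sum of
  point probabilities ≤ the observed table's probability, with a 1e-12
  relative tolerance on that comparison; cross-checked against scipy.
* **Mann–Whitney** enumerates all C(n₁+n₂, n₁) labelings when
  n₁+n₂ ≤ 12 (midrank U, two-sided permutation p), otherwise uses the
  tie-corrected normal approximation. The two-sample comparisons for the
  vHIT sub-cohort use it for consistency with the rank-based screen.
* **ROC/AUC.** Candidate thresholds are midpoints between adjacent
  distinct observed scores plus ±∞ — hence half-integer thresholds on
  integer scales. Positive classification is `score ≥ t` under the
  "greater" orientation and `score < t` under "less" (used for age,
  since CDA patients are younger); with midpoints the boundary is
  unobservable. AUC is the Mann–Whitney concordance probability
  (0.5 credit for ties), identical to the trapezoidal area under the
  curve. The Youden maximizer breaks ties by higher sensitivity, then
  the lower threshold on the oriented scale.
* **AUC confidence intervals** use DeLong's placement-value variance
  (verified to 1e-9 against R pROC on a frozen fixture); a stratified
  percentile bootstrap (2000 resamples) is available by configuration.
  At the study's class sizes for CP% (23 UVH vs 147 rest) the DeLong
  interval's empirical coverage is ≈ 90%, a little under nominal — a
  known small-sample effect amplified by the clipped score distribution.

## Algorithms and evaluation

Within a block the criteria combine with OR by default ("CP% or
catch-up saccades" for UVH), configurable to AND; under OR, a sensitive
PPPD block placed first captures many CDA patients, which is exactly the
behavior seen in the published per-class recalls (10 of 19 CDA patients
called PPPD). Missing values fail their criterion; a missing catch-up
saccade observation (no vHIT performed) is a negative criterion, not an
exclusion, because the vHIT exists only for a 62-patient sub-cohort and
requiring it would shrink the evaluable cohort to that sub-cohort.
Complete-case evaluation requires the five core battery inputs (NPQ
total and visual scores, HADS-A, age, CP%).

The six orderings are numbered 1: PPPD–UVH–CDA, 2: PPPD–CDA–UVH,
3: UVH–PPPD–CDA, 4: UVH–CDA–PPPD, 5: CDA–PPPD–UVH, 6: CDA–UVH–PPPD.
This numbering, and the complete-case class sizes (PPPD 70, UVH 14,
CDA 19, UD 15), are reconstructed rather than printed: with those sizes,
integer correct counts, and the published per-class recalls, all six
published overall accuracies (72.8, 71.8, 57.3, 35.0, 41.7, 35.9%)
reproduce exactly at one-decimal rounding — a regression-tested
identity. Overall accuracy is 100 × Σ correct / Σ n over the PPPD, UVH
and CDA classes only; UD recall is reported separately because the
fallback class is "diagnosed" by exclusion.

## Problem sizes and tolerances in the test suite

Simulation-based checks run at the study's own sizes unless stated:
parameter recovery uses three cohorts at scale 10 (a 2 310-patient
cohort per seed) and requires ≥ 95% of group × item cells within 3
standard errors of target; screening recovery and AUC plausibility use
50 single-scale cohorts and require the five battery items shortlisted
in ≥ 80% and the CP%→UVH AUC inside the published CI (0.736–0.927) in
≥ 90% of them. The full suite completes in well under a minute; the
acceptance script, which regenerates twenty cohorts, in a few seconds.

## Known limitations

* Independent-within-patient draws understate real between-test
  correlation; derived complete-case counts and any multivariate
  structure are accordingly approximate.
* Thresholds re-derived on a single synthetic cohort scatter around the
  published cutpoints (the published values are retained as the default
  rule thresholds for evaluation).
* Ground-truth labels are simulated group memberships, not adjudicated
  clinical diagnoses; accuracy figures on synthetic cohorts quantify the
  pipeline's internal consistency, not clinical performance.
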