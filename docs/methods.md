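# Methods

This note documents the models, scoring rules, numerical choices and
known limitations behind `phenosleep`. Everything stated here is
computed by the code; nothing is asserted that the test suite or
`scripts/acceptance.py` does not itself reproduce.

## Study design being modelled

The package implements the analysis workflow of a 4-week observational
digital-phenotyping study of insomnia: each participant wears a
consumer wrist device (heart rate sampled every 5 minutes, cumulative
step counts, nightly sleep-stage records), keeps a daily EMA log
(caffeine, alcohol, naps, stress, each with a time-of-day slot), and
completes nine self-report instruments. Participants are banded into
four severity groups by ISI total — 0–7 none, 8–14 mild, 15–21
moderate, 22–28 severe — and every derived variable is compared across
the bands. The enrollment screen is a distinct, stricter rule (ISI > 15
with ≥ 3 symptomatic days/week for the insomnia arm; ISI < 8 with < 3
days for the control arm; the 8–15 range is ineligible) and is
implemented separately from the analysis banding because the two serve
different purposes.

## Questionnaire scoring

All nine instruments are scored as unweighted sums of item ratings; no
instrument here reverse-scores items. Item counts and ranges: ISI 7×0–4,
IRLS 10×0–4, DBAS 16×0–10, STAI-S 20×1–4, PHQ-9 9×0–3, GAD-7 7×0–3,
AUDIT-C 3×0–4, SOS-Q 28×1–4, BRIAN 21×1–4. Two deliberate decisions:

* **BRIAN total = sum of its first 18 items.** The instrument carries
  21 items, but only 18 belong to the four scored rhythm-disturbance
  categories (sleep, social rhythms, activity, eating); the remaining 3
  collect chronotype information. The published total range 18–72 is
  only consistent with 18 scored items, so the last 3 items are stored
  but unscored.
* **SOS-Q total of exactly 49 → low risk.** The published cutoff
  sentence defines high risk as scores *higher than* 49 and low risk as
  scores below 49, leaving 49 itself unassigned; the strict ">" reading
  is adopted.
* IRLS per-item range is taken as 0–4 (10 items, total 0–40, consistent
  with the printed range); per-item anchors are not published with the
  banding.

## EMA encoding and weighting

Nap duration categories are half-open intervals [0,1), [1,2), [2,3),
[3,∞) hours, encoded 0.5/1/2/3 (the half-open convention resolves the
otherwise-undefined exact-integer boundaries). Stress intensity is
encoded 1/2/3. Caffeine and alcohol amounts are unitless self-reported
counts. Each encoded value is multiplied by a (kind, slot) weight —
caffeine/nap/stress: morning 1, afternoon 1.5, before bedtime 2;
alcohol: morning 1.5, afternoon 1, before bedtime 2 — and summed within
days. The participant-level statistic is the **sum over the study
period** by default (a mean-per-day option is provided): the published
per-participant caffeine scale (median ≈ 10 with a 4-week log) is most
consistent with a period aggregate, but the daily→participant
aggregation was never stated, so the default is a documented choice
rather than a verified fact. Multiple same-kind entries in one slot on
one day are summed before weighting.

## Sleep parameters

TST = total inactive time − total awake time, per night. Sleep quality
is 100·TST/(TST + awake): the source description says only that quality
is computed from TST and awake time and is a percentage; sleep
efficiency over the detected inactive period is the one formula
consistent with both statements and with the observed 80–85% scale.
This formula choice is flagged prominently because it is inferred, not
quoted. Participant summaries are arithmetic means over recorded
nights; quality is computed from the mean TST and mean awake time by
default (averaging nightly ratios is available as an option; the two
differ when night lengths vary). Nights with zero inactive time are
treated as device non-wear, excluded and counted. Wake-ups are scaled
to a 7-night week using the number of recorded nights as denominator.

## Cosinor analysis

A single-component cosinor at fixed 24-h period is fit by ordinary
least squares in the cos/sin basis — exact and deterministic for this
model, with no nonlinear optimization. Amplitude = √(β²+γ²) ≥ 0 by
construction; acrophase = atan2(γ, β)·24/2π, reported as hours past
midnight in [0, 24) (a signed offset-from-midnight convention in
(−12, 12] is also exposed, since negative published step-acrophase
values imply an alternative reference that is never defined; neither
convention is asserted against those values). Goodness of fit is the
coefficient of determination R² against the mean-only model, clamped to
[0, 1]; a zero-variance window returns amplitude 0 and R² 0 by
convention. Participant-level parameters come from a 2-day sliding
window stepped by 1 day (step length is a choice; the window length is
part of the study design), averaged arithmetically except the
acrophase, which is averaged circularly (vector mean of angles) —
arithmetic averaging would be wrong near the midnight wrap. Windows
with under 50% non-missing samples are skipped and counted.

## Rest–activity metrics

On hourly-binned means (bins with under 50% epoch coverage dropped):

* IV = n·Σ(xᵢ−xᵢ₋₁)² / [(n−1)·Σ(xᵢ−x̄)²], successive differences
  across dropped bins excluded. ≈ 0.07 for a clean 24-h cosine sampled
  hourly, → 2 for white noise, > 2 for ultradian alternation.
* IS = n·Σₕ(x̄ₕ−x̄)² / [p·Σᵢ(xᵢ−x̄)²] with p = 24 hourly means pooled
  across days; 1 for a perfectly repeating daily profile, → 0 for noise.

These are the canonical hourly-binned definitions; the source cites a
convention without printing formulas, so the implementations are
verified against independent naive double-loop oracles rather than
against published values. L5/M10 are the minimum 5-h and maximum 10-h
moving-average levels on the native epoch grid (complete windows only;
windows with under 50% coverage ignored); because every full 10-h
window is the mean of two disjoint 5-h windows, L5 ≤ M10 always holds.
IV/IS/L5/M10 are computed on differenced step increments by default
(heart rate optional) — the stream used was not stated in the source.
Cumulative counters are differenced with midnight resets: the first
epoch of a day contributes its own value, and within-day decreases are
data errors.

## Statistical workflow

Normality is assessed per group by Shapiro-Wilk at α = 0.05 (the
specific test and level were not published; this choice reproduces the
qualitative pattern of mostly-rank-based rows with occasional ANOVA
rows). Any non-normal group routes the variable to Kruskal-Wallis with
all C(4,2) = 6 pairwise two-sided Wilcoxon rank-sum tests flagged at
the strict threshold p < 0.05/6 (≈ .0083); all-normal variables use
one-way ANOVA with Tukey HSD; categoricals use chi-square with a
low-expected-cell warning. The rank-sum test uses the exact null
distribution for combined n ≤ 20 without ties, otherwise the normal
approximation with mid-rank tie correction and continuity correction.
"Paired" appears once in the source's description of the rank test, but
the groups are independent and the table footnotes name the (unpaired)
rank-sum test, so the unpaired test is implemented. No correction is
applied across variables — the Bonferroni family is each variable's six
pairwise comparisons. Summary cells follow the table conventions:
median (IQR) on the rank path, mean (SD) on the ANOVA path, n (%) for
categoricals. With identical values in every group the Kruskal-Wallis
statistic is defined as 0 with p = 1.

## Synthetic cohort generator

The generator defines the study conditions for all tests:

* **Groups**: proportions (0.252, 0.424, 0.276, 0.048) apportioned by
  largest remainder, so n = 250 always splits 63/106/69/12; labels are
  then randomly permuted over participants.
* **ISI**: totals drawn uniformly inside the assigned band and
  distributed over the 7 items by sequential constrained draws, so the
  banding always recovers the assigned group.
* **Scales**: totals Gaussian around a no-insomnia baseline plus a
  per-group shift from the `effect_profile` (defaults reproduce the
  observed severity gradients, e.g. DBAS group means 65.17 / 81.23 /
  94.12 / 119.5 with SD ≈ 24), rounded and clipped to legal ranges,
  then distributed over items. AUDIT-C has zero shifts (a null result).
* **Sleep**: every group shares one distribution — TST ~ 375.5 ± 30 min
  between subjects (± 25 nightly), awake 65 ± 9 (± 8), stages REM/light/
  deep around 210/78/54 rescaled never to exceed TST, wake-ups Poisson
  ≈ 3.7/night. This encodes the null finding; the discrepancy pattern in
  the acceptance run is that Kruskal-Wallis on TST rejects at ≈ the
  nominal 5% while DBAS and weighted stress reject essentially always.
* **EMA**: daily Bernoulli occurrence per kind (caffeine 0.30, alcohol
  0.12, nap 0.15, stress 0.08 plus graded group shifts up to +0.45),
  kind-specific slot preferences, amounts 1 + Poisson.
* **Heart rate**: per-participant cosine with MESOR ~ N(74.6, 6) bpm,
  amplitude ~ N(11, 3) clipped positive, mid-afternoon acrophase
  ~ N(15 h, 1.5), Gaussian noise SD 5 bpm, clipped to 30–220 bpm.
* **Steps**: log-normal per-epoch increments around a two-level diurnal
  rate (active 8 AM–10 PM), cumulated within calendar days.
* **Missingness**: independent Bernoulli 2% per epoch (wear-time
  compliance is not otherwise modelled).
* **Determinism**: all randomness flows through `SeedSequence` children
  keyed by (seed, stream, participant), so identical configs are
  byte-identical and generating a subset of streams does not perturb
  the rest.

What the generator does **not** emulate: raw accelerometry or the
device's staging heuristics, dropout/attrition, autocorrelated
within-night structure, non-Gaussian scale distributions (floor effects
in GAD-7/PHQ-9 are only partly captured by clipping), seasonal or
weekday behavioral structure. Passing tests therefore demonstrate that
the pipeline is correct and that the workflow reproduces the designed
statistical pattern — not that real wearable data would show it.

## Problem sizes

The default test suite and the acceptance script use: 200 simulation
seeds × 250 participants for the null-pattern rejection rates (sleep,
questionnaire and EMA streams only — wearable epoch streams are not
needed for those variables); 200 seeds of 28-day 5-minute series for
noisy cosinor recovery; a 120-participant, 14-day cohort for the
population-level heart-rate cosinor medians; and 400–500 simulations
for Type-I-error properties. These sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerances (e.g. 3 SE ≈ 4.6
percentage points on a 5% rejection rate at 200 seeds).

## Known limitations

* The sleep-quality formula and the EMA participant-level aggregation
  are inferred choices (documented above), not published definitions.
* The acrophase reference convention for step rhythms cannot be matched
  to the published negative values; both conventions are emitted.
* Tables of observed per-group medians/IQRs derive from unreleased
  participant data; the package reproduces recomputable quantities
  (score ranges, counts, thresholds, weights) and the qualitative
  significance pattern, not those medians.
* The normality gate (Shapiro-Wilk, α = 0.05) cannot exactly replicate
  the published per-row test choices, which depended on the unreleased
  data.
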