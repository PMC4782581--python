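# Methods

## Setting and model

`stepscreen` evaluates depression screening instruments against a structured
diagnostic reference in a primary-care cohort. The instrument is a nine-item
questionnaire (items scored 0–3, total 0–27, screen-positive at a chosen
cutoff); the reference is a structured diagnostic interview for a major
depressive episode over a two-week frame. Two single-question
idiom-of-distress screens are evaluated alongside: "heart-mind problems"
(a common, non-stigmatized Nepali idiom of psychological distress) and
"brain-mind problems" (a stigmatized idiom), plus a follow-up question about
functional impairment due to heart-mind problems.

Every accuracy quantity derives from the 2×2 cross-tabulation of screen
result against reference status:

- sensitivity `tp/(tp+fn)`, specificity `tn/(fp+tn)`, PPV `tp/(tp+fp)`,
  NPV `tn/(fn+tn)`, prevalence `(tp+fn)/n`;
- likelihood ratios `LR+ = sens/(1−spec)`, `LR− = (1−sens)/spec`;
- diagnostic odds ratio `DOR = (tp·tn)/(fp·fn) = LR+/LR−`;
- Youden's `J = sens + spec − 1`.

The stepped detection algorithm asks the heart-mind question first, the
impairment question second, and administers the full instrument (cutoff ≥ 10
by default) only to patients answering "yes" twice. Because gates can only
remove screen positives, the algorithm dominates universal screening in
false positives and instrument workload while bounding the sensitivity loss
by the reference cases lost at the gates.

## Confidence intervals

- **Proportions** (sensitivity, specificity, PPV, NPV): Wilson score
  interval by default, Clopper–Pearson ("exact", beta-quantile) selectable.
  Both are computed by `statsmodels.stats.proportion.proportion_confint`.
  The two methods disagree at the second decimal for small counts; both are
  exposed because published screening reports rarely name their method.
  Note a boundary fact: at 0 or n successes the exact one-sided bound
  `1 − (α/2)^(1/n)` is *tighter* than Wilson's `z²/(n+z²)` once n ≳ 46, so
  "exact is wider" holds only for interior counts.
- **Likelihood ratios**: asymptotic log method,
  `exp(ln LR ± z·SE)`, `SE(ln LR+) = sqrt(1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn))`
  (fn/tn analogue for LR−).
- **Diagnostic odds ratio**: Woolf's log method,
  `SE = sqrt(1/tp + 1/fp + 1/fn + 1/tn)`.
- z is the two-sided standard-normal quantile at `(1+level)/2`, computed,
  never hard-coded.

## Zero cells, undefined values, rounding

No continuity correction is applied by default. A statistic whose
denominator is zero (LR+ at specificity 1, DOR with an empty fp or fn cell)
is returned as a typed `Undefined` marker with a reason code and rendered
`n/a`; an LR− of exactly 0 (no false negatives) is the defined value `0.00`.
An optional Haldane–Anscombe flag adds 0.5 to each cell for the ratio
statistics only.

Reports round half-up to two decimals; internal computation is full double
precision. In the rendered cutoff table, Youden's J is derived from the
*displayed* (rounded) sensitivity and specificity, so the identity
`J = sens + spec − 1` holds at report precision — the convention used in
published accuracy tables of this kind, where the J column is consistent
with the rounded columns rather than with full-precision values (e.g.
sens 16/17, spec 75/108 gives 0.6356 at full precision but 0.94+0.69−1 =
0.63 at display precision). Full-precision J remains available via
`SweepTable.to_frame` and `MetricSet.youden_j`, and cutoff selection always
uses full precision.

## Cutoff sweep and ROC

Screen-positive means total ≥ cutoff; no strictly-greater convention is
offered, to avoid silent off-by-one disagreements with "≥ k"-labelled
tables. AUC is the Mann–Whitney probability that a reference-positive
subject outscores a reference-negative one with ties counted one-half
(identical to the trapezoidal area under the empirical ROC; integer scores
guarantee ties, so half-credit handling matters). `best_cutoff` supports
maximizing J, maximizing the DOR (rows with undefined DOR excluded), or
maximizing specificity subject to a sensitivity floor; ties break toward
the lower cutoff because screening privileges sensitivity.

## Synthetic cohort generator

`generate(study_preset(n), seed)` emulates the joint structure of the
validation study:

- reference status ~ Bernoulli(17/125);
- per group, the nine items are produced by cutting correlated latent
  standard normals at per-item thresholds. Each subject has one shared
  latent factor with loading `sqrt(ρ)` plus independent item noise
  (equicorrelation ρ) — the simplest mechanism able to hit the published
  per-item group means/SDs and the published internal consistency at once;
- gate answers are Bernoulli with group-conditional probabilities
  (heart-mind 16/17 and 79/108; impairment-given-heart-mind 15/16 and
  44/79; brain-mind 8/17 and 4/108), with impairment structurally
  restricted to heart-mind endorsers. The 44/79 value is derived: 59
  stage-two passers minus 15 reference-positive passers, over the 79
  reference-negative heart-mind endorsers. Under these constants the
  expected instrument workload is exactly 59/125.

**Threshold calibration.** Matching a target mean/SD on {0,1,2,3} with three
thresholds is underdetermined (three cut points, two moments). The package
selects the maximum-entropy distribution with those moments
(`p_k ∝ exp(a·k + b·k²)`, solved by a 2-d root find) and maps its cumulative
probabilities through the normal quantile function. This is deterministic,
reproduces a symmetric target as the 25/50/75% quantile cuts, and raises a
calibration error for targets outside the moment set of a 4-point scale
(variance above the two-point {0,3} maximum or below the adjacent-integer
minimum).

**Correlation calibration.** The equicorrelation constant stored in
`study_preset` (ρ = 0.3054) was found once by seeded bisection
(`calibrate_latent_correlation`) so that Cronbach's alpha of a large
generated cohort is 0.84; the calibration function ships in the module so
the constant is reproducible. Alpha increases strictly with ρ (tested on a
three-point grid), because the shared factor is the only source of
inter-item covariance within groups and group separation is fixed.

**What the generator does and does not emulate.** It reproduces prevalence,
the group-conditional item moments, gate endorsement rates, the
impairment⇒heart-mind constraint, and an internal consistency of 0.84. It
does *not* reproduce item-specific correlation structure (all items load
equally on one factor), demographics, or any coupling between gate answers
and item scores beyond their common dependence on reference status. Rank
properties observed in the study nevertheless emerge from the moments
alone: the appetite item has the lowest corrected item-total correlation
(its group separation per unit SD is the smallest) and the suicidality item
the highest per-item LR+ (its endorsement rate among reference negatives is
by far the lowest). The population gap between the two lowest item-total
correlations is only ≈0.02, so tests check this rank on cohorts of
n = 100,000, where sampling noise (≈0.003) resolves it decisively; alpha is
checked at n = 10,000 within ±0.05, and gate/workload parameter recovery at
n = 100,000 within ±0.01.

## The deterministic fixture

`reconstruct_fixture()` rebuilds a 125-subject dataset exactly consistent
with every published marginal count, with no randomness:

- **Totals.** The 17 reference positives take totals derived from first
  differences of the published true-positive column over cutoffs 7–15: one
  each at 8, 10, 12, two at 13, two at 14, and the ten at ≥15 spread one
  per score over 15–24. The 108 negatives likewise: 59 below 7 (spread over
  scores 2–6 by a fixed cycle), then 8, 8, 11, 4, 4, 3, 1, 5 at scores
  7–14, and 5 spread over 15–19. With this assignment the fixture AUC is
  0.936, inside the published interval (0.87–0.99); the band-filling rule
  is fixed in code, not adjusted per run.
- **Gate flags.** Among positives, the single heart-mind non-endorser is
  the lowest scorer at or above the terminal cutoff (total 10) — forced by
  "one case missed at the heart-mind gate" together with the algorithm's
  tp = 15 — and the score-8 positive endorses heart-mind but not impairment
  (the case missed at the impairment gate). Among negatives, the 79
  highest-scoring endorse heart-mind and score ranks 5–48 endorse
  impairment, so exactly 18 negatives at total ≥10 pass both gates and the
  stage-two pass count is 59 (15 positive, 44 negative).
- **Brain-mind flags** (8 positives, 4 negatives) are assigned by
  construction order, independent of scores — no published joint constraint
  exists. The published record is internally inconsistent about the
  brain-mind row (8 vs 9 endorsing positives in two places); the fixture
  follows the demographic cross-tabulation (8), and brain-mind statistics
  are treated as approximate only.
- **Items.** Each total is spread evenly over the nine items
  (base = total div 9, remainder distributed to the first items). Only
  totals and flags are pinned by published counts, so fixture *item-level*
  statistics (alpha 0.97, item-total correlations near 1) are artifacts of
  this decomposition and are not meaningful; item-level analyses belong on
  generated cohorts.

A self-check asserts every reproduced marginal each time the fixture is
built.

## Psychometrics conventions

Cronbach's alpha uses the variance decomposition with n−1 denominators.
Corrected item-total correlations correlate each item with the sum of the
other eight. Group comparisons use Welch's t by default (pooled-variance
optional); the published item table does not state which variant was used,
so t statistics are not treated as exact targets. The per-item LR+
dichotomizes at score ≥ 1 by default (any endorsement); the published
dichotomization rule is unstated, so per-item LR+ values are rank targets
only. Multiple testing uses a Bonferroni-type correction: raw p times the
number of items, capped at 1.

## Problem sizes and determinism

Test and acceptance computations use the deterministic 125-subject fixture
for every exact target, cohorts of 10,000 for the alpha band, and cohorts
of 100,000 for rank and recovery properties — sizes at which the checked
gaps exceed sampling noise severalfold. Every stochastic draw flows from a
single `numpy.random.default_rng` seed; the same (config, seed) pair yields
a byte-identical cohort.

## Known limitations

- The generator's equicorrelated single-factor structure cannot express
  item-specific reliability deficits; it reproduces the appetite item's low
  item-total correlation only through its moments, and more weakly than the
  study observed (0.50 vs 0.37).
- Brain-mind statistics are approximate (see above).
- Test–retest reliability and sensitivity to change are out of scope; the
  evaluation is cross-sectional.
- Predictive values are at the study prevalence (14%); no post-test
  probability machinery for external prevalences is provided.
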