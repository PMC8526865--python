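# Methods

This note documents the statistical model behind the package, the
generative model used to test it, the numerical choices, and the known
limitations.

## The measurement model

A looking-while-listening (LWL) trial shows two pictures side by side while
a carrier phrase names one of them (the *target*).  Gaze is sampled at
60 Hz over a trial spanning −1,000…7,000 ms around picture onset; each
sample is classified as a look to the left picture region, the right
picture region, elsewhere on screen, or off-screen/invalid.  Looking is
scored over a post-naming window of 368–3,505 ms after target-word onset.

Comprehension is operationalised by the **proportion index (PI)** of a
yoked picture pair.  With p₁ and p₂ the target-looking proportions of the
pair's two trials (each picture named once, AOI-only denominator
target/(target+distractor)),

    PI = p₁ + p₂ − 1 ∈ [−1, +1].

Equivalently, PI is the looking to one image when it is named minus the
looking to that same image when the other is named; the two anchorings are
arithmetically identical, which is exactly true *only* under the AOI-only
denominator — the reason that denominator is the package default.
**PI-by-infant** averages one infant's pair PIs; **PI-by-item** averages
one pair's PIs over infants.

### Exclusion rules

1. *Trial level:* trials with less than 12.5% valid on-screen looking
   (any of the three on-screen categories) during 0–7,000 ms are dropped
   (fussiness).  The criterion is strictly `<`, so exactly 12.5% is kept.
   The −1,000 ms preview second does not enter the denominator: "during
   the trial" is read as the stimulus-presentation period.
2. *Pair level:* a pair yields a PI only when **both** of its trials
   survive; single-trial pairs are logged and dropped.
3. *Infant level:* infants contributing fewer than 4 scoreable pairs (of
   14) are excluded.
4. *Optional rare-word rule:* per infant, pairs where the parent rated
   either word's exposure 1 ("rarely") can be dropped before analysis.

All exclusions are logged with participant/trial identifiers and a reason;
the logs exactly account for row-count differences.

## Inference

* **Wilcoxon signed-rank** (two-sided, against 0).  Exact
  dynamic-programming null distribution when n < 50 with no zeros or ties
  (subset counts stay below 2⁵³, so float64 DP is exact); otherwise the
  normal approximation with continuity correction and tie-corrected
  variance.  Zeros are dropped before ranking; ties get midranks.
  The 95% CI inverts the test over the Walsh averages (Hodges–Lehmann);
  the exact branch mirrors the classical signed-rank quantile
  construction, the approximate branch uses the large-sample
  quantile-index formula.  The source analyses this package reproduces do
  not state their CI method; Hodges–Lehmann is the standard companion and
  is adopted as a reconstruction.
* **Cohen's d** (one-sample): (mean − μ)/SD with the n−1 denominator.
* **Kruskal–Wallis** across age groups (midranks, tie correction) and
  **Pearson correlations** (one-sided variants supported) delegate to
  scipy behind the package surface.
* **Default-prior Bayes factors**, reported as BF01 (evidence for the
  null):
  * one-sample t family: Jeffreys–Zellner–Siow — Cauchy(0, √2/2) prior on
    the standardised effect size, marginalised against the noncentral-t
    likelihood by adaptive quadrature (absolute tolerance 1e−10);
    depends on the data only through (t, n), so printed summary
    statistics suffice to reproduce published values;
  * Pearson correlation: stretched-beta(1/κ, 1/κ) prior on ρ with
    κ = 1/3, integrated against the exact sampling density of r (the
    hypergeometric form, evaluated in logs); depends only on (r, n).
  * One-sided variants truncate the prior and renormalise.  The test
    suite checks both integrators against independent dense-grid
    trapezoid oracles and, for correlations, against pingouin's
    closed-form implementation.
  * Evidence labels follow the anecdotal (1–3) / moderate (3–10) /
    strong (10–30) / very strong (30–100) / extreme (>100) ladder on
    max(BF01, 1/BF01).

### A reporting quirk reproduced deliberately

The directional correlation Bayes factors in the reference results follow
a *complement-row* convention: interval-hypothesis BF software reports the
stated interval (ρ > 0) and its complement against the null, and the
published "BF01" values equal the **complement row's BF10** — evidence for
the opposite-signed alternative — rather than 1/BF10 of the stated
direction.  This identification rests on six independent published
anchors, each matching the complement-row value to print precision while
none matches the canonical computation.
`inference.published_directional_bf01` recomputes exactly that quantity so
published values can be reproduced; `inference.bf01_correlation` is the
canonical directional BF and is what new analyses should use.

## Cluster-based permutation test

Per retained participant, target looking is pooled over trials into 50 ms
bins spanning 0–7,000 ms (three 60 Hz samples per bin per trial; bins with
no AOI samples are missing, not zero), transformed with y = arcsin(√p),
and expressed as deviation from chance y − arcsin(√0.5) = y − π/4.
Testing deviations against zero is algebraically identical to the paired
test against a constant chance series.  Per bin, a one-sample t across
participants is computed (bins with < 2 contributors or zero variance are
skipped); maximal runs of adjacent bins with |t| > 2.02 form signed
clusters with mass Σt.  Missing bins break adjacency.  The threshold is a
configuration value, not a constant: 2.02 ≈ the two-sided t critical value
near df 40.

The null distribution of max |mass| is built from 1,000 resamples that
flip the sign of each participant's entire deviation series with
probability ½ — the standard exchangeability argument for one-sample
cluster tests, chosen because it preserves within-participant temporal
autocorrelation (the dwell structure that makes cluster masses large).  A
participant-resampling bootstrap of the mean-centred series is available
behind a flag, since the wording of the procedure this reproduces is
ambiguous between the two.  Cluster p = b/B (no add-one smoothing,
matching common package behaviour; (b+1)/(B+1) available), significant at
p < 0.05.

## The synthetic-gaze generator

The generator produces the full study design: 3 age groups (ages drawn
uniformly per group in 30-day-month bands 6.1–8.0, 8.0–11.0, 11.0–15.0),
14 yoked pairs × 2 presentations (once per half, sides and naming order
counterbalanced at random, order shuffled within half), 481 samples per
trial on the 60 Hz grid.

Looking is a two-state **dwell chain** (target/distractor) at the sample
level: before the named word has been heard (plus a truncated-normal
saccade latency, mean 300 ms, SD 100 ms, lower bound 0) the chain is
symmetric; afterwards its transition rates become P(T→D) = c(1−p*),
P(D→T) = c·p* with c = 2(1−stay_prob), giving stationary target
probability p* = 0.5 + δᵢⱼ while keeping overall gaze mobility comparable
across bias levels.  The per-infant, per-pair bias is

    δᵢⱼ = clamp(δ + infantᵢ + β·imbalanceⱼ),   infantᵢ ~ N(0, τ²).

Bias enters through the stationary distribution rather than per-sample
independence deliberately: independent samples would understate
cluster-mass variance and invalidate the permutation test's calibration.
An independent on/off chain (hazards p_off = 0.02, p_return = 0.15,
≈ 12% off-screen occupancy) superimposes off-screen excursions; "fussy"
trials (probability 0.12) switch to much higher off-screen occupancy
(≈ 94%), so they fall below the 12.5% attention filter.  The first sample
after each dwell switch is recoded as an on-screen non-AOI look (the gaze
travelling between pictures), which keeps the AOI-denominator semantics
exercised.

Default effect structure: δ = −0.03, τ = 0.05, β = 0.03 per Likert point.
With the default stimulus set's mean imbalance of ≈ 1.01 Likert points,
the grand-mean bias δ + β·1.01 is ≈ 0: a cohort at chance overall with
imbalance-driven item differences — the regime the reference findings
describe.  The stimulus set's named anchor pairs carry the reported mean
ratings (diaper 4.68 / brush 2.26; hat 3.72 / bottle 3.67), and parental
ratings are clamp(round(true ± N(0, 0.7)), 1, 5).  Comprehension status
follows a logistic model in age and true exposure, calibrated so a
10-month-old with average exposure understands roughly 11–13 of the 28
words.  Dwell persistence (stay_prob = 0.95, mean dwell ≈ 333 ms),
fussiness and latency values are plausible placeholders — the reference
material reports no empirical dwell or fussiness distributions — and are
stated here as such.

### The analytic PI oracle

`expected_pi` gives E[PI] for homogeneous configurations (τ = β = 0).
The dwell chain's target probability q_k relaxes geometrically (rate 1−c)
from 0.5 to 0.5 + δ once the bias is active.  One subtlety matters: the
arrival-sample recoding makes scored AOI samples the *non-arrival* ones,
and conditioning on "no switch" over-represents the state with the lower
leave-rate (the target, once δ > 0), so the scored expectation is
P(target, no switch)/P(no switch), slightly above q_k.  The oracle
propagates q_k exactly across the grid, weights window samples by their
scoreability probability, and integrates the truncated-normal latency on
a grid; it matches brute-force chain simulation to < 0.01 and the full
generator-plus-pipeline to < 0.02 at ~200 infants.  It supports the
transit-recoding settings 0 and 1 samples; off-screen excursions are
independent of the dwell state and cancel.

### What the generator does not emulate

Pixel-level gaze and saccade kinematics; anticipatory or word-specific
looking strategies; drift and calibration error; item-specific salience
differences beyond the frequency-imbalance channel; attrition patterns
correlated with age.  Passing tests therefore demonstrate correctness of
the *pipeline* under a plausible gaze process with known truth — not that
real infant data satisfy the model.

## CHAT transcripts and corpus counts

Word-frequency imbalance has two routes: parental Likert ratings
(|mean_a − mean_b| per pair, means over responding parents) and corpus
token counts from CHAT transcripts.  Transcripts whose target child is
33 months or older are excluded; within a document, tokens are counted
case-insensitively by exact orthographic match (no lemmatisation or
compound splitting — the simplest reproducible rule) across all speakers
*except* the target child, since the measure is what the child heard.
The CHAT reader is a minimal parser for headers, `@ID` ages
(`years;months.days`, 30-day months) and utterance tiers; the writer emits
small valid documents for fixtures and is labelled synthetic.

## Problem sizes used by the test suite

Calibration and recovery checks run at reduced but statistically adequate
sizes, chosen as the package's own test design: type-I calibration of the
cluster permutation uses 200 null cohorts of 24 infants × 200 resamples
(familywise rate checked against the binomial band [0.02, 0.09] around
5%); Wilcoxon null uniformity uses 2,000 exact tests at n = 40 plus the
200 generator-level cohorts; δ-recovery uses one 201-infant cohort against
the analytic oracle (±0.02); the item-effect direction uses 50 cohorts of
60 infants (positive imbalance–PI-by-item correlation required in ≥ 80%).

## Known limitations

* The approximate-branch confidence interval uses order-statistic indexing
  rather than root-finding inversion; bounds can differ from R's
  `wilcox.test` in the third decimal.
* Cluster p-values of 0 are possible under the b/B estimator; use the
  add-one mode for strictly positive estimates.
* `expected_pi` covers the homogeneous, full-post-onset-bias case only.
* The questionnaire's age–vocabulary correlation is stronger than real
  parental reports typically show; it is a convenience model, not a fit.
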