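# Methods

## Problem and scope

Endogenous compounds in postmortem femoral blood change with the time since
death, which confounds any metabolomics study built on autopsy material.
`pmmetab` implements the complete analysis chain for a two-time-point
design: each forensic case contributes a blood sample at mortuary admission
(t1) and a second one at autopsy (t2), both measured by targeted LC-HRMS
peak integration within the same instrument batch. The pipeline covers the
38-compound analyte panel, quality control, three normalization strategies,
paired and unpaired nonparametric inference, and a four-pattern temporal
classification, together with a synthetic cohort generator that emulates
the study's structure so that every stage is testable against a known
ground truth. The real cohort is not publicly available; the package's
input schema accepts such tables unchanged should they be obtained.

## Analyte panel and monoisotopic masses

The shipped panel (`data/panel_rp.csv`) lists 38 compounds — amino acids,
acylcarnitines C0–C18, phospholipids, bile acids, a steroid, and others —
with sum formula, printed accurate mass, logP (flagged experimental vs
predicted), and retention times in reversed-phase and HILIC chromatography.
Monoisotopic masses are computed from the formula with a fixed table of
lightest-isotope atomic masses (AME2020/CODATA: H 1.00782503, C 12 exact,
N 14.00307400, O 15.99491462, S 31.97207100, P 30.97376200 Da), making the
computation bit-reproducible. Four long-chain acylcarnitine rows
(C12–C18) print the protonated-cation formula and m/z rather than the
neutral species; the loader detects this (computed minus printed equals one
electron mass, 5.486e-4 Da) and records `mass_convention="cation"`. Five
lipids are listed by class shorthand without a formula and carry no mass.
Leucine/isoleucine is a single isobaric entry with one integration.

## Synthetic cohort model

Peak areas follow a fully multiplicative model:

    area(case i, analyte a, time t) =
        exp(N(mu_a, sigma_inter)) * f_a(t) * batch(b, a) * prep(sample)
        * exp(N(0, sigma_intra))

- **Temporal drift** f_a(t), one of four patterns: steady increase
  f = 1 + r·t; lag-then-increase f = 1 for t < lag, then 1 + r·(t − lag);
  decrease f = max(exp(−r·t), 0.05) (floored so areas stay positive and
  detectable); stable f = 1.
- **Collection times**: t1 and Δt = t2 − t1 are log-normal, truncated by
  resampling to the study's observed ranges — t1 median 8 h in 1.3–290 h
  (log-sd 1.0), Δt median 71 h in 6.4–434 h (log-sd 0.8). Only medians and
  ranges are reported for the real cohort; the log-normal shape and log-sds
  are our modelling choice, fixed once and checked by Monte-Carlo tests
  (simulated medians fall in [6, 10] h and [60, 85] h).
- **Design structure**: 427 cases in 17 batches, both samples of a case in
  the same batch, 5 pooled-QC injections per batch, three isotope-labelled
  internal standards (creatinine-d3, arginine-13C6, phenylalanine-d1)
  spiked at fixed nominal levels, and 163/427 cases with day-level-only
  time of death (flagged, with noon/midpoint imputation helpers).
- **Noise defaults** (log-sd of multiplicative log-normal factors):
  between-case `sigma_inter` 0.6, measurement `sigma_intra` 0.15, batch
  `sigma_batch` 0.15, per-sample preparation `sigma_prep` 0.10, IS
  injection repeatability 0.05. These reproduce the reported QC landscape:
  IS RSDs among authentic samples of roughly 20–25% (under the 30%
  acceptance bound), pool RSDs near 15%, and occasional intra-batch pool
  excursions past the 20% gate — mirroring the fact that the study's own
  criteria were not met by every analyte. QC failures therefore warn and
  annotate, they never abort.
- **Default kinetics** assign each panel analyte its published temporal
  pattern, with the drift rate calibrated so that the modelled change at
  the central pair (t1 = 8 h, t2 = 79 h) equals the magnitude of the
  published overall paired median change. Two analytes (proline, valine)
  are listed as increasing although their reversed-phase paired medians are
  negative (a matrix effect in that chromatography mode); the generator
  follows the pattern taxonomy and uses the magnitude only.
- A ground-truth table (kinetics, batch factors, preparation factors) is
  always emitted; acceptance tests are parameter-recovery based.

What the generator does **not** emulate: cause-of-death covariates,
drug co-detection, chromatographic drift within a batch, missing or
censored integrations, non-multiplicative (additive background) noise, and
any dependence of drift on case covariates. Passing tests therefore show
that the pipeline recovers what the multiplicative model plants, not that
real postmortem data satisfy that model.

## Quality control

- **RSD**: 100·sd/mean with sample (n−1) sd.
- **Grubbs screen**: two-sided single-outlier test per internal standard at
  alpha 0.05, on IS areas batch-normalized by the batch's pool-mean IS area
  (the same transform as batch correction, making batches comparable before
  a single pooled test; a per-batch option exists since the original
  pooling is not documented). Critical value
  ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper alpha/(2n) Student-t quantile
  (n−2 df); this reproduces published Grubbs tables to three decimals.
  Single pass, non-iterative. A sample is excluded only when flagged for
  all three standards — one deviant IS more plausibly reflects that
  standard's chemistry than a failed injection.
- **Drift gates**: pooled-QC areas within 20% (intra-batch) and 30%
  (inter-batch, RSD of batch means); retention-time gates of 0.05/0.2 min
  apply when RT columns are present and pass trivially otherwise.

## Normalization

- **Batch correction** divides each area by the mean pool area of the same
  analyte and batch; corrected pool means are exactly 1, and batch factors
  cancel exactly under the multiplicative model.
- **IS normalization** divides an analyte by its matching labelled
  standard (creatinine→creatinine-d3, arginine→arginine-13C6,
  phenylalanine→phenylalanine-d1); all other analytes fall back to
  phenylalanine-d1 with a logged notice.
- **PQN** is applied to the batch-corrected table: per sample, the median
  over analytes of value/reference is the dilution factor, divided out.
  The default reference is the grand pool-mean spectrum (configurable to
  the median spectrum of all samples; which variant the original used is
  not documented). On a noise-free pure-dilution cohort PQN recovers the
  planted preparation factors exactly; when a majority of the small panel
  drifts with time, the median quotient absorbs part of the temporal
  effect and attenuates the recovered change — a bias the test suite
  asserts rather than hides, and the reason the paired stage runs on raw
  areas by default.

## Statistical inference

All tests are two-sided and rank-based, implemented in-package with exact
small-sample branches (scipy supplies only reference distributions):

- **Wilcoxon signed-rank** (paired t2 vs t1): zero differences discarded,
  midranks on |d|, W = min(W+, W−); exact p by a dynamic program over the
  2^n sign patterns (ranks doubled to integers so ties are exact) for up to
  25 nonzero differences, otherwise tie-corrected normal approximation with
  continuity correction.
- **Mann–Whitney U** (t1-vs-t2 sampling-procedure check in the 24–36 h
  group): exact by enumeration of group assignments for N ≤ 12, else
  tie-corrected normal approximation.
- **Kruskal–Wallis** with tie correction against chi-square (k−1 df); a
  full-permutation exact branch exists for N ≤ 10 and is used by the test
  oracles.
- **Dunn's post-hoc** on the joint ranks with the tie-corrected variance
  N(N+1)/12 − ΣT/(12(N−1)), run only on Kruskal–Wallis-significant
  analytes (gate on the Holm-adjusted KW p by default).
- **Holm step-down** controls the family-wise error rate. The adjustment
  is applied across the 38-analyte family within each comparison (overall
  and per bin) for the paired stage, across analytes for the KW screen,
  and across the 45 group pairs within each analyte for Dunn (per-analyte
  rather than analytes×pairs; the original scope is not documented). The
  source describes Holm as a false-discovery-rate correction; Holm is an
  FWER procedure and is implemented as named, not silently replaced by
  Benjamini–Hochberg.
- **Median confidence intervals** are distribution-free order-statistic
  intervals from Binomial(n, 1/2) quantiles; below n = 6 the interval
  degenerates to (min, max) and is flagged.
- Significance codes: ns > 0.05, * < 0.05, ** < 0.01, *** < 0.001, always
  derived from the adjusted p.

## Binning

Both schemes use half-open intervals [lo, hi) with the boundary assigned to
the upper bin (12.0 h → "12–24 h"; 6.0 h → group 2) — the printed interval
lists are ambiguous at shared endpoints, so one convention is fixed and
tested. Paired Δt bins: 0–12, 12–24, 24–36, 36–48, 48–72, 72–96, 96–120,
120–144, >144 h. Unpaired tx_ToD groups 1–10: the same with 0–6 and 6–12
replacing 0–12. The paired stage uses raw areas (batch factors cancel
within a pair); the unpaired stage uses batch-corrected areas because
different cases sit in different batches.

## Temporal pattern classification

The published four-group taxonomy gives one numeric anchor: "no or < 30%
change over time" for the stable class. The remaining rules are our
documented reconstruction, validated only on synthetic ground truth, with
all thresholds exposed as parameters:

1. **stable** — every per-bin |median| < 30%;
2. **decrease** — final median ≤ −30% and no median above +30%;
3. **lag_then_increase** — every bin of the lag window (bins whose upper
   edge is ≤ 36 h) flat, i.e. |median| < 15% (half the band: an early
   profile already drifting inside the band signals a steady rise, not a
   lag), and a later bin above +30%;
4. **steady_increase** — the first out-of-band bin is positive and the
   profile ends at its running maximum within half a band.

Profiles matching no rule fall back to the nearest rule with a
low-confidence flag, so every analyte receives exactly one pattern. Bins
with fewer than 10 pairs are excluded as evidence (medians of a handful of
pairs are dominated by measurement noise); on small cohorts the threshold
relaxes until four bins remain. Note that a lag in absolute time appears
shortened by the admission delay in Δt space (a 48 h lag looks like a
~40 h lag when t1 ≈ 8 h), and pairs with late admission leak post-lag
signal into early Δt bins; classification accuracy on synthetic cohorts
(≈ 97–98% with well-separated kinetics at 427 cases) is bounded by this
leakage, not by the statistics.

## Interpretation stage

Per-analyte change magnitudes are correlated (Spearman) with logP,
molecular weight and retention time; on generator cohorts drift is
assigned independently of these properties, and the pipeline reproduces
the null result. The paired/unpaired concordance correlates each
analyte's overall paired median change with its highest unpaired change
versus group 1 (ties toward the later group); on default synthetic cohorts
rho² is typically 0.86–0.93. The normalization-mode comparison reruns the
paired stage under batch-only, IS, and PQN modes and reports the PQN
attenuation ratio (median over drifting analytes of |PQN change| /
|batch-only change|, ≈ 0.6 on the default cohort). Cross-platform
concordance correlates two acquisitions' per-bin profiles per analyte and
flags sign-discordant analytes.

## Problem sizes and numerical choices

Simulation-based tests use the study's own dimensions where the property
depends on them (427 cases for parameter recovery, concordance and pattern
recovery; 100 pairs × 1000 replicates for type-I calibration; 60-case
cohorts for the normalization-bias screens, where the property is
scale-free). The generator is vectorized, so a full 427-case, 38-analyte
cohort simulates in well under a second. All randomness flows through a
single seeded `numpy` generator; identical config and seed give
byte-identical output tables. Exact-test branches switch to normal
approximations at 25 (Wilcoxon) and 12 (Mann–Whitney) observations, where
the two branches agree to within 0.01 in p.

## Known limitations

- The pattern rule set is a reconstruction; with gently drifting analytes
  the lag and steady classes genuinely overlap in Δt space, and the
  shipped default kinetics (calibrated to modest published changes) are
  *not* well-separated in this sense.
- PQN on a 38-analyte panel with majority drift is biased by construction;
  the package exposes the bias rather than correcting it.
- The unpaired stage inherits whatever between-case variation the cohort
  carries; it is noisier than the paired contrast and is not corrected for
  case covariates.
- The generator's multiplicative-noise assumption makes ratio corrections
  exact; real detector noise is not purely multiplicative.
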