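# Methods

## The score and its decision rule

A tumor's somatic single-base substitutions, read on the coding
non-transcribed strand, are classified into the 12 ordered classes
C>A, G>T, C>G, G>C, C>T, G>A, A>C, T>G, A>G, T>C, A>T, T>A.  Keeping all
12 classes (rather than the 6 obtained by collapsing complementary pairs)
preserves transcriptional strand bias, which carries the signal of
transcription-coupled repair of bulky tobacco adducts; the 96
trinucleotide-context classes are deliberately avoided to keep the test
usable on a plain ref/alt list.  Relative frequencies are percentages of
the per-tumor total; the mutational burden (prevalence) is
total / target-region size in Mb.

The EASILUNG score combines eight classes: four thresholded binary terms
(+175 if %CA > 12, +62 if %GT > 13, −74 if %AG > 5, −73 if %TC > 5; all
comparisons strict, boundary values fall in the "≤" arm) and four
continuous terms (−9·%CT, −6·%GA, −17·%AC, −17·%TG).  One caution for
implementers: a compact statement of the formula sometimes omits the
−17·%TG term, but the coefficient table and both worked examples include
it, so this implementation includes it.  Scores are computed on unrounded
frequencies by default; a round-half-up-to-whole-percent mode reproduces
the integer worked-example arithmetic exactly.

Classification proceeds gate-first: a sample below 1 sub/Mb is labelled
`non-lung-low-burden` and receives no score or probability (the score is
statistically meaningless on a handful of substitutions, and lung tumors
of smokers below that burden are rare).  Otherwise the sample is `lung`
iff score > threshold; at exactly the threshold the call is non-lung.
The calibrated probability is expit(A + B·score) with (A, B) =
(1.216, 0.010) for the development variant and (2.094, 0.008) for the
validation variant.  Note that expit(1.216 + 0.010·93) = 0.8953, which a
two-decimal truncation displays as 0.89.

## Development pipeline

`develop_score` re-derives a score of this family from any labelled
cohort:

1. **Gate.** Samples under `low_burden_cutoff` (default 1 sub/Mb) are set
   aside; they re-enter only in the overall performance tally.
2. **Binarization.** Eight classes (%CA, %GT, %CG, %GC, %AG, %TC, %AT,
   %TA) enter as binary indicators thresholded at their Youden-optimal
   cut-point; %CT, %GA, %AC, %TG stay continuous.  This fixed default
   mirrors the reference analysis; `binarize="auto"` instead binarizes
   classes whose decile empirical-logit trend is non-monotone
   (|Spearman ρ| < 0.9 between group mean and group logit), and an
   explicit class list is accepted.  The fixed set is the default because
   the automatic rule, applied to smoothly monotone simulated cohorts,
   binarizes nothing — reasonable statistically, but then the developed
   model is not comparable to the published one.  Keeping all 12 raw
   frequencies continuous is impossible anyway: they sum to 100 and are
   collinear with the intercept.
3. **Full fit** of the 12 predictors by maximum-likelihood logistic
   regression (statsmodels; Wald SEs, p-values, exp(β) odds ratios).
4. **Backward selection**: repeatedly drop the largest-p predictor while
   it exceeds α = 0.2 (ties break toward the earlier column).
5. **Bootstrap stability**: backward selection on B with-replacement
   resamples (default B = 1000; configurable — tests and examples use
   50–200 to keep runtimes in seconds); predictors selected in ≥ 60% of
   resamples survive.  B, the retention fraction and the RNG seed are
   explicit parameters; the procedure is deterministic given the seed.
   Resamples that lose a label class or fail to fit are redrawn (bounded
   retries).  A caveat established by the test suite: stability selection
   does **not** undo in-sample selection optimism — predictors that owe
   their apparent effect to sample-specific noise are stably re-selected
   in resamples of the same sample, so a null cohort can still yield a
   non-empty "stable" set.  The honest null check is out-of-sample: a
   score developed on label-independent data shows AUC ≈ 0.5 on a fresh
   cohort, and the tests assert exactly that.
6. **Points**: 100·β rounded half-away-from-zero per retained term; the
   intercept is absorbed into the calibration, never into points.
7. **Assessment**: logit calibration of outcome on the integer score;
   rank-based AUC (midranks for ties, identical to Mann–Whitney
   U/(n₁n₀)); Hosmer–Lemeshow χ² on deciles of predicted risk
   (χ² = Σ(O−E)²/(E(1−E/n_g)), df = groups − 2, degenerate groups merged
   with a neighbor); Youden-optimal threshold with Wald 95% CIs
   (p̂ ± 1.96·√(p̂(1−p̂)/n)); overall sensitivity/specificity over the whole
   cohort with gated lung cases counted as misses and gated non-lung
   cases as correct rejections.  2×2 odds ratios use Woolf intervals
   (exp(ln OR ± 1.96·√Σ1/cell)), with Haldane +0.5 on zero cells.

Numerical conventions worth stating: Youden searches run over all
observed values plus a −∞ sentinel with the predicate `value > cutoff`;
ties break toward the smallest cutoff, and the positive direction is the
one giving an odds ratio ≥ 1.  Logistic fits that fail to converge or
drift beyond |β| > 1000 are reported as separation; rank-deficient
designs are rejected with the collinear columns named.  Empirical logits
of pure decile groups use the +0.5 continuity correction
ln((y+0.5)/(n−y+0.5)).

## Recalibration

Discrimination transfers across platforms (an affine map with positive
slope leaves the ROC invariant — asserted as a test invariant), but
calibration does not.  `fit_recalibration` fits label ~ score on the new
cohort; (A, B) = (0, 1) means the score's logit is already calibrated.
`validate` reports the AUC, the Hosmer–Lemeshow test on the recalibrated
probabilities, se/sp at the old threshold, and a new Youden threshold —
reported on the **original** score scale, so the unmodified score terms
plus the new threshold form a deployable model.  Low-burden samples never
enter the recalibration fit.

## Synthetic cohorts

`simulate_cohort` draws, per tumor: a label (lung with probability 0.1 by
default, echoing the ~10% lung share of a pan-cancer cohort), a capture
size uniform on 36–64 Mb, a burden log-normal per label (lung: log-mean
1.6, log-sd 1.0, median ≈ 5 sub/Mb, so few lung tumors fall under the
gate; non-lung: log-mean 0.35, log-sd 1.5, median ≈ 1.4 sub/Mb, so a
sizable minority is gated), a 12-class spectrum from a Dirichlet around
the label's mean profile, and counts from a multinomial with
total = round(burden × Mb).  The mean profiles are anchored on the two
worked examples (C>A/G>T-rich lung-like vs C>T/G>A-rich non-lung-like),
each completed to 100% by splitting the unassigned remainder equally over
C>G, G>C, A>T and T>A — an admittedly arbitrary completion.  Zero-mean
classes get a floored Dirichlet weight (0.01) so they remain representable.

The Dirichlet concentration defaults to 3.  This was chosen to match the
heavy inter-tumor dispersion of real cohorts, in which roughly half of
lung tumors exceed the %CA/%GT cut-offs while well under a tenth of
non-lung tumors do; concentrations of ~50 make the two classes nearly
separable in %CA alone, a regime real spectra are not in and in which the
logistic MLE of the full model does not even exist.  What the generator
does **not** emulate: trinucleotide context, histology and smoking-status
substructure within the lung class (real lung cohorts are mixtures of
smoky and non-smoky spectra; the generator's lung class is unimodal),
platform-specific artifacts (e.g. FFPE C>T/G>A inflation), and
correlation between burden and spectrum.  Passing pipeline-recovery tests
therefore demonstrates correctness of the machinery under the stated
model, not clinical performance on real data; the published
dataset-level figures (development AUC 0.931, Se 85.7%/Sp 89.6% at −303,
validation Se 83.0%/Sp 72.3% at −467) require the original cohorts and
are carried here only as fixed constants of the bundled model variants.

## Problem sizes used by the test suite

The default simulated development cohort is n = 2000 (seed 7) with
bootstrap B = 50–200; recalibration recovery uses n = 5000 per replicate
with coverage asserted over 40–60 replicates.  These sizes give stable
statistics in seconds while remaining an order of magnitude below the
original cohorts.

## Known limitations

* The development pipeline reports in-sample performance; no optimism
  correction (e.g. bootstrap-validated AUC shrinkage) is implemented.
* Wald intervals are used throughout for proportions, matching the
  reference conventions; they degenerate at p̂ ∈ {0, 1}.
* MAF parsing assumes alleles are reported on the genomic + strand and
  complements through the gene's `Strand` column; inputs with a
  different convention must be pre-oriented and supplied as pair lists.
* All single-base substitutions are counted; no functional-class
  (silent/non-silent) filtering is applied.
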