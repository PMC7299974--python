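# Methods

## Rhythm model and test

A timed series is modelled as a fixed-period harmonic regression

    y(t) = M + sum_{k=1..H} [ a_k cos(2 pi k t / P) + b_k sin(2 pi k t / P) ] + e,

with P = 24 h and H = 1 by default (a pure sinusoid, matching the
sine-wave-regression tradition for circadian data; H up to 3 is available for
skewed waveforms). The design is solved by least squares; rhythmicity is the
F-test of the full model against the intercept-only model,

    F = [(SSE0 - SSE1) / 2H] / [SSE1 / (n - 1 - 2H)],   df = (2H, n - 1 - 2H),

with the p-value from the F distribution. Replicates at a timepoint enter as
independent observations; timestamps are folded modulo the period before
fitting (exact, since the basis is periodic), which also handles
constant-darkness recordings expressed as elapsed hours. Bin-labelled intake
data are fitted at bin midpoints — a 6-h bin is represented by its centre,
the unbiased choice for a symmetric window.

Reported quantities: mesor M; amplitude sqrt(a1^2 + b1^2) (half the
peak-to-trough of the fundamental); acrophase atan2(b1, a1) * P / (2 pi)
mapped to [0, P), the clock time of the fundamental's maximum. A grid-search
acrophase at 0.1-h resolution is provided for parity with peak-time tables;
it agrees with the closed form to half a grid step, ties breaking toward the
earlier time.

Degenerate inputs: a constant series has amplitude 0, F defined as 0, p = 1
and an undefined acrophase; a noise-free series fits exactly and is reported
with p = 0 and a `perfect_fit` flag; designs with fewer distinct timepoints
than parameters raise a design error. P-values are raw by default (matching
single-series usage); Benjamini-Hochberg is available for the genome-wide
screen.

Circular phase differences use the convention
d = P/2 - ((P/2 - (a - b)) mod P), mapping to (-P/2, P/2] with the antipodal
difference reported as +P/2; positive d means a is phase-delayed relative
to b.

## Behavioral indices

- **Caloric conversion**: chow 2.988 kcal/g, chocolate 5.3 kcal/g, cookie
  4.95 kcal/g (configurable). Lick counts are used directly, with no volume
  conversion; a ratio is always formed within one common unit.
- **CPP preference index**: time in the food-conditioned chamber over the
  summed time in the two conditioning chambers. The two-chamber denominator
  is the default because it makes indifference exactly 0.5, the customary
  chance line; an `include_neutral` switch adds the corridor time for the
  alternative reading. Pre-test exclusion keeps animals with PI in
  [0.35, 0.65] — symmetric about chance, bounds inclusive and configurable,
  since published exclusion thresholds are rarely stated numerically.
- **Overconsumption**: per bin, total choice-condition intake over the bland
  item's homeostatic baseline. The default baseline is the group mean of a
  separate non-choice cohort (the usual design); an animal-matched mode
  divides by the same animal's own baseline when one cohort provides both
  phases. Zero-baseline bins yield an explicit NaN-with-flag rather than
  infinity so downstream rhythm fits are not poisoned.
- **Microdialysis**: the k = 5 20-min fractions nearest the snack on each
  side are averaged; the response is 100 * (post - pre) / pre, negative for
  decreases.
- **ΔΔCt**: fold = 2^-[(Ct_goi - Ct_ref)_sample - (Ct_goi - Ct_ref)_calibrator].
- **Knockdown inclusion**: strict "more than" 50% reduction, i.e.
  rel_expr < 0.5.

## Transcriptome screen

Values are first normalized per gene to mean 1 (zero-mean genes are dropped
and reported). Each gene is then fitted with the harmonic model; since all
genes share one set of sample timestamps, the screen solves the whole matrix
against a single design in one batched least-squares call — exactly
equivalent to per-gene fits (asserted in the tests) and fast enough to
screen thousands of genes in seconds. Genes with p < 0.05 are flagged R.

The phase-sorted heatmap restricts rows to R genes ordered by acrophase
(ties by identifier), with one column per timepoint (replicate means)
duplicated over two periods. The acrophase histogram uses 1-h circular bins;
mode detection — an extrapolation, since published cluster peaks are usually
read off the histogram by eye — smooths counts with a 3-bin circular moving
average and reports local maxima exceeding 1.5x the mean bin count.
Cross-tissue comparisons consume phase tables directly and report per-gene
circular deltas plus their circular mean; reproducing published reference
phases for other tissues would require external datasets and is out of
scope, so the operation is exercised on synthetic phase maps.

## Synthetic-data generators

The generators emulate the study design the pipeline targets, and their
defaults are the study conditions, not tuning knobs:

- **Intake** (`gen_intake`): 4 x 6-h bins, cohorts of 10 animals per
  condition. Homeostatic chow intake is a cosine with mesor 2.5 kcal/bin
  (~10 kcal/day, ~3.3 g chow/day), amplitude 1.5 kcal/bin and acrophase
  ZT15 (inside the observed ZT12-18 peak window), with Gaussian bin noise
  (SD 0.25 kcal) truncated at zero — truncation biases very-high-noise
  configurations upward, documented here rather than corrected. Choice
  cohorts multiply the same profile by a raised-cosine overconsumption
  factor running from 1 (active phase) to 4-fold (rest phase, acrophase ZT3;
  the reported range is 2-7-fold), split 85:15 between chocolate and chow.
  Clock-mutant genotypes scale both oscillation amplitudes by
  (1 - mutant_damping), preserving means.
- **Expression** (`gen_expression`): 2000 genes — a desk-scale stand-in for
  a ~26k-probe array — at 4 ZTs x 4 replicates. 10% of genes are rhythmic
  with relative amplitudes 0.3-0.6 and acrophases from an equal two-component
  wrapped-Gaussian mixture at ZT3 and ZT16 (SD 0.75 h); relative noise SD
  0.1, log-normal baselines. Expected screen fraction at alpha = 0.05 is
  therefore ~0.10 + 0.05 x 0.90 = 0.145.
- **CPP** (`gen_cpp`): pre-test PI centred at 0.5, test PI at 0.70
  (SD 0.06), ~1/3 of the 300-s session in the neutral corridor.
- **qPCR** (`gen_qpcr`): target Ct shifted by -log2(fold) against an
  invariant reference gene; default residual expression 0.3 (70% knockdown).
- **Microdialysis** (`gen_dialysate`): six 20-min fractions before and after
  the snack; morning sessions respond +35%, night sessions 0%.

Each generator draws from its own fixed substream of the seed
(`default_rng([seed, stream])`), so generators can be added or reordered
without perturbing one another, and the same config reproduces byte-identical
tables. The generators do not attempt to match real between-animal variance
components (rarely printed) beyond plausible SEM scales, nor array-specific
artefacts (probe effects, heteroskedasticity, batch structure); passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to microarray noise.

## Problem sizes and numerical choices

The test suite and the acceptance script run the calibration experiments at
2000 null series (type-I error and KS uniformity), 100 series against the
least-squares oracle, 1000 acrophase grid draws, 500 phase-recovery trials,
and one full synthetic study (2 genotypes x 20 animals, 2000 genes); the
whole acceptance run completes in a few seconds. Sum-of-squares comparisons
use a 1e-12 relative floor to classify constant and perfectly fitted series;
the F statistic is clipped at zero against floating-point cancellation.

## Known limitations

- Phase recovery at low signal-to-noise is limited by the information in the
  design: for 4 timepoints x 4 replicates the asymptotic acrophase SD is
  (sigma/A) * sqrt(2/n) * 24/(2 pi) hours (0.68 h at amplitude/noise = 2),
  so no estimator reaches, e.g., 90% coverage within +/-1 h at that
  signal-to-noise; the package reports the attained rate honestly.
- Group-mean overconsumption ratios share a per-bin denominator across
  animals, which correlates their errors; with only 4 bins this can inflate
  the rhythm test's type-I error on ratio profiles of truly flat mutants in
  a minority of cohorts.
- Period is fixed; no period estimation, Lomb-Scargle or non-parametric
  detectors.
- The screen assumes one shared timestamp vector per matrix; matrices with
  per-gene missingness must be screened gene by gene via `fit_harmonic`.
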