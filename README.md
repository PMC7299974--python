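# circafeed

Circadian analysis of homeostatic and hedonic appetite in mice.

Food intake in nocturnal rodents is driven by two dissociable motivations
with opposite daily timing: *homeostatic* intake of bland chow peaks in the
dark (active) phase, while *hedonic* overconsumption of palatable food —
quantified as total caloric intake under choice conditions divided by the
homeostatic chow baseline in the same time bin — peaks in the light (rest)
phase and is blunted when core clock genes are disrupted. `circafeed`
packages the quantitative toolchain for such studies:

- **Harmonic (cosinor-style) rhythm detection.** For a timed series
  *y(t)* with fixed period *P* (24 h), the model

  *y(t) = M + Σₖ [aₖ cos(2πkt/P) + bₖ sin(2πkt/P)] + ε*

  is fitted by least squares (one harmonic by default) and tested against the
  intercept-only model with *F = [(SSE₀ − SSE₁)/2H] / [SSE₁/(n − 1 − 2H)]*.
  Mesor *M*, amplitude √(a₁² + b₁²), acrophase (clock time of the
  fundamental's maximum, also available as a 0.1-h grid search), and an R/N
  rhythmicity flag at p < 0.05 are reported.
- **Behavioral indices**: caloric conversion of binned intake, conditioned
  place preference index (chance = 0.5) with a pre-test bias filter, hedonic
  overconsumption and preference fractions, cumulative 24-h intake,
  microdialysis fraction pooling with percent-change dopamine responses,
  ΔΔCt relative qPCR quantification, and the >50 %-knockdown inclusion rule.
- **Transcriptome phase screen**: per-gene mean normalization, a
  genome-wide rhythm screen, phase-sorted double-plotted heatmap matrices,
  circular acrophase histograms with mode detection, and cross-tissue
  clock-gene phase deltas on the circular scale (−12 h, +12 h].
- **Seeded synthetic-data generators** for every input above, with
  configurable effect sizes, so the full pipeline is testable end to end.

## Worked example

```python
import numpy as np
from circafeed import SimConfig, gen_intake, overconsumption, fit_harmonic

cfg = SimConfig(seed=1)                      # WT, LD, 10 animals/cohort
intake = gen_intake(cfg)                     # long-format table, grams
base = intake[intake.condition == "baseline"]
choice = intake[intake.condition == "choice"]

prof = overconsumption(choice, base)         # per-animal x bin ratios
print(prof.ratios.round(2))
fit = fit_harmonic(prof.table.bin_start + 3.0, prof.table.ratio)
print(fit.summary())
```

```
bin_start
0.0     3.76
6.0     2.40
12.0    0.96
18.0    2.45
Name: ratio, dtype: float64
Harmonic Regression Results
==============================================
No. observations:           40
Period (h):                 24
Harmonics:                  1
Mesor:                      2.39094
Amplitude:                  1.39989
Acrophase (h):              2.929
F-statistic:                1040.3
Df (model, resid):          (2, 37)
Prob (F):                   3.045e-33
Rhythmic (alpha=0.05):      R
```

Choice-fed animals eat ~3.8× their homeostatic baseline in the early rest
phase (ZT0–6) but only ~1× in the early active phase: the overconsumption
rhythm is significant (R) with acrophase ≈ ZT3, in antiphase to the
homeostatic intake peak (≈ ZT15). The same seed reproduces these numbers
byte-identically.

A command-line surface wraps the stages:

```sh
circafeed simulate --out sim --seed 3
circafeed behavior --intake sim/intake.tsv --cpp sim/cpp.tsv --out beh
circafeed screen --matrix sim/expression.tsv --meta sim/samples.tsv --out scr
circafeed report --in beh
```

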