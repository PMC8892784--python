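# circaheart

Around-the-clock transcriptome studies ask two questions of every gene: *is
it rhythmic, and in whom?* and *is its level shifted between conditions?*
`circaheart` implements the complete analysis stack used to answer them in a
shift-work heart study design — three groups of rats (control `C`, shift
worker `W`, shift worker with restricted feeding `WRF`), sampled every 4 h
across the day (ZT1..ZT21) with three animals per group and timepoint — and
a synthetic-data generator that emulates that design with known ground truth,
so every stage can be validated by recovery experiments.

The package is for computational biologists analyzing bulk expression time
courses (fpkm-scale tables with sample labels like `WRF42ZT13`), and for
methodologists who want a tested, deterministic reference implementation of
the rhythm-detection ensemble.

## What it computes

**Rhythmicity (per gene, per group, 18 samples).** Six detectors:

1. *Harmonic (cosinor) regression* — least squares
   `y = m + a cos(ωt) + b sin(ωt)` at ω = 2π/24 h; amplitude `√(a²+b²)`,
   peak phase `atan2(b, a)/ω`, p from the F statistic with (2, n−3) df.
2. *Lomb–Scargle* — variance-normalized power `z` scanned over 25 periods in
   [20, 28] h; `p = 1 − (1 − e^{−z_max})^M` (Horne–Baliunas).
3. *JTK_CYCLE* — Kendall concordance with phase-lagged reference cosines;
   exact permutation null by dynamic programming (convolved Mann–Whitney
   distributions) for untied data, Bonferroni over lags.
4. *ARSER* — autoregressive spectral period selection in [20, 28] h, then a
   cosinor F test with the linear trend as nuisance covariate.
5. *RAIN* — Mack–Wolfe umbrella (rise-then-fall) rank statistic over
   candidate peak times, Bonferroni over peaks.
6. *F24* — fraction of spectral power at the 24-h component of the 6-point
   mean profile, significance by label permutation.

Per gene the six p-values are pooled with **Fisher's method**
(χ² = −2Σln pᵢ, 2k df), BH-adjusted across genes within a group, and genes
with q < 0.05 are called rhythmic, with phase and relative amplitude
(amplitude/mesor) from the cosinor fit.

**Differential expression.** Genes expressed above 1 fpkm in ≥ 18 of 54
samples enter a per-gene **Kruskal–Wallis** test over the pooled groups
(time ignored), BH correction, **Mann–Whitney** post-hoc pairs, a compact
letter display, and a pattern category (e.g. `WRF_up_vs_C_and_W`).

**Disease signatures.** Gene modules (≥ 50 genes after cross-referencing
with the expressed universe) are scored against a null module `M0`:
percent-upregulated with a one-sided **Fisher's exact** test, log2 WRF/C
median-ratio distributions with **Kruskal–Wallis vs M0**, and disease
up/down gene sets with a two-sample **Kolmogorov–Smirnov** test after
normalizing both distributions to 500 quantiles.

## Worked example

```bash
python examples/detect_rhythms.py
```

```
C: 50 rhythmic genes called (planted 38)
W: 24 rhythmic genes called (planted 31)
WRF: 137 rhythmic genes called (planted 124)

Venn regions (exclusive):
  C          32
  W          22
  WRF        119
  C&W        1
  C&WRF      17
  W&WRF      1
  C&W&WRF    0

WRF peak-phase bins (planted clusters at ZT8 and ZT20.5):
  ZT[7,8): 19.0 genes
  ZT[8,9): 14.0 genes
  ZT[20,21): 13.0 genes

strongest C rhythm: g00358 (q=1.60e-18, peak ZT8.8, relative amplitude 0.45)
```

The counts reproduce the shift-work phenotype the generator plants: roughly
half as many rhythmic genes in shift workers as in controls (driven both by
a lower planted fraction and by one W replicate series running 8 h out of
phase), about twice as many under restricted feeding, little overlap between
the groups, and WRF peak phases concentrated in two clusters.  The other
examples (`simulate_study.py`, `differential_expression.py`,
`disease_signatures.py`) walk the remaining stages the same way.

A thin CLI mirrors the library for shell pipelines, writing TSVs plus a JSON
run-manifest:

```bash
circaheart simulate --seed 1 --out run/
circaheart rhythm --expression run/expression.tsv --group WRF --out run/
circaheart de --expression run/expression.tsv --out run/
circaheart signature --expression run/expression.tsv --de run/de.tsv \
    --modules run/modules.tsv --gene-sets run/disease_sets.tsv --out run/
```

Identical seeds give byte-identical outputs.

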