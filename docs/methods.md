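# Methods

## Study design and data model

The pipeline targets a 3 × 6 × 3 design: groups C (control), W (shift
worker), WRF (shift worker with restricted feeding); Zeitgeber times ZT1,
5, 9, 13, 17, 21 (every 4 h starting 1 h after lights-on); three animals per
group and timepoint, each animal contributing one sample — 54 samples.
Expression values are fpkm-scale and are used exactly as given: no
re-normalization happens anywhere downstream, matching the direct use of
fpkm by the rank-based and regression tests.  Sample identity is parsed from
labels of the form `<group><animal>ZT<hour>`; replicate indices are assigned
by ranking animal IDs within each (group, ZT) cell.

## Synthetic-data generator

Each gene g has a mesor `b_g` (log-uniform on [2, 100] fpkm), per-group
rhythm flag, amplitude `a_g = rel_amplitude · b_g` (0 for arrhythmic genes),
peak phase `φ_g`, and per-group fold multiplier `m_g`.  A sample from group
k at time t realizes

    y = m_k · (b_g + a_{g,k} · cos(2π (t − φ_{g,k}) / 24)) · exp(ε),
    ε ~ N(0, σ),  σ = sqrt(ln(1 + cv²)),

so the multiplicative coefficient of variation equals `noise_cv` and values
are strictly positive (amplitudes never exceed the mesor by construction).
Multiplicative log-normal noise is the natural choice for fpkm data, whose
variance grows with the mean.

Defaults encode the emulated study conditions, chosen once:

| parameter | default | why |
|---|---|---|
| `n_genes` | 10,257 | expressed-gene universe of the emulated study |
| `frac_rhythmic` | C 0.10, W 0.05, WRF 0.20 | ~2-fold fewer rhythmic genes in W and ~2-fold more in WRF than control |
| phase distributions | C uniform; W von Mises ZT12.5 (κ=4); WRF mixture ZT8 / ZT20.5 (κ=6) | uniform control phases vs clustered W/WRF phases; κ values are calibration choices, config-exposed |
| `rel_amplitude` | 0.5 | a strong but realistic relative amplitude; also the planted value of the recovery experiments |
| `amplitude_dampening` | 0.7 | WRF rhythms oscillate with reduced amplitude |
| `replicate_phase_shift` | +8 h on W replicate series 2 | one of the three W replicate series runs out of phase (replicate desynchrony) |
| `n_de_genes` | 875/10,257 of `n_genes` | DE block scaled to the study's 875 affected genes (808 up / 67 down → `de_up_fraction` 0.923) |
| `de_fold` | 2.0 | planted fold change in WRF |
| `responder_fraction` | 2/3 | the DE block is animal-gated: only responder WRF animals express it, giving the individual-specific block structure |
| `noise_cv` | 0.2 | multiplicative CV of fpkm noise |

The generator also produces disjoint module catalogs (planted modules draw a
stated fraction of members from an up-gene set; unassigned genes form the
null module M0) and disease up/down gene-set pairs (sampled above/below a
planted log2 WRF/C threshold, or uniformly when the threshold is 0).

What the generator does *not* emulate: count-level sampling noise, library
size variation, gene-gene correlation beyond the module/DE structure,
multiple cell types, or waveform asymmetry.  Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
stated model, not performance guarantees on real tissue data.

## Rhythm detectors

All detectors target a fixed 24-h period — one sampled cycle cannot resolve
finer period structure — and period searches are restricted to [20, 28] h.
Regression/rank detectors (cosinor, Lomb-Scargle, JTK, RAIN) consume all 18
observations with repeated time values; spectral detectors (ARSER, F24) use
the 6-point per-ZT mean profile.  Every detector returns p = 1 on constant
input so Fisher combination stays defined.

**Cosinor.** OLS fit of mean + cosine + sine; F statistic (2, n−3) against
the intercept-only model; phase is the fitted peak time, relative amplitude
is amplitude/mesor.  Exact under Gaussian noise; mildly conservative under
the log-normal noise of the generator.

**Lomb-Scargle.** Classical variance-normalized periodogram on 25 periods
evenly spaced in [20, 28] h (the grid includes 24.0 h);
`p = 1 − (1 − e^{−z_max})^25`.  The 25 frequencies over a narrow band with
an 18-point series are heavily correlated (roughly 1-3 effective
independent frequencies) and the variance normalization bounds z at
(n−1)/2, so this detector is *strongly conservative*: its measured null
rejection at α = 0.05 is ≈ 0.  This matches the behavior of the cited tool
lineage; it weakens the ensemble slightly but never inflates it.

**JTK_CYCLE.** Candidate peak lags step through the sampling grid (six lags
at 4-h steps).  The reference cosine evaluated at the six ZTs has tied
values by cosine symmetry, partitioning the 18 observations into blocks of
sizes (3, 6, 6, 3).  The per-lag statistic is the between-block concordance
count T; for untied data and n ≤ 18 its exact null pmf is the convolution
of Mann-Whitney U distributions (each block against the pool of earlier
blocks — Harding's algorithm), cached per block-size tuple.  Tied data fall
back to the tie-corrected normal approximation of Kendall's tau (one-sided).
The reported p is the per-lag minimum Bonferroni-multiplied by the number of
distinct lag patterns (6); the phase estimate is the best lag.

**ARSER.** Replicates averaged; linear detrending for the spectral step;
period candidates are interior spectral peaks of AR models whose
coefficients are fit by *conditional least squares* over the order ladder
{round(n/4), round(n/3), round(n/2)} — CLS recovers a deterministic
sinusoid's AR(2) relation exactly, which Yule-Walker/Burg cannot do on a
6-point profile (their biased short-series autocovariances push the
spectral peak to the search-band edge even for a noise-free cosine).  The
24-h target is always included as a candidate and is the fallback when no
interior peak exists.  Candidates are scored by the residual of an OLS fit
of intercept + linear trend + cosinor; the reported p is the partial F test
of the cosinor pair given the trend, df (2, n−4).  Keeping the trend as a
nuisance covariate (rather than testing sequentially detrended residuals)
makes a pure linear profile exactly null and a pure cosine exactly
significant; measured null rejection is 0.050.

**RAIN.** For each candidate peak position along the time-ordered groups,
the Mack-Wolfe peak-known statistic sums pairwise Mann-Whitney counts up
the rising arm and reversed counts down the falling arm (linear umbrellas,
so monotone profiles peak at the first/last timepoint).  Per-peak p-values
use the normal approximation with the Mack-Wolfe variance scaled by the
pooled tie-correction factor; the minimum is Bonferroni-multiplied by the
number of candidate peaks (6).

**F24.** The mean profile's discrete Fourier power at the fundamental
divided by total non-DC power; p by permuting the observation-to-timepoint
assignment (balanced designs only), `p = (1 + #{perm ≥ obs}) / (1 + N)`.
The permutation count is configurable (default 10,000; the test suite and
acceptance script use 1,000, which resolves p at the 0.001 level — ample
for α = 0.05 calibration at the suite's problem sizes).

## Ensemble combination

Fisher's method: χ² = −2 Σ ln pᵢ with 2k df, p-values floored at 1e−300
before the log.  BH adjustment runs across all genes within one group's
analysis (per-group universes).  Genes with q < 0.05 are rhythmic.

Fisher's method assumes independent p-values; the six detectors examine the
same series and their −2 ln p are correlated (pairwise r ≈ 0.1-0.9), so the
combined p is *anti-conservative* even though every individual detector is
tail-conservative.  At the recovery experiment's conditions the observed
false-discovery proportion at q < 0.05 is ≈ 0.2 (tail inflation ≈ 5× at the
BH threshold).  This is a property of the stated procedure, implemented
verbatim and reported as measured.  An optional Brown's-method correction
(`brown=True` in `call_rhythmic_genes`) rescales the chi-square by the
empirical covariance of −2 ln p across genes and restores FDP control; it
is off by default because the default procedure is the verbatim one.

Phase definition: peak time of the fitted cosinor in ZT hours.  Relative
amplitude: cosinor amplitude / mesor.  A known estimator displacement: when
one of three replicate series runs Δ hours out of phase, the single-cosinor
peak of the 2:1 phase mixture sits at `angle(2/3 + e^{iωΔ}/3)/ω` past the
majority phase (+2.0 h for Δ = 8), which is where the W phase-histogram
mode is expected.

## Differential expression

Expression filter: strictly above 1 fpkm in at least 18 of 54 samples.
Kruskal-Wallis (tie-corrected, chi-square df k−1) per gene on the pooled
18-sample groups; BH across genes; q ≤ 0.05 genes get all three pairwise
two-sided Mann-Whitney tests — exact by enumeration when the pooled n ≤ 12
and untied, otherwise the tie- and continuity-corrected normal
approximation.  Post-hoc p-values are deliberately *not* multiplicity
adjusted (only the omnibus is); letters derive from raw post-hoc p < 0.05
via the insert-and-absorb clique cover of the "not significantly different"
graph, lettered in the fixed order C, W, WRF.  Categories:
`WRF_up_vs_C_and_W` requires WRF to share no letter with either other group
and to have the largest median (symmetrically for down); `W_different`
requires W's letters disjoint from both; remaining significant genes are
`other`; genes with q > α are `none`.

## Signature analysis

Modules are cross-referenced with the expressed universe *before* the
≥ 50-gene size filter; the null module M0 is always retained and must stay
usable.  Enrichment contrasts each module against M0 specifically (not the
whole universe) in a 2×2 Fisher's exact test, one-sided for enrichment
(two-sided available via `alternative=`).  Expression shift uses
log2(median_a / median_b) per gene over each group's 18 samples; genes with
a zero median in either group are excluded (a pseudocount would distort the
log2 scale) and the exclusion count is logged; module distributions are
compared to M0 with Kruskal-Wallis and reported with M0's interquartile
band.  Distribution-shift testing normalizes both samples to 500 quantiles
at Hazen plotting positions (i − 0.5)/500 by linear interpolation, then
applies the asymptotic two-sample KS test at effective n = 500 per side —
removing raw-size sensitivity as intended; KS invariance to monotone
transforms is exact up to interpolation granularity.

## Numerical and degenerate-input conventions

Zero p-values are floored at 1e−300 before logs.  Constant series yield
p = 1 in every detector and H = 0, p = 1 in Kruskal-Wallis.  Reference-value
ties inside JTK are detected after rounding to 1e−9.  The F24 permutation
observes `perm ≥ obs − 1e−12` to make float-equal statistics count as ties.
Expression tables are parsed with numpy's correctly rounded string→float
conversion so that read∘write is the identity byte-for-byte.  All
randomness flows through explicit seeds (the generator requires one; the
permutation detector takes one), making every pipeline run reproducible to
the byte.

## Problem sizes used by the test suite and acceptance script

Null calibration uses 5,000 flat genes; rhythm recovery ~500 planted
rhythms (relative amplitude 0.5, cv 0.15) among 5,000 genes; the
reprogrammed-study check 1,500 genes across all three groups; the DE screen
300 planted 2-fold genes among 5,000; permutation detectors run at 1,000
permutations in these experiments.  These sizes give stable rates (binomial
SE ≤ 0.01 on calibration estimates) while keeping a full run in the
low minutes on one CPU.

## Known limitations

- The Lomb-Scargle false-alarm correction is deeply conservative on this
  narrow-band, short-series design (see above); it contributes little
  power to the ensemble.
- Fisher combination over correlated detectors inflates the false-discovery
  proportion beyond the nominal BH level (measured ≈ 0.2 at q < 0.05 in the
  recovery experiment); use `brown=True` when FDR control matters more than
  procedure fidelity.
- RAIN uses a normal approximation for its per-peak null even at n = 18,
  where it is conservative; JTK's exact null requires untied data.
- Amplitude differences between groups are reported descriptively (relative
  amplitudes per group); no between-group amplitude test is provided.
- The generator's effect sizes are calibration choices, not estimates from
  real data; absolute sensitivities measured here do not transfer to other
  noise regimes.
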