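# Methods

## The question and the data model

An aneuploid strain carries `c` copies of some chromosome against a base
ploidy `P ∈ {1, 2}`. If transcription simply scales with template number,
genes on that chromosome show RNA log2(aneuploid/euploid) ratios centered at
`log2(c/P)` — 0.58 for a trisomy in a diploid, 1.00 for a tetrasomy. Dosage
compensation, if real, pulls a subset of those genes back toward 0. All
pipeline stages operate on a `GeneTable`: one row per (gene, strain,
replicate) carrying the DNA and/or RNA log2 ratio and a chromosome
assignment. The DNA assay anchors the copy number; the RNA assay carries the
biological question; both are treated as Gaussian on the log2 scale.

## Normalization

Ratios are centered so that genes on declared euploid chromosomes average 0,
separately per strain, replicate and assay; every gene in that slice is
shifted by the same constant, so centering is idempotent and
shift-equivariant. The euploid set must be declared (directly or from a
karyotype spec); an `auto_euploid` helper exists but is deliberately opt-in,
since automatic reference selection on a heterogeneous strain silently
shifts the whole scale by 0.1–0.2 log2 units — the exact failure mode the
heterogeneity analysis is designed to expose. Centering uses the arithmetic
mean by default (a median option exists). Copy numbers are `P · 2^ratio`;
chromosome summaries report the mean of replicate-level chromosome means,
their SD across replicates (absent for n = 1), and the implied copy number.

## Karyotype heterogeneity

Per-gene DNA copy numbers (replicate-averaged by default) are tested against
the nearest integer copy state with a two-sided one-sample t-test; an exact
half-integer estimate tests both neighbours and must reject both. P-values
are corrected across all tests within a strain — Bonferroni by default,
matching the conservative hard α = 0.01 convention; Benjamini–Hochberg is
available. A chromosome that rejects every candidate integer is
heterogeneous (its average copy state is non-integral, i.e. the population
mixes karyotypes); a strain is heterogeneous if any chromosome is, and
otherwise labeled euploid, "stable aneuploid confined to ≤2 chromosomes", or
stable complex aneuploid. Degenerate (zero-variance) inputs short-circuit to
p = 1 or 0 with an explicit flag; chromosomes with fewer than three usable
genes are skipped with a warning rather than failing the strain.

## Distribution diagnostics

Histograms use half-open bins `[mh, (m+1)h)` anchored at 0 with h = 0.2 log2
units (anchoring at 0 is a convention of this package). The Gaussian "fit"
is a least-squares curve fit of `A·exp(−(x−μ)²/2σ²)` to bin-center
frequencies — the estimator a curve-fitting package applies to histogram
data, which is what makes the reported R² meaningful — initialized from the
histogram's own weighted moments, requiring at least four populated bins.
Skewness is the adjusted Fisher–Pearson statistic (bias-corrected G1); the
estimator matters when quoting values like 0.02 as evidence of symmetry.
Outlier counts are strictly below/above mean ± k·SD (k = 2 by default) of
the same value set; under pure scaling the two sides are symmetric within
binomial noise.

The theoretical compensated distribution is the two-component mixture
`(1−f)·N(μ_unc, σ) + f·N(μ_comp, σ)`; its mean, SD and skewness come from
the mixture raw moments in closed form. With any genuine compensated
fraction (0 < f < 1, μ_comp < μ_unc) the skewness is strictly negative —
the left shoulder a compensated cohort would print on the histogram. The
components share σ by default; the spread parameters are inputs, not
guesses.

## FDR engines for compensation calls

The classifier under audit is represented by an *effective cutoff*: over
0.1-wide bins of the per-gene compensation statistic (the replicate-averaged
`rna_log2 − dna_log2`, i.e. the log RNA/DNA fold ratio), the fraction of
genes in each bin that the classifier flagged. This reconstruction needs
only a hit list, not the original classifier. Bins outside the observed
range, and empty bins, carry probability 0. When applied, bin probabilities
are realized as Bernoulli draws per gene and randomization; the observed
count defaults to the cutoff's expected flag count on the unpermuted data
(identical in expectation, and an explicit count can be supplied instead —
e.g. the length of a published hit list).

* **Permutation engine**: each randomization independently permutes every
  replicate column across genes (each column's multiset of values is
  preserved exactly), re-averages per gene, applies the cutoff, and counts
  hits. Averaging across permuted replicates shrinks outliers by √r, which
  is precisely why a per-gene average that survives permutation is evidence
  of nothing.
* **Noise-sampling engine**: each randomization draws one statistic per
  gene from `N(0, √(σ_g² + σ_dna²))`, with σ_g resampled from the empirical
  per-gene RNA noise list. Because the engine models the *replicate-averaged*
  statistic, the natural inputs are per-gene SEMs (`per_gene_rna_sem`,
  SD/√r; single-replicate genes take the median) and a DNA term likewise
  scaled by √r. Per-gene SDs estimated from three replicates are themselves
  noisy and slightly biased low (the chi-distribution c4 factor), so this
  engine tends to run a few points below the permutation engine — an
  underestimation inherent to plug-in noise models, worth remembering when
  the two disagree slightly.

FDR = 100 × mean(null hit counts)/observed hits; the result object carries
the full null distribution, its spread and the Monte-Carlo SE. FDR is
undefined (an error, not 0) when nothing was observed. On data with no true
compensation both engines report ≈100% for any cutoff: observed and null
distributions coincide. Note that between nonzero compensated fractions the
permutation FDR is *not* monotone — permuted columns resample the
compensated mode itself, so at a hard cutoff the null hit rate grows like
3f²(1−f) + f³ against f observed; what is guaranteed is that any genuine
compensation pulls the FDR well below the null's ≈100% level.

## Ploidy-series slopes

Dose is expressed in doubling units `x = log2(c/P)`; on this scale
proportional expression has slope exactly 1 regardless of the dose set, and
the three-point worked example (0.3, 0.6, 0.8 at copies 2, 3, 4) fits slope
0.50 — on raw copies it would be 0.25, which pins down the abscissa
convention. Per-gene fits average replicates per dose level by default; for
a balanced design this equals the pooled all-points fit. The slope-threshold
surrogate classifies a gene as candidate-compensated when its slope is below
0.5. The slope-permutation FDR fits each gene on all per-replicate
measurements (nine RNA values and matching measured DNA values for a
three-level, three-replicate series) and permutes RNA and DNA columns
independently across genes within each (strain, replicate) column.

The replicate-consistency filter flags genes with `rna_log2` below
(center − k·SD) of the amplified chromosome's genes in *every* replicate of
a ploidy level, then intersects the trisomic and tetrasomic sets (k = 1 by
default). The center is the empirical replicate mean by default, matching
the filter's operational description. A `center="dose"` variant centers on
the proportional expectation `log2(c/P)` instead: when a large fraction of
genes is truly compensated, the empirical SD absorbs the compensation signal
itself (at 30% compensated the per-replicate SD roughly triples), the
mean-centered cutoff drifts toward the compensated mode, and per-ploidy
recall drops to about 0.89³ ≈ 0.71 at the trisomic level; dose-centering is
immune to this self-masking. Under the null the two coincide.

## The synthetic generator

`simulate_strain` draws, per gene and replicate,
`dna_log2 ~ N(log2(c_eff/P), σ_dna)` and
`rna_log2 ~ N(s_g·log2(c_eff/P), σ_g)`, with `s_g = 1 − d` for a
ground-truth compensated gene of depth d and 1 otherwise. Defaults encode
the study conditions: σ_dna = 0.10 (the ~10% DNA copy error), per-gene σ_g
drawn once — noise is a gene property, shared across replicates — from
U(0.4, 0.8), the range that brackets typical strain-level RNA SDs; three
replicates; a 16-chromosome layout with ~6200 genes in realistic per-
chromosome counts. Karyotypes may assign subpopulation mixtures, whose
effective copy `c_eff = Σ f_i·c_i` is what both the generator and the
heterogeneity caller see. `simulate_ploidy_series` shares the layout,
per-gene noise and compensated set across dose levels. An `average_dna`
switch emulates mean-only DNA reporting. Everything is driven by one seed
and bit-reproducible.

What the generator does *not* emulate: read-count statistics (no
overdispersed counts — the pipeline never touches counts), GC/mappability
bias, partial-chromosome amplifications, correlated gene programs such as a
stress response, or non-Gaussian noise. Passing tests therefore demonstrate
that the *statistical machinery* behaves as derived under its stated
assumptions, not that real sequencing data meet those assumptions.

## Problem sizes and numerical conventions

The validation suite runs at desk scale: 500 genes on the varied chromosome,
3 replicates, B = 400–1000 randomizations, 100 seeds for caller power, 10⁶
draws for the mixture Monte-Carlo oracle — sizes at which every analytic
expectation used as a test oracle is sharp enough to be discriminating.
Stochastic assertions use explicit error bands: binomial 3-SE bounds for
rates, batch-estimated Monte-Carlo SEs for moments, and for FDR ratios a
conservative delta-method band `3·100·√((1−p)/observed)` that ignores the
(favourable) correlation between observed and null counts. Half-integer
copy ties are detected at 1e−9; Gaussian fits that fail to converge raise an
error carrying their initial values; config files may be YAML or JSON, with
unknown keys warned about rather than rejected.

## Known limitations

* Whole-chromosome resolution only: no segmentation, no arm-level calls.
* The heterogeneity test flags non-integer copy states but does not
  deconvolve subpopulation fractions.
* The effective-cutoff reconstruction assigns probability 0 to bins never
  observed in the input, including extreme tails a classifier would surely
  flag; with a hit list that covers the tails this is immaterial.
* The noise-sampling FDR inherits plug-in bias from per-gene SD estimates
  (see above); the permutation engine is the more assumption-free of the
  two.
* The original mixture-of-regressions classifier is represented only by its
  slope-threshold behaviour; intercept-based gene classes are out of scope.
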