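# Methods

## Statistical model and estimators

### Expression normalization

Gene-level read counts are converted to RPKM:
`RPKM(g, s) = count(g, s) / (L_g / 1000) / (N_s / 10^6)`, with `L_g` the
exon-union length of gene g (total genomic span covered by at least one
exon, overlaps counted once; 1-based inclusive coordinates throughout)
and `N_s` the library size of sample s (by default the column sum of
the count matrix). Total-count library sizes are dominated by a few
very highly expressed genes, so the package also offers quantile
rescaling: each sample is divided by the q-quantile (q = 0.75
upper-quartile, q = 0.5 median) of its **positive** RPKM values and
multiplied by the geometric mean of those quantiles across samples.

Numerical choices, frozen in the tests:

* quantile definition: linear interpolation between order statistics,
  h = (n−1)q + 1 (the default of mainstream statistical environments);
* zeros are excluded from the quantile — with zero-inflated data the
  raw percentile can be 0, leaving the scale undefined;
* the geometric-mean anchor keeps the output on a scale comparable to
  the input. Any common anchor preserves every within-analysis ratio;
  only comparability of absolute RPKM across reruns is affected. A
  corollary: globally rescaling the input rescales the output by the
  same factor — relative structure, not absolute level, is invariant;
* MA diagnostics use M = log2((a+pc)/(b+pc)), A = ½·log2((a+pc)(b+pc))
  with pseudocount pc = 0.01 on RPKM (1.0 recommended on raw counts);
* depth resampling is binomial thinning of counts (each count replaced
  by Binomial(count, target/colsum)), the count-space analogue of
  drawing fewer reads: expected RPKM is exactly preserved.

### Chromosomal ratios

The central statistic is the ratio of median expression between
chromosome sets: X:A = med(X)/med(chr2 ∪ chr3) and chr3:2 =
med(chr3)/med(chr2), computed per sex on replicate-averaged RPKM
(arithmetic mean across the sex's libraries) over a sweep of minimum
expression thresholds. Thresholding uses `value ≥ t`; within-sex sweeps
filter on the sex's own averaged profile, male:female contrasts and
deciles filter on the mean of the male and female averages (both rules
exposed as options). Two male:female comparisons are provided:

* **Method 1** — ratio of the per-sex chromosomal ratios,
  (X:A)_male / (X:A)_female;
* **Method 2** — per-gene male:female ratios are formed first (genes
  with zero female expression are excluded and counted), and the
  estimate is med(ratios on X) / med(ratios on autosomes).

Method 2 cancels between-gene baseline variation and is therefore less
variable; on unbiased data the two agree closely, and both are checked
against brute-force oracles.

The decile analysis ranks genes by the mean of male and female
expression, splits them into 10 equal-count bins (remainder to the
lowest bins) and applies Method 2 with bootstrap CIs within each bin.

### Stratified bootstrap

Confidence intervals are percentile intervals over (default) 10,000
bootstrap replicates. Genes are resampled with replacement
independently within each chromosome stratum, preserving stratum sizes,
and the **same resampled gene multiset is applied to every sample**
entering a contrast. The shared-resample rule preserves the paired
male/female structure, without which per-gene M:F ratios would be
meaningless; independent per-sex resampling is available as an option.
Degenerate strata of size 1 collapse the CI and are flagged. CIs are
only computed for thresholds in [0.2, 15] RPKM — outside that range the
filtered gene sets become so small or so homogeneous that the intervals
are not informative. Undefined ratios (empty gene set, zero denominator
median) are carried as flagged estimates with reasons, never silent NaN.

### Sliding windows

Windows of 1 Mb step along the X in 100-kb increments, starting at
position 1; trailing windows extending past the chromosome end are
emitted and flagged partial. A gene belongs to a window iff its
midpoint (⌊(start+end)/2⌋) lies within it, giving every interior gene a
membership multiplicity of exactly window/step; assignment by gene
start or by any overlap is available. The window X:A ratio divides the
median of the window's expressed X genes by the median of **all**
expressed autosomal genes; windows with fewer than `min_genes`
(default 5) expressed X genes are flagged undefined. The gene-density /
ratio-departure correlation is Pearson's r between the per-window gene
count and |log2(window ratio)| — the departure metric is a package
choice, as is combining multiple samples by the mean of per-sample
window ratios.

### Sex bias and enrichment

A gene is male-(female-)biased when its q-value is below 0.005 and its
male:female fold is ≥ 1.5 (≤ 2/3) — "fold change above 50%" read as a
1.5× ratio. Externally supplied q-values (e.g. from a dedicated DE
tool) take precedence; otherwise p-values come from a two-sided
two-sample t test on log2(RPKM + 0.01) across replicates with
Benjamini–Hochberg correction — a deliberately simple in-house test,
adequate for the enrichment question, not a replacement for a
full DE model. Genes silent in females but active in males have an
undefined fold and are classified by q-value and direction; genes
silent in both sexes are "undefined". Enrichment uses Fisher's exact
test on (X/autosome) × (male-/female-biased), two-sided by the
minimum-likelihood rule, with the sample odds ratio ad/bc (zero cells
flagged). Ratio histograms use half-open bins [k·w, (k+1)·w), default
width 0.02. Ratio-set comparisons use the two-sided Mann–Whitney U
test: exact enumeration below combined n = 20 without ties, otherwise
the normal approximation with tie correction.

### Replicate QC

For each replicate r, ssd(r) = Σ_g Σ_{r′≠r} (x_{g,r} − x_{g,r′})² on
RPKM. The permutation null shuffles each gene's values across
replicates independently (whole-column permutations would leave the
statistic unchanged and are degenerate for this purpose); p-values use
the add-one rule p = (1 + #{perm ≥ obs})/(1 + n_perm), so they are
never exactly 0, with 10,000 permutations by default and a flag
threshold of p < 0.001. With two replicates both SSD values coincide
and the test is uninformative (warned). Flagged replicates are excluded
downstream, and the pipeline emits the ratio analysis both with and
without them.

## The synthetic-data generator

The simulator emulates a mosquito-like genome at ~1/10 of a real gene
complement: 860 + 760 autosomal genes (chr2, chr3), 110 X-linked genes
and 20 unplaced genes on chromosomes of realistic lengths (111, 95,
24.4 Mb). Exon-union lengths are log-normal (median 1.5 kb, σ_log
0.6), split into 1–6 exons. Per-gene baselines are log-normal and
rescaled so that Σ baseline·kb = 10^6, which makes the baseline the
gene's expected RPKM; a silent fraction (default 5%) has baseline 0.
Expected counts are baseline × kb × multiplier × lib/10^6 with library
size 2×10^6 reads jittered ±20%; counts are gamma-Poisson (negative
binomial) with dispersion φ = 0.1 (var = μ + φμ²), or exact rounded
expectations in the deterministic limit φ = 0, jitter 0. Multipliers:
male X genes carry the compensation factor c (1.0 complete, 0.5
absent; optionally a contiguous X block with its own factor), female X
genes a separate factor (e.g. 1.3 to model female-X overexpression),
and sex-biased genes multiply the favoured sex by a log-normal fold
(median 6). An optional divergent replicate multiplies a random gene
subset (default 30% × 4-fold). Identical config + seed reproduces
byte-identical outputs.

Two scale properties of desk-scale data are worth stating explicitly:

* **Absolute RPKM runs high.** RPKM across a sample sums to roughly
  10^6 / (mean gene length in kb) regardless of depth, so with ~1,750
  genes the expressed median sits near ~300–400 RPKM rather than the
  single digits typical of a 16k-gene transcriptome. The analysis
  thresholds (0.2–40 RPKM) therefore fall below the expressed bulk and
  separate silent from expressed genes, which is their essential role;
  threshold-dependent selection effects within the expressed bulk are
  exercised by the unit tests on constructed matrices instead.
* **The expression spread is deliberately compressed** (σ_log = 0.2
  between genes). The spread was chosen from a variance budget: the
  median over ~110 X genes must estimate the chromosomal level to
  within a few percent for parameter-recovery checks to be meaningful
  at this scale. Real transcriptomes spread over several orders of
  magnitude; one visible consequence is that simulated between-replicate
  Spearman correlations (~0.3–0.4) are far below the 0.8–0.95 seen in
  real data, where the huge between-gene dynamic range dominates the
  ranks. Passing tests therefore demonstrate correctness of the
  estimators and calibration of the resampling machinery, not
  robustness to real-data dynamic range.

Presets: `pupae_complete` (c = 1, three libraries per sex),
`larvae_female_high` (female X factor 1.3 — an illustrative magnitude
for female-X overexpression, not an empirical estimate),
`no_compensation` (c = 0.5), and `testes_like` (male-only shallow
library at 450k reads, c = 0.5, X silent fraction 0.45 vs 0.10
elsewhere, mimicking reduced expressed-X breadth in germline tissue).
The simulator does not model read-level artifacts, isoform structure,
or positional autocorrelation of expression along chromosomes.

## Design choices where the design was open

* **Arm mapping**: annotations with arms 2L/2R/3L/3R are merged to
  chr2/chr3 by a configurable map; unmapped scaffolds become
  "unplaced" and are excluded from all ratio analyses.
* **Replicate handling**: libraries of one sex/stage (including pupal
  time points) are averaged arithmetically on RPKM before ratio
  computation.
* **Bootstrap resampling unit**: "stratified by chromosome and sample"
  admits shared or independent resampling across samples; shared is the
  default (it preserves pairing), independent is an option.
* **Genes with zero expression in one sex** are excluded from per-gene
  ratio analyses and counted, rather than imputed.
* **Zero-length or exon-less genes** are rejected at load (RPKM divides
  by length), never silently dropped.
* Strand is recorded but unused; expression is strand-agnostic here.

## Known limitations

* The in-house differential-expression test assumes approximately
  log-normal replicate noise; with 2–3 replicates per sex its q-values
  are conservative and underpowered relative to purpose-built DE models.
* Percentile bootstrap intervals for ratios of medians can undercover
  slightly below ~50 genes per stratum; coverage is verified empirically
  at the default scale (see the acceptance checks).
* Fisher's exact test is conservative when few biased genes are
  detected; enrichment calibration holds at ≥ ~40 biased genes.
* Window ratios at the chromosome ends come from partial windows and
  are flagged rather than corrected.
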