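# Methods

This note documents the generative model, the statistical procedures, the
parameter defaults and why they were chosen, and what the synthetic
validation does and does not establish about real data.

## Generative model

The simulator emulates a sex- and reporter-sorted neuronal ATAC-seq
design: four conditions (male/female × fru+/fru−), `replicates` libraries
each (default 2), over a miniature genome of chrX (2 Mb, stratum X) and
chr2/chr3 (3 Mb each, autosomal). Peaks are laid out non-overlapping,
`n_peaks_per_chrom` per chromosome (default 200), 400 bp wide.

The expected fragment count for peak *i* in sample *j* is

    mu_ij = s_j · f_i · mu_base · x_ij · d_ij · g_ij

with

- `s_j` — library size factor, log-uniform on [0.7, 1.4], forcing
  normalization to do real work;
- `f_i` — cell fraction, uniform on `cell_fraction_range`, identical
  across conditions: accessibility is near-binary per cell, so peak
  height measures the fraction of cells in which the element is open.
  Differential effects act multiplicatively on top of `f_i`;
- `x_ij = 2` for female samples at X peaks (two X copies), else 1;
- `d_ij = dcc_boost` (default 2) for male samples at DCC-class peaks,
  modelling dosage-compensation upregulation of the single male X;
- `g_ij = 2^{±Δ}` (default Δ = 2) only when the sample is male fru+ and
  the peak is of the opened/closed class — the condition-specific
  regulatory elements the analysis must recover.

Counts are negative binomial with mean mu_ij and dispersion α
(variance μ + αμ²; α = 0 degenerates to Poisson). Default α = 0.05,
typical of well-behaved ATAC replicate sets at region scale.

Classes: DCC peaks only on the X (`frac_dcc_sites_on_x`, default 10%);
opened/closed peaks only on autosomes by default, keeping X effects
attributable to dosage (both configurable). Tether sites are defined as
the DCC peak midpoints, so relative-distance recovery has exact truth.

Fragments are emitted with midpoints uniform within their peak — so
midpoint re-counting reproduces the count matrix exactly — plus uniform
genome-wide background at `background_rate` (default 10⁻⁴/bp), with
lengths from a two-component normal mixture (65% at 80 ± 25 bp
sub-nucleosomal, 35% at 200 ± 40 bp mono-nucleosomal, truncated at
20 bp). Peak sequences are i.i.d. at 42% GC with the motif consensus
planted at class-dependent probability on a random strand.

Parameter defaults not fixed by the modelled study design were set once
by design-stage power analysis: `cell_fraction_range = (0.5, 1.0)` keeps
moderate cell-fraction heterogeneity while leaving a 2-vs-2 design with
μ_base = 50 and α = 0.05 enough power (analytically ≈ 90–99% per
comparison) to recover |log2FC| = 2 planted effects — mirroring real
experiments, which are depth-calibrated to their expected effect sizes.
The fraction of fru+ cells using each element is not observable in the
modelled data and remains a free, documented parameter.

The expression arm simulates gene-level NB counts per condition, with an
optional mild coupling of baseline expression to gene accessibility
(slope 0.25 on the standardized log10 scale against lognormal σ = 1
noise, giving r² ≈ 0.2 — accessibility is informative but far from
deterministic for expression) and an optional female-bias shift
(Δ_expr, default 0.5 log2) for a designated gene set, used to validate
the neighbor-gene Welch test.

## Peak calling

Fragment midpoint coverage is tested in sliding windows (window 200 bp,
step 50 bp) against Poisson expectations with λ = window ×
max(genome-wide rate, local rates over 5 kb and 10 kb centered on the
window) — the standard local-lambda guard against regional background
variation. BH is applied over all tested windows genome-wide (one FDR
for one genome-wide question); windows at q < 0.001 that overlap or
touch are merged, the merged peak takes its windows' minimum p/q, and
the summit is the leftmost coverage maximum (determinism under ties).

## Stratified differential accessibility

Pooling X and autosomes under one normalization misattributes X dosage:
the female X doubles both X-region counts and the X share of the
library. In pooled mode (median-of-ratios over all regions, single BH)
the simulated sex comparison calls >90% of ordinary X regions
female-biased and shifts autosomal fold changes male-ward (the median
reference is dragged by the X block; with library-total normalization
the artifact is stronger still). Stratified mode computes size factors,
dispersions, tests, and BH independently within X regions and autosomal
regions and concatenates the lists; the within-X normalization absorbs
the uniform dosage factor, leaving DCC sites — genuinely more accessible
on the male X per copy — detectable as male-biased.

Engine details, all chosen for a fully specified, desk-scale,
well-calibrated 2-vs-2 test rather than a full GLM:

- size factors: median-of-ratios against the per-region geometric mean
  over samples (regions containing any zero excluded from the
  reference), rescaled to geometric mean 1 within the stratum;
- dispersion: per-region method-of-moments on normalized counts
  (grand mean m_i; within-group pooled variance v_i;
  raw α_i = max(0, (v_i − m_i)/m_i²)), then a least-squares trend
  α(m) = a₀ + a₁/m over regions with m > 1 (median fallback below 10
  regions), finally α_i* = max(trend(m_i), 10⁻⁴). The floor avoids
  zero-variance Wald statistics; the trend borrows strength across
  regions, which is what keeps the test calibrated at n = 2 per group;
- Wald test on moderated group means: log2FC = log₂((m_B + c)/(m_A + c))
  with c = 0.5 (keeps fold changes finite and shrinks low-count
  estimates), SE from the NB variance of each group mean, two-sided
  normal p. The orientation is always target/reference and is stated in
  the result header — the single most effective guard against sign bugs
  when two comparisons are later intersected;
- BH within stratum, lists concatenated (a global-BH flag exists for
  comparison).

Null calibration was verified by simulation: across 100 fully null
2000-region simulations the raw p < 0.05 fraction is ≈ 4.5% and the
FDR < 0.05 call fraction ≪ 5%.

## Specificity calls

A region is specific to the target condition when it passes FDR < 0.05
in both comparisons (each re-oriented target/reference before sign
comparison); shared positive sign → opened, shared negative → closed;
significant-with-opposite-signs is reported as discordant rather than
dropped — zero discordance is a finding about the data, not an
assumption of the method. Both comparisons must share one consensus
region set; intersecting two independently derived region lists by
overlap is deliberately not supported, because partial-overlap matching
makes "the same region" ill-defined.

## Annotation, enrichment, relative distance

A peak midpoint is classified with precedence promoter > exon > intron >
intergenic; the promoter window is ± 50 bp around a TSS (unusually
narrow, but exposed as `promoter_halfwidth`), and the nearest gene
minimizes |midpoint − TSS| (TSS, not gene boundary — the nearest-gene
annotator paradigm), ties broken lexicographically. Term enrichment is
an upper-tail hypergeometric against a user-supplied background with BH
across terms; it matches exhaustive enumeration for small universes.

Relative distance: for each query midpoint strictly between consecutive
reference midpoints b₁ < b₂, d = min(a−b₁, b₂−a)/(b₂−b₁) ∈ [0, 0.5];
uniform placement gives d ~ U(0, 0.5) (mean 0.25), attraction shifts
mass toward 0. Query midpoints outside the reference span are skipped
and counted; the fraction of query intervals overlapping any reference
interval by ≥ 1 bp is reported alongside.

## Motif scanning

Log-odds matrices use a pseudocount mixed with the background
(p' = (p + pc·bg)/(1 + pc), pc = 0.1) and are rounded to an integer grid
of ε = 0.01 bits. The exact null score distribution for one width-w
alignment of i.i.d. background bases follows by column-wise convolution
on that grid; p-values are suffix sums. Grid rounding is the only
approximation, and DP tails equal brute-force enumeration over all 4^w
sequences on the same grid to machine precision.

Scanning takes the maximum log-odds over all positions on both strands;
ties go to the smallest position, then the + strand. The reported
p-value is per-alignment — deliberately not corrected for region
length, since best-hit minima are compared *between classes* whose
length distributions are comparable; a length-corrected option
(1 − (1−p)^(2(L−w+1))) exists but is off by default, and class length
distributions should be reported alongside any comparison. Non-ACGT
bases contribute zero log-odds and are flagged; sequences more than half
ambiguous are rejected; sequences shorter than the motif get p = 1,
flagged. The class comparison reports per-class ECDFs of −log10 best p,
pairwise two-sample KS, and Fisher exact 2×2 counts at the well-matched
threshold p < 10⁻³.

## Coverage and expression

All counting uses the fragment-midpoint rule — one rule everywhere, so
tiling partitions conserve totals exactly. Gene-scale counting uses full
gene spans (not exon unions): diffuse intronic enhancer signal across a
long locus is precisely what span-level aggregation is meant to expose.
A fragment whose midpoint lies in two overlapping spans counts in both.
Locus displays report raw and size-factor-normalized columns (autosomal
size factors, avoiding X-dosage contamination of an autosomal locus).
Anchored profiles mask (rather than zero-fill) bins that run off a
chromosome and exclude them from column means. TPM uses exon-union
effective lengths; differential expression reuses the NB engine with
pooled normalization (dosage compensation acts on transcription, so
X-stratified normalization of expression would remove real biology;
a flag allows it for exploration).

## Pipeline

Stages run in fixed order with one global seed fanned out per stage by
SHA-256 hashing of the stage name (stage reruns in isolation reproduce
their in-pipeline output). Identical configuration reproduces every
output byte; the manifest records the config hash, thresholds, per-stage
row counts, and wall time. Demo-scale note: at the default depth the
DCC effect (log2FC = 1) is underpowered at FDR < 0.05 in a 2-vs-2
design, so the demo's tether-site stage falls back to nominally
male-biased X regions and records which selection was used.

## Problem sizes used in validation

Validation experiments are sized for seconds-scale runs: 600 peaks × 8
samples for the bias demonstration and specificity recovery; 2001
regions × 100 seeds for null calibration; 200 regions per class with
300-bp sequences for motif detection; 10⁴ queries for the
relative-distance null; a 3-Mb single-chromosome genome with a 100-kb
multi-intron gene for gene-scale recovery. These sizes were chosen so
that each planted effect is comfortably within analytic power bounds —
results reflect method correctness, not marginal power.

## What passing the synthetic tests does and does not show

The generator reproduces the *statistical* structure the methods assume:
NB counts with trended dispersion, X dosage and DCC boosts as clean
multiplicative factors, uniform fragment placement within peaks, i.i.d.
background sequence. Real ATAC data violate all of these in degree:
Tn5 insertion bias, duplicate reads, mappability gaps, peak-shape
heterogeneity, correlated biological replicates, non-uniform background,
and cell-type composition drift between sorted populations are not
modelled. Passing recovery and calibration here therefore establishes
that the implementations are correct and internally calibrated under
their stated model — not that effect sizes or FDRs transfer untouched
to any particular real library.

## Known limitations

- The Wald-on-moderated-means engine is not a GLM: no covariates, no
  batch terms, no shrinkage of fold changes beyond the moderation
  constant.
- The peak caller has no fragment-shift model or broad-peak mode and is
  intended for simulated/desk-scale data.
- Nearest-TSS annotation ignores 3D contacts and enhancer–promoter
  assignment beyond linear proximity.
- Motif class comparisons do not length-match region sets; the length
  distributions should be inspected when classes differ systematically.
- The bedGraph reader materializes per-base arrays and is meant for
  megabase-scale genomes, not whole mammalian chromosomes.
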