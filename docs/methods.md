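# Methods

This note documents the models, parameter choices and numerical
conventions behind `cistrans`, and what the synthetic validation does
and does not demonstrate.

## Coordinates and conventions

All coordinates are 0-based half-open (BED convention); a region's
anchor point is its integer midpoint ⌊(start+end)/2⌋. TSS = gene start
on the + strand and gene end on the − strand. Signed TSS distances are
(midpoint − TSS) on the + strand and (TSS − midpoint) on the − strand,
so positive always means downstream of transcription. Effects are
always group2 − group1 (exposed minus control): *hyper*, *GA* and *up*
mean higher in the exposed group.

## Synthetic data generator

The generator emulates a two-group inhalation-exposure study on a small
annotated genome: by default two chromosomes, 400 genes in regular
10-kb slots (bodies 2–5 kb, random strand, ≥2 kb flanks), each with a
±100 bp TSS window, a ±1 kb promoter (minus the TSS window),
alternating 200/800-bp exons/introns, a 300-bp 3′UTR at the distal end,
LINE/SINE/LTR repeat blocks in intergenic space, and distal enhancers
(20–80 kb from the TSS) wired to 15 % of genes. Partition labels may
touch; queries resolve overlaps by the fixed precedence TSS > Promoter
> Exon > 3UTR > Intron > SINE > LINE > LTR, with Intergenic as
fallback. The precedence order itself is a convention of this package;
it is config-visible through `PARTITION_PRECEDENCE`.

Assays share one cohort of animals; the methylome and accessibility
assays measure the first 3 animals per group and the transcriptome 4
(the emulated design), so sample-wise integration uses the matched
subset. Count models:

* **Methylation** — CpG sites every 25 bp; per-site coverage 1 +
  Poisson(29) (mean ≈ 30×); methylated reads Binomial(coverage, β) with
  logit β = logit(0.5) + N(0, 0.5) per 100-bp bin (baseline
  heterogeneity, shared across samples). β₀ = 0.5 gives symmetric
  headroom for planted shifts of either sign. Planted DMRs (100 ×
  200 bp, |Δβ| = 0.3) shift the logit in exposed samples only.
* **Accessibility / expression** — negative binomial, mean
  μ = 200·LogNormal(0,1) per feature with dispersion 0.05 and
  LogNormal(0, 0.1) per-sample library factors; planted DARs/DEGs
  (100/200 features, |log₂FC| = 1.5) act on the log link in exposed
  samples.
* **Couplings** — each of 30 cis + 30 trans couplings per epigenome
  assay ties one region to one gene through a per-animal latent factor
  z ~ N(0,1): the region's logit-methylation gains κ_m·±z (κ_m = 0.25)
  and the gene's log₂ mean gains κ_c·±z (κ_c = 0.35), with the two
  loadings' sign product equal to the planted coupling sign. Coupled
  features also carry group effects whose directions are aligned with
  the coupling sign, so the pooled-sample correlation of a coupled pair
  is ≈ 0.9 (group channel + latent channel). The κ values realize that
  target correlation while leaving the coupled features' own group
  effects detectable; raising them further inflates within-group
  variance until the features stop being callable. Cis couplings sit on
  the gene's own promoter (methylation) or promoter peak
  (accessibility); trans couplings sit > 2 kb from every TSS and off
  every enhancer. Cis methylation couplings default to repressive sign
  and cis accessibility couplings to activating sign, the canonical
  promoter biology.
* **Rhythm** — per gene and group, value(t) = M + A·cos(2π(t−φ)/24) +
  N(0, σ), sampled at ZT0–ZT20 every 4 h with 3 replicates; defaults
  M = 10, A = 3, φ = 8 h, σ = 0.5, with exposed-group deltas −2 (mesor),
  −1 (amplitude), +4 h (acrophase).

One RNG stream per assay is derived from the master seed by fixed
offsets, so changing one assay's parameters cannot perturb another's
draws. The real study's sequencing depths are not public at this
granularity; all depth parameters are config-exposed estimates, not
claims about the deposited datasets.

**What the generator does not emulate:** read-level artifacts (mapping,
duplication, GC bias), CpG clustering and genome-scale feature counts,
biological covariance beyond one latent factor per coupling, batch
structure, and—importantly—the *diffuseness* of real effect sizes. All
planted features respond coherently to the exposure, which creates one
dominant across-sample covariance mode; consequently a much larger
fraction of region–gene pairs clears the permutation thresholds here
than one should expect on real data, where called features are noisier
and less uniformly exposure-driven. Passing the recovery tests shows the
machinery is correct and calibrated under its stated model, not that
real data will be as cooperative.

## Differential calling

**DMRs.** Site counts are pooled into 100-bp half-open bins; bins with
pooled coverage < 10 in any sample are excluded. Per-sample bin levels
are arcsine-square-root transformed (variance-stabilizing for
proportions) and tested with the same moderated statistic used for
counts (below). A per-bin Welch t is available (`method="welch"`) but
not the default: at n = 3–4 per group it has ~4–6 df, so even an
overwhelming effect cannot produce p-values small enough to survive a
BH adjustment across tens of thousands of bins; the ensemble-moderated
test restores power and measured within 0.049–0.051 on the null
fraction-below-0.05 check. Significant bins (q < 0.05 and |Δβ| ≥ 0.10)
of the same sign with gap ≤ 100 bp merge into regions; a region must
rest on ≥ 2 significant bins (the standard region-support rule —
isolated significant bins are bin-level noise and were the dominant
source of region-level false positives), its effect is the
coverage-weighted mean Δβ and its reported statistics come from the
most significant member bin.

**DARs/DEGs.** Counts become log₂(CPM+1) with DESeq-style
median-of-ratios size factors; a plain total-count library is not
robust here because up- and down-shifted features are unbalanced in
linear space, and at the planted density (half the genes differential)
that composition bias fabricates calls. The moderated test estimates
the prior (d₀, s₀²) by matching the mean and variance of log s² to the
marginal s₀²·F(d, d₀) distribution (digamma/trigamma inversion by root
finding; Var[log s²] at or below ψ′(d/2) maps to d₀ = ∞ and a normal
reference). Features with s² = 0 still get a finite statistic through
the prior floor. Significance is q < 0.05 with *no* fold-change filter;
the smallest significant |z| is reported as the calls' boundary
statistic ("Zcut") together with each call's posterior variance, the
two axes of the shrinkage plot. The all-identical-input corner case
(every variance zero, every difference zero) returns p = 1 everywhere
rather than failing the prior fit.

**Curation.** Calls are annotated with partition, nearest gene and
signed TSS distance; the curation step keeps, per (target gene, status),
the call with the smallest q (ties: smaller |distance|, then position),
and drops calls with no target gene. "Target gene" is the nearest gene
within 1 Mb — not the ±2 kb candidate set, which would discard every
distal region and empty the trans-pair population downstream.

## Integration

Region signals (pooled methylation fraction, or log₂(CPM+1) for peaks)
and gene signals are collected over the samples shared by the two
assays, standardized per feature (mean 0, variance 1, ddof 1); constant
or zero-coverage features are dropped with a warning. Both groups are
pooled: the pairing measures across-sample covariation, and group
labels influence only which features enter.

PLS2 is fit by NIPALS with a fixed deflation order (the starting score
is the current Y column with the largest sum of squares) and a fixed
sign convention (largest-|w| entry positive), making the fit
deterministic. Identities used as correctness anchors: β = Pearson r in
the standardized 1×1 case; β = multivariate OLS when K = rank(X) with
n > p.

The pipeline uses **one latent component** by default. This was a
genuinely open choice and was settled empirically: with K ≥ 2, refits
on permuted Y let the later components chase noise and concentrate
weight on few columns, pushing the pooled null |β| quantile (≈ 0.14)
above every real coefficient (≤ 0.10, diluted by the collinearity of
the region block), so no heterologous pair can ever pass; with K = 1
the null and real β scales match and planted couplings are recovered.
`fit_mpls` itself accepts any K.

Thresholds r\* and β\* are pooled (1−α) quantiles over B = 200 row
permutations of Y (α = 0.05); permutation rather than parametric
p-values keeps the procedure assumption-light and seedable. Homologous
membership is decided by the candidate-target rule (TSS strictly within
±2 kb of the region midpoint, or an overlapping enhancer wired to the
gene); the homologous/heterologous split is therefore a partition —
no pair can be both. Significance: OR of the two criteria for
homologous pairs, AND for heterologous. The recorded pair sign is
sign(r), with an inconsistency flag when sign(β) disagrees.

## Intersections and dependence

Venn cells are exact set algebra over the per-assay gene sets (curated
DMR targets, curated DAR targets, DEGs). The direction-dependence test
builds a 2×2 table of sign(region effect) × sign(gene change) over
significant pairs in promoter/enhancer scope (homologous, plus any pair
with |TSS distance| < 2 kb) and computes the Pearson χ² without
continuity correction (the intended regime is large tables; a zero
margin raises instead of silently correcting); the odds ratio uses
Haldane's +0.5 on zero cells. The overlap test compares the PLS
pairing against a distance predictor (region → nearest gene) within
|TSS distance| bins (0–2 kb, 2–50 kb, 50–500 kb, ≥500 kb — edges chosen
to span the proximal/distal vocabulary of such studies and
config-overridable) by the upper-tail hypergeometric probability, with
the universe defined explicitly as all scored (region, gene) pairs in
the bin. On synthetic data the distance predictor only reaches
promoter-proximal targets, so distal-bin overlaps are structurally
empty; the bins are reported regardless.

## Cosinor

Single-component cosinor by least squares on [1, cos ωt, sin ωt].
Amplitude is the canonical A = √(β_c² + β_s²) — half the peak-to-trough
swing; because "amplitude" is sometimes used for the full swing, 2A is
reported alongside as `peak_to_trough`. Acrophase is anchored to the
cosine maximum, reported in hours on [0, 24). Standard errors come from
the delta method; rhythmicity from the 2-df zero-amplitude F test. Fits
require ≥ 4 distinct timepoints (with 3 the design is exactly
identified and no inference is possible) and reject collinear designs.
A fit with A below 10⁻⁹·max(1, |M|) is flagged degenerate and its
acrophase reported missing. Group comparisons are Wald tests on ΔM, ΔA
and the circular Δφ wrapped to (−12, 12] h, skipped (and flagged) for
degenerate amplitudes, with BH applied jointly across genes ×
parameters. The group-comparison test in the emulated study is not
published in detail; the Wald comparison is this package's own choice.

## Pipeline

`RunConfig` is the single parameter source; it is schema-validated
before any computation and echoed verbatim (all defaults materialized)
into the run directory. Stages run in the fixed order simulate → call →
integrate → intersect → rhythm, each reading its inputs from and
writing its outputs to the run directory, so partial re-runs from
cached stage outputs reproduce downstream artifacts bit for bit. The
summary JSON carries call counts by status, pair tallies by
(type × direction × sign), thresholds, intersection results, rhythm
comparisons and sha256 checksums of every artifact.

## Validation scale

The test suite and `scripts/acceptance.py` run everything at desk
scale, chosen to keep the full suite around half a minute: genomes of
4–8 Mb with 300–400 genes, 5 000 null features for calibration, 100/100/200
planted effects at n = 4+4 for recovery, 60 latent couplings at n = 8
for pairing (aggregated over three seeds), 1 000 replicate series for
cosinor bias and 500 for shift detection. Determinism is at integer
level for fixed (config, seed) across runs.

## Known limitations

* The moderated test assumes exchangeable variances after the
  transform; a strong residual mean–variance trend (visible as a mild
  gradient in null rejection rates across abundance quartiles) is not
  modelled — a trended prior would be the natural extension.
* β from a one-component PLS cannot attribute a gene to one specific
  region among collinear regions; pair significance is a joint
  correlation/regression screen, not a causal assignment — at n = 8,
  sixty latent factors are not mutually identifiable even in principle.
* The permutation null permutes whole samples; it preserves feature
  covariance but not any group structure beyond what standardization
  removes.
* Enhancer wiring is taken as given (annotation input); the package
  does not predict enhancers.
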