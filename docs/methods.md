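# Methods

## Study design emulated

The pipeline targets a two-tissue (epidermis, soft tissue) amputation time
course at 0, 3 and 8 days post-amputation (dpa) with a vehicle-control arm
and a small-molecule inhibitor arm and two pooled biological replicates per
condition. The 0-dpa homeostatic sample exists once per tissue and serves as
the shared baseline of both arms: every design, contrast and profile in the
package treats 0 dpa as control-only. Tissues are analyzed as independent
arms throughout.

## Normalization

Counts are converted to TPM using per-gene effective lengths, with the TMM
(trimmed mean of M-values) factor of each sample multiplying its library
size inside the TPM denominator; expression used downstream is
`log2(TPM′ + pseudocount)` with pseudocount 1 (configurable). The TMM
implementation follows the published procedure: reference sample = the one
whose upper-quartile count proportion is closest to the mean upper quartile;
genes with a zero in either sample excluded; log2 proportion ratios (M)
trimmed 30% two-sided and average log2 proportions (A) trimmed 5% two-sided
by rank; the factor is `2^(precision-weighted mean of retained M)` with
delta-method weights, and factors are rescaled to geometric mean 1. Factors
for the packaged composition-biased toy match the reference
implementation's values (frozen in the tests) to well below 1%.

The "expressed transcript" filter defaults to count ≥ 1 in ≥ 1 sample
(configurable min-count / min-samples).

## Differential expression

Per tissue, gene-wise ordinary least squares with cell-means (indicator)
coding over the five condition groups {0dpa, 3dpa_ctrl, 8dpa_ctrl, 3dpa_inh,
8dpa_inh}; with two replicates per group this leaves d_g = 5 residual df per
gene — the moderation below exists precisely because that is small. The
empirical-Bayes prior (d₀, s₀²) is fitted by moment matching on log s²
(digamma/trigamma moments, Newton inversion of the trigamma); posterior
variances are the df-weighted average and contrasts are tested on d₀ + d_g
df. Degenerate inputs: all-equal variances return d₀ = ∞ with the common
value as prior (no log-scale bias correction is applied in that case);
`d0_override=0` reproduces the classical unmoderated t exactly (verified to
1e-10 against an independent group-means/pooled-variance route).

The dynamic-gene filter takes unadjusted p < 0.05 in at least one of the six
pairwise stage comparisons (3v0, 8v0, 8v3 under each arm). No multiplicity
correction is applied at this stage by design — it is a recall-oriented
screen; FDR control happens in enrichment. Under the generator's null this
union filter selects 15–25% of genes, which the tests assert.

## Temporal profiles and fuzzy c-means

For each dynamic gene and arm, replicate-mean log2 expression at (0, 3, 8)
dpa — reusing the 0-dpa mean for the treated arm — is z-scored (sample sd;
rows with sd < 1e-12 dropped and logged). Both arms are stacked into one
matrix and clustered in a single fuzzy c-means fit, so control and treated
rows share one centroid space; transitions are therefore label-consistent by
construction rather than via post-hoc cluster matching.

Fuzzy c-means alternates the membership update
`u_ij = (Σ_k (‖x_j−v_i‖/‖x_j−v_k‖)^{2/(m−1)})⁻¹` and the centroid update
`v_i = Σ_j u_ij^m x_j / Σ_j u_ij^m` until max |ΔU| < 1e-6 or 200 iterations.
Points coincident with a centroid receive full membership split among the
coincident centroids. The fuzzifier defaults to the size/dimension estimate
`m = 1 + (1418/N + 22.05)D⁻² + (12.33/N + 0.243)D^(−0.0406 ln N − 0.1134)`,
which is ≈ 3.6–4.1 for matrices of a few hundred to a few thousand 3-point
rows.

Initialization: k-means++-style seeding over identifier-sorted rows followed
by at most 20 hard (Lloyd) polish iterations, then the fuzzy alternation;
best of 3 restarts by the objective J = Σ u^m d². Purely random
initialization was tried first and converged to visibly inferior optima
(J ≈ 15% higher, two archetypes merged) in roughly a fifth of runs at c = 8
with these high fuzzifiers; the seeded spread-out start removed that failure
mode. Because the seeding only uses the seed and the row values (rows are
sorted by identifier first), results are invariant to row order. Cluster
labels are canonicalized by lexicographic centroid order; hard assignments
are argmax memberships with ties broken toward the lower label.

The cluster number is scanned over c = 4..27: for each c a fit is run and
the minimum pairwise centroid distance d_min(c) recorded; the chosen c is
the largest with d_min(c) > θ, default θ = 0.1 in z-score units. On
well-separated archetype data d_min collapses by ~5× right above the true
k (surplus centroids coalesce at high m), so the rule is insensitive to θ
anywhere in the gap. If no c qualifies the scan falls back to the smallest
c with a warning.

## Transition matrix

`counts[i, j]` = genes assigned to control cluster i and inhibitor cluster
j; proportions are row-normalized (empty rows flagged and left all-zero).
Genes with only one arm's row (the other dropped as flat) are excluded and
logged. Membership strength is deliberately ignored here — transitions are
categorical — but full membership matrices are exported for users.

## Enrichment

Ranking: `r_g = sign(log2FC)·(−log10 p)`, descending; ties broken by
|log2FC| then gene identifier; p = 0 clamped to the smallest positive
double. The enrichment score is the weighted Kolmogorov–Smirnov running sum
(hits add `|r|^p/N_R` with p = 1, misses subtract `1/(N−N_H)`); ES is the
signed maximum deviation and the leading edge the hits at or before (after,
for negative ES) the extremum. Significance uses a gene-label permutation
null — random same-size sets — because two replicates per group cannot
support phenotype permutation. NES divides ES by the mean |null ES| of
matching sign; nominal p uses the same-sign tail with add-one correction;
FDR q follows the standard NES tail-ratio on the pooled sign-normalized
null, made monotone in |NES| within each sign. ORA is the upper-tail
hypergeometric (exact against enumeration for every universe ≤ 12 in the
tests) with Benjamini–Hochberg adjustment. Enrichment maps connect
significant sets (q < 0.05) whose Jaccard similarity on the measured
universe is ≥ 0.25 (overlap coefficient available).

## Cell abundance

The abundance proxy of a cell type in a sample is the arithmetic mean of its
signature genes' normalized (log2) expression; a linear-scale option exists
because averaging on the count scale is equally defensible. Missing
signature genes are dropped and logged, never imputed; a z-scored per-type
variant supports cross-type display. Signature scores are relative — they
track composition changes only as far as global normalization allows, so
signatures should be a small fraction of the measured universe (see below).

## Synthetic generator

Counts are negative binomial with mean
`lib_s · baseline · 2^(amplitude · archetype(t) + N(0, noise_sd))`.
Archetypes are eight canonical z-scored trend shapes (monotone up/down,
late up/down, early up/down, transient peak/dip) evaluated at ordinal stage
positions; additional shapes (3 timepoints) are packed on the circle of
z-scored 3-point profiles at a minimum separation (default 0.5; the
canonical eight are ≥ 0.73 apart). Premature-shift genes follow the late-up
archetype under control; under the inhibitor their 3-dpa expected value is
moved to the control 8-dpa value, which is exactly the early-up archetype —
so ground truth specifies a single expected transition cell. Gene effective
lengths are log-uniform in [500, 5000] nt so TPM genuinely differs from CPM.
`dispersion = 0` is the documented deterministic limit (counts = rounded
means).

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| timepoints / arms / replicates | (0,3,8) dpa × {control, inhibitor} × 2 | the emulated design; 0 dpa shared |
| amplitude | 2 (log2 units) | strong but realistic stage effects |
| baseline_mean | 1000 counts | deeply sequenced libraries; keeps Poisson noise subdominant |
| dispersion | 0.0025 | replicates are pools of 4 limbs: biological CV 0.1 (inbred) / √4 = 0.05 |
| noise_sd | 0.25 | per-gene-per-sample log2 biological noise; the controlling noise dial |
| frac_dynamic | 0.3 | matches the ~30% of transcripts that are temporally dynamic in this kind of study; the flat majority is what makes TMM's most-genes-unchanged assumption hold |
| frac_shifted | 0.1 | planted premature-shift fraction |

The count-layer defaults (baseline_mean, dispersion) are chosen so that
`noise_sd` dominates the generative noise; with small baselines or large
dispersion the NB sampling floor would silently overwhelm the dial and
"low-noise" fixtures would not be low-noise.

Planted gene sets: one set of mid-range size composed ≥ 80% of shifted
genes (flagged), plus decoys drawn uniformly from non-shifted genes.
Signatures: disjoint per-type gene lists, flat in time, scaled by per-type
abundance trajectories (expanding, contracting, transient — tie-free so
rank correlation against truth is informative).

What the generator does **not** emulate: batch effects, library-preparation
biases, correlated genes within pathways, isoform structure, count
overdispersion heterogeneity across genes, or single-cell resolution.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted temporal structure under idealized noise — not
performance on any real dataset.

## Problem sizes used in tests and the acceptance script

The shift-recovery fixture uses 2,000 genes (200 shifted, noise_sd 0.25,
one tissue arm); the cluster-number scan fixture uses 300 fully-dynamic
genes (noise_sd 0.1), scanned 20 times; null calibration uses 5,000 flat
genes; GSEA calibration uses a 1,000-gene universe with 200 decoy sets and
1,000 permutations; the packaged demo runs 300 genes end to end. These
sizes make the whole battery complete in well under a minute while leaving
each statistical check comfortably powered.

## Known limitations

* The minimum-centroid-distance rule assumes well-separated temporal
  structure; on data whose clusters blend continuously the d_min curve
  decays smoothly and the chosen c tracks θ rather than structure (the scan
  table is exported so users can inspect the curve).
* False positives of the p < 0.05 dynamic filter contribute pure-noise
  profiles to clustering; they spread across clusters and inflate
  off-diagonal transition mass slightly. With default planted structure this
  does not affect the expected transition cell.
* With ≤ 2 replicates per group the GSEA null must be gene-label
  permutation, whose p-values are approximately, not exactly, calibrated for
  correlated gene sets.
* TMM assumes most genes unchanged; fixtures in which planted signature or
  dynamic genes dominate the universe violate this and shrink abundance
  estimates toward the mean.
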