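# Methods

## The measurement model

The pipeline targets paired half-cell data: one cell's lysate split into
two halves, one half sequenced for small RNAs and the other for mRNA.
Profiles from the two layers therefore share the cell as their biological
unit, and cross-layer correlations across cells are meaningful at *n* as
small as 19. Two kinds of noise matter:

* **half-split technical noise** — the stochastic difference between two
  halves of the same lysate, observable directly by processing both halves
  with the same assay and computing the replicate concordance *R*²;
* **biological heterogeneity** — genuine cell-to-cell variation, what the
  analysis is after.

## Synthetic generator

For miRNA *i* in cell *c* the latent log2 abundance is
`m_ic = mu_i + delta_ic`, `delta_ic ~ N(0, sigma_i^2)`. Emitted miRNA
expression is the fraction within all miRNAs, `2^m / sum 2^m` per cell
(base-2 softmax), matching the fraction normalization used for real data.
For gene *g*, `x_gc = b_g + cluster shift − sum_i s_gi * delta_ic +
N(0, sigma_bio^2)`, emitted as RPKM = `2^x`. Key choices:

* **Repression is linear in the latent log2 deviation delta**, not in the
  fraction, because all downstream correlation analysis operates on log2
  data. No quantitative miRNA-dose→repression law is assumed beyond this
  linear coupling; effect sizes for recovery tests are calibrated within
  the package, not taken from measurements.
* **Technical noise enters the latent log2 values** before the softmax /
  exponentiation. This keeps fraction columns summing to exactly 1 (the
  invariant real normalized data satisfy before flooring) while making the
  emitted matrices behave like one measured half each.
* **Fractions, not counts**: the analysis consumes fractions; an optional
  multinomial resampling step (`multinomial_counts`) exists for experiments
  needing integer counts, off by default.
* **Stream separation**: miRNA draws, mRNA draws and cluster assignment use
  separate seed-derived RNG streams, so changing `n_genes` leaves the miRNA
  layer bit-identical.
* **Cluster structure** shifts only designated module genes in cluster-2
  cells, emulating pathway-level transcriptome subtypes without modeling
  pathway identity.

Defaults (a "realistic" 19-cell experiment): miRNA log2 means ~ N(0, 3²)
(abundances spanning ~10 log2 units), per-miRNA intercellular SD 0.5,
gene baselines ~ N(3, 2²) log2 RPKM, biological SD 0.5, technical SD 0.4
log2 units. Recovery studies use 400 genes / 50 targets / coupling s = 1
with biological and technical SD 0.2 — an abundant-miRNA regime where
detection should be near-certain, paired with a zero-coupling control.

### Technical-noise calibration

The correlation between two equally noisy copies of a latent profile is
`r = sd_b² / (sd_b² + sd_t²)`; solving `r = sqrt(R²)` for a target
replicate `R² = 0.93` gives `sd_t = sd_b * sqrt((1−r)/r)` ≈ 0.19·sd_b.
`calibrate_tech_sd` instead bisects on simulated pairs (median R² over 100
pairs of 1000 features, monotone in sd_t), agreeing with the closed form to
Monte-Carlo error. With a feature-baseline spread of 2.5 log2 units the
calibrated technical SD is ≈ 0.48.

What the generator does *not* emulate: count overdispersion and dropout,
ligation/adaptor biases, double-counted multi-locus reads (accepted on
input but not generated), and any real pathway structure. Passing recovery
tests therefore show the inference machinery is sound under the stated
noise model, not that real libraries meet that model.

## Preprocessing

miRNA counts are divided by the cell's total miRNA-mapped reads
(quantified separately, so column sums may exceed 1 when multi-locus reads
are double-counted — accepted, never renormalized). Floors: 1e-4 for
fractions, 1e-3 for RPKM, applied before log2; values below the floor are
set to it, and fraction columns are *not* renormalized afterwards — the
floor is a transform floor, preserving the order of operations of the
normalization it mirrors. Sample SDs use the *n*−1 denominator everywhere.
Small-RNA category assignment is sequential first-match over
(miRNA, snoRNA, snRNA, scRNA, tRNA, rRNA, piRNA), configurable.
`detected_features` counts RPKM strictly above a threshold that defaults
to 0, since no detection criterion is canonical.

## Consensus clustering and differential expression

Rows are z-scored once on the full matrix (not per subsample; a per-run
alternative would be easy but the single standardization keeps the
consensus matrix interpretable against one fixed data scale). Each of 50
iterations draws `ceil(0.8 n)` cells without replacement, builds the
Pearson dissimilarity `1 − r` between cells and cuts an average-linkage
(UPGMA) tree at each k in 2..5. Consensus = co-clustered / co-sampled per
pair, diagonal 1 by convention. Final labels per k cut an average-linkage
tree of `1 − consensus`; k selection is deliberately left to the user,
with mean within-cluster consensus reported per k as the guide.

DE uses Welch *t* (pooled *t* by flag), a single global label shuffle per
permutation applied to all genes (preserving inter-gene correlation in the
null), and nominal p = plain fraction of permutations with
|t_perm| ≥ |t_obs| — p can be exactly 0 at finite permutations; an
add-one-smoothed option is available but off, keeping the plain-fraction
definition. Exceedances are counted with a 1e-9 absolute tolerance so
permutations that reproduce the observed split count as ties despite
float summation-order differences. Zero-variance genes get t = 0, p = 1.
q-values are Benjamini–Hochberg; the working threshold at 19-cell scale
is q < 0.1 (q < 0.05 for larger designs).

## Enrichment and KS comparison

The running sum walks the ranking top to bottom; a hit increments by
`|r| / sum_set |r|`, a miss decrements by `1/(N − n_set)`; ES is the
signed maximal deviation and lies in [−1, 1]. Weighting uses |r| with
exponent 1 (raw signed weights available by flag). If every set member has
r = 0 the hits fall back to equal weights so the hit mass stays 1. The
permutation p draws random same-size gene sets and is one-sided in the
observed direction, normalized by the number of same-sign null scores —
the convention under which null p-values are uniform; normalizing by all
permutations would center null p near 0.25.

Targets are filtered at total context score strictly < −0.1. Expression
strata default to mean log2 RPKM ≤ 4 vs > 4 (strict >, boundary low);
additional edges are configurable since no canonical multi-bin scheme
exists. KS is two-sample, two-sided; exact when both groups ≤ 25, else
asymptotic. Correlation ties are broken by gene ID for determinism;
zero-variance genes are excluded from rankings and reported.

## Signatures

Up = r > cutoff, down = r < −cutoff, strict at the boundary, default
cutoff 0.45. Symbols expand to *all* of their probes (first-probe-only by
flag), deduplicated in first-occurrence order; GRP files are one probe per
line, newline-terminated, byte-deterministic.

## qPCR and the variance permutation test

Relative expression is `2^−(Ct_target − Ct_reference)`; technical
replicates are averaged on the Ct scale before transformation (averaging
after exponentiation would weight replicates unequally on the log scale).
Group means compare by Welch's two-tailed t-test.

The variance test draws `subsample` values without replacement from each
*intact* group (no label mixing — the construction is subsampling, not a
label-permutation test), computes sample SDs, and reports
p = P(SD_treated ≥ SD_control) over 1000 draws; it is exactly invariant to
shifting both groups or scaling both by a positive factor. The robustness
scan repeats this over sizes 13–18 with independent substreams.

**Known limitation**: the test is calibrated only when the subsample is
well below the group size. At 15-of-30 the null rejection rate at
p < 0.05 is ≈ 5%; at 15-of-20 the subsampled SDs nearly reproduce the
full-group SDs and the rate inflates to ≈ 17%. Use a subsample of at most
about half the group.

## Problem sizes and numerical conventions

Simulation studies in the test suite and the acceptance script use 19
cells, 400 genes, 50-gene target sets, 100 replicates for detection rates,
20 replicates for FDR checks, 500 for null calibration, and 200–4000
permutations per test — sizes at which every Monte-Carlo assertion has
comfortable margin while the whole suite runs in seconds. Degenerate
inputs are conventions, not errors, wherever a convention is standard:
constant DE features (t = 0, p = 1), equal constant groups in Welch
(p = 1), empty enrichment intersections and constant correlation vectors
raise instead, since no meaningful value exists. Overflow of `2^x` is
guarded by capping latent log2 values at ±300.
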