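# halfcell

Analysis toolkit for **paired half-cell miRNA–mRNA co-profiling**: small
single-cell experiments in which each cell's lysate is split into two equal
halves, one profiled for small RNAs and the other for mRNA, so that both
omics layers come from the *same* cell. With paired profiles across a
handful of phenotypically identical cells (typically ~19), one can ask
whether the cell-to-cell variation of a miRNA is echoed — with opposite
sign — in its predicted target mRNAs, i.e. whether miRNA expression
heterogeneity alone drives non-genetic transcriptome heterogeneity.

## What it computes

* **Normalization & variability** — miRNA read counts become the fraction
  of each miRNA within all miRNA reads of a cell; mRNA enters as RPKM.
  Data are floored (1e-4 / 1e-3) and log2-transformed; per-feature
  mean–SD variability profiles use the sample SD (*n*−1).
* **Consensus clustering** — 50 iterations of average-linkage hierarchical
  clustering (Pearson dissimilarity, 1 − *r*, on row-z-scored data) on
  random 80% cell subsamples; the consensus matrix records co-clustering
  frequency per co-sampled cell pair.
* **Permutation differential expression** — Welch *t* per gene, a global
  label-shuffle null (5000 permutations), nominal *p* as the fraction of
  permutations reaching |*t*|, Benjamini–Hochberg FDR.
* **Target anti-correlation enrichment** — every gene is ranked by Pearson
  correlation *r* with a miRNA across cells; TargetScan-style predicted
  targets (total context score < −0.1) are tested for a shift toward
  negative *r* by (a) a GSEA-style weighted running-sum enrichment score
  (hits weighted by |*r*|, gene-label permutation *p*) and (b) a two-sample
  Kolmogorov–Smirnov test, optionally stratified by mean log2 RPKM
  (abundant targets: mean > 4).
* **Connectivity signatures** — genes with *r* > 0.45 / *r* < −0.45 form
  up/down signatures, mapped to microarray probes and exported as GRP files
  for querying a connectivity database.
* **Variance permutation test** — for perturbation qPCR data (comparative
  Ct, 2^−ΔCt): repeatedly subsample 15 values per group and report
  p = P(SD_treated ≥ SD_control) over 1000 draws, with a robustness scan
  over subsample sizes 13–18.
* **Synthetic data** — a fully seeded generator of paired profiles with
  log-normal miRNA heterogeneity, planted log2-linear target repression,
  half-split technical noise calibrated to replicate *R*² ≈ 0.93, optional
  two-group module structure, and a ground-truth record for recovery tests.

## Worked example

Plant repression (*s* = 1) of 50 target genes by an abundant, variable
miRNA in a 19-cell simulation, then recover it:

```python
import numpy as np
from halfcell import (SimConfig, default_config, generate_paired_profiles,
                      generate_target_table, plant_repression, floor_and_log2,
                      correlate_to_mirna, ks_compare, es_permutation_p,
                      extract_signature)

table = generate_target_table(1, 400, 50, seed=0)
cfg = default_config(seed=1, n_cells=19, n_mirnas=2, n_genes=400)
cfg = SimConfig(**{**cfg.__dict__, "mirna_sd_log2": (1.0, 0.1),
                   "mirna_mean_log2": (2.0, 0.0),
                   "target_edges": plant_repression(table, "miR-001", 1.0)})
mi, mr, truth = generate_paired_profiles(cfg)

mr_log = floor_and_log2(mr, 1e-3)
mi_log = floor_and_log2(mi, 1e-4)
ranking = correlate_to_mirna(mr_log, mi_log.data.loc["miR-001"].to_numpy(),
                             "miR-001")
targets = set(table["gene"]) & set(ranking.genes)
es = es_permutation_p(ranking, targets, n_perm=1000, seed=1)
ks = ks_compare(ranking, targets)
print(f"ES = {es.es:.3f}  (permutation p = {es.p_perm:.3g}, n_set = {es.n_set})")
print(f"KS D = {ks.d:.3f}  (p = {ks.p:.3g}, {ks.n_target} targets vs "
      f"{ks.n_nontarget} non-targets)")
print(f"median target r = {np.median(ranking.r_of(targets)):.3f}")
sig = extract_signature(ranking, 0.45)
print(f"signature: {len(sig.up)} up, {len(sig.down)} down genes at |r| > 0.45")
```

Output:

```
ES = -0.951  (permutation p = 0, n_set = 50)
KS D = 0.926  (p = 4.18e-50, 50 targets vs 350 non-targets)
median target r = -0.675
signature: 9 up, 60 down genes at |r| > 0.45
```

The strongly negative enrichment score and the large KS distance say the
planted targets sit at the anti-correlated end of the ranking — exactly the
footprint miRNA-mediated repression leaves in paired single-cell data. The
median target correlation of −0.675 reflects the planted coupling diluted
by biological and half-split technical noise.

The same stages are available from the shell:

```sh
halfcell simulate --seed 1 --out run/
halfcell normalize --matrix run/mrna_rpkm.tsv --unit rpkm --floor 1e-3 --out run/mrna_log2.tsv
halfcell cluster --matrix run/mrna_log2.tsv --k 2:5 --iters 50 --frac 0.8 --seed 1 --out run/
halfcell run --config cfg.yaml          # full pipeline with a manifest
```

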