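"""Synthetic paired half-cell miRNA/mRNA profile generator.

Emulates the statistical structure of a small paired single-cell co-profiling
experiment (default: 19 cells): log-normal miRNA abundance heterogeneity,
linear repression of planted target genes on the log2 scale, half-split
technical noise, and optional two-group cluster structure in mRNA modules.
Every generator is fully deterministic under a fixed seed and returns a
ground-truth record for parameter-recovery testing.

Model
-----
For miRNA *i* in cell *c* the latent log2 abundance is

    m_ic = mu_i + delta_ic,     delta_ic ~ N(0, sigma_i^2)

and the emitted miRNA "expression" is the fraction within all miRNAs,
``2^m / sum_i 2^m`` per cell (a softmax in base 2). For gene *g*,

    x_gc = b_g + cluster_effect*[g in module, c in cluster 2]
           - sum_i s_gi * delta_ic + N(0, sigma_bio^2)

with emitted RPKM = ``2^x``. Repression couplings ``s_gi >= 0`` act on the
latent deviation delta (not on the fraction), because all downstream
correlation analyses operate on log2 data. Half-split technical noise of SD
``tech_sd_log2`` is added to the latent log2 values before the softmax /
exponentiation, so emitted fraction columns still sum to exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

# Guard against overflow of 2**x in float64 (log2 space cap).
_LOG2_CAP = 300.0

DEFAULT_SCORE_RANGE = (-0.6, -0.02)


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i + 1:03d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{j + 1:05d}" for j in range(n)]


def generate_target_table(
    n_mirnas: int,
    n_genes: int,
    targets_per_mirna: int,
    score_range: tuple[float, float] = DEFAULT_SCORE_RANGE,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a TargetScan-style table of predicted (miRNA, gene) edges.

    Each miRNA receives exactly ``targets_per_mirna`` distinct target genes,
    sampled without replacement, with total context scores drawn uniformly
    from ``score_range`` (a sub-interval of [-1, 0]; more negative means
    stronger predicted repression).
    """
    if targets_per_mirna > n_genes:
        raise ValueError(
            f"targets_per_mirna ({targets_per_mirna}) exceeds n_genes ({n_genes})"
        )
    lo, hi = score_range
    if not (-1.0 <= lo <= hi <= 0.0):
        raise ValueError(f"score_range {score_range} must lie within [-1, 0]")
    rng = np.random.default_rng(seed)
    mirnas = _mirna_ids(n_mirnas)
    genes = np.asarray(_gene_ids(n_genes))
    rows = []
    for mirna in mirnas:
        chosen = rng.choice(n_genes, size=targets_per_mirna, replace=False)
        scores = rng.uniform(lo, hi, size=targets_per_mirna)
        for g, s in zip(genes[chosen], scores):
            rows.append((mirna, g, float(s)))
    return pd.DataFrame(rows, columns=["mirna", "gene", "total_context_score"])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the paired-profile generator.

    Per-feature parameters (``mirna_mean_log2``, ``mirna_sd_log2``,
    ``gene_baseline_log2``) are tuples of length ``n_mirnas`` / ``n_genes``.
    ``target_edges`` lists (mirna_id, gene_id, s) couplings; every non-listed
    pair has coupling 0. ``cluster_frac`` cells form cluster 2, whose
    ``module_genes`` are shifted by ``cluster_effect_log2``.
    """

    n_cells: int
    n_mirnas: int
    n_genes: int
    mirna_mean_log2: tuple[float, ...]
    mirna_sd_log2: tuple[float, ...]
    gene_baseline_log2: tuple[float, ...]
    target_edges: tuple[tuple[str, str, float], ...] = ()
    biological_sd_log2: float = 0.5
    tech_sd_log2: float = 0.4
    cluster_frac: float = 0.0
    cluster_effect_log2: float = 0.0
    module_genes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if len(self.mirna_mean_log2) != self.n_mirnas:
            raise ValueError("mirna_mean_log2 length must equal n_mirnas")
        if len(self.mirna_sd_log2) != self.n_mirnas:
            raise ValueError("mirna_sd_log2 length must equal n_mirnas")
        if len(self.gene_baseline_log2) != self.n_genes:
            raise ValueError("gene_baseline_log2 length must equal n_genes")
        for name, sds in (
            ("mirna_sd_log2", self.mirna_sd_log2),
            ("biological_sd_log2", (self.biological_sd_log2,)),
            ("tech_sd_log2", (self.tech_sd_log2,)),
        ):
            if any(s < 0 for s in sds):
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.cluster_frac <= 1.0:
            raise ValueError("cluster_frac must be in [0, 1]")
        mirnas = set(_mirna_ids(self.n_mirnas))
        genes = set(_gene_ids(self.n_genes))
        for mi, g, s in self.target_edges:
            if mi not in mirnas or g not in genes:
                raise ValueError(f"edge ({mi}, {g}) references unknown feature")
            if s < 0:
                raise ValueError("repression_strength must be >= 0")
        if any(abs(m) > _LOG2_CAP for m in self.mirna_mean_log2):
            raise ValueError(f"miRNA log2 means must stay within +/-{_LOG2_CAP}")

    @property
    def mirna_ids(self) -> list[str]:
        return _mirna_ids(self.n_mirnas)

    @property
    def gene_ids(self) -> list[str]:
        return _gene_ids(self.n_genes)


def default_config(
    seed: int = 0,
    n_cells: int = 19,
    n_mirnas: int = 30,
    n_genes: int = 2000,
    **overrides,
) -> SimConfig:
    """A realistic default configuration for a 19-cell paired experiment.

    miRNA log2 abundances span roughly ten log2 units (SD 3), intercellular
    SDs default to 0.5 log2 units, gene baselines mimic a log2 RPKM
    distribution centred near 3, and biological/technical SDs default to
    0.5 / 0.4 log2 units. Baselines are drawn from a seed-derived stream
    independent of the per-cell draws.
    """
    rng = np.random.default_rng([int(seed), 97])
    params = dict(
        n_cells=n_cells,
        n_mirnas=n_mirnas,
        n_genes=n_genes,
        mirna_mean_log2=tuple(rng.normal(0.0, 3.0, n_mirnas)),
        mirna_sd_log2=tuple(np.full(n_mirnas, 0.5)),
        gene_baseline_log2=tuple(rng.normal(3.0, 2.0, n_genes)),
        seed=int(seed),
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class GroundTruth:
    """Planted simulation parameters for parameter-recovery tests."""

    target_edges: tuple[tuple[str, str, float], ...]
    cluster_labels: np.ndarray  # per-cell, values in {1, 2}
    mirna_deviations: pd.DataFrame  # miRNA x cell latent delta (log2)
    module_genes: tuple[str, ...] = field(default_factory=tuple)

    def n_clusters(self) -> int:
        return len(set(self.cluster_labels.tolist()))


def plant_repression(
    table: pd.DataFrame, mirna: str, strength: float, genes: list[str] | None = None
) -> tuple[tuple[str, str, float], ...]:
    """Turn a target table's rows for one miRNA into coupling edges."""
    sub = table[table["mirna"] == mirna]
    if genes is not None:
        sub = sub[sub["gene"].isin(genes)]
    return tuple((mirna, g, float(strength)) for g in sub["gene"])


def generate_paired_profiles(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate one paired miRNA-fraction / mRNA-RPKM dataset.

    Separate seed-derived RNG streams drive the miRNA draws, the mRNA draws
    and the cluster assignment, so changing ``n_genes`` does not perturb the
    miRNA layer (and vice versa).
    """
    cells = [f"cell{c + 1:02d}" for c in range(config.n_cells)]
    rng_mi = np.random.default_rng([config.seed, 1])
    rng_mr = np.random.default_rng([config.seed, 2])
    rng_misc = np.random.default_rng([config.seed, 3])

    mu = np.asarray(config.mirna_mean_log2)[:, None]
    sd = np.asarray(config.mirna_sd_log2)[:, None]
    delta = rng_mi.standard_normal((config.n_mirnas, config.n_cells)) * sd
    m_latent = mu + delta
    m_obs = m_latent
    if config.tech_sd_log2 > 0:
        m_obs = m_obs + rng_mi.normal(0.0, config.tech_sd_log2, m_latent.shape)
    if np.abs(m_obs).max() > _LOG2_CAP:
        raise ValueError(
            "miRNA log2 abundances exceed the overflow cap; reduce means or SDs"
        )
    pw = np.exp2(m_obs)
    fractions = pw / pw.sum(axis=0, keepdims=True)

    # Cluster 2 membership: a random subset of round(frac * n) cells.
    n2 = int(round(config.cluster_frac * config.n_cells))
    labels = np.ones(config.n_cells, dtype=int)
    if n2 > 0:
        idx2 = rng_misc.choice(config.n_cells, size=n2, replace=False)
        labels[idx2] = 2

    baseline = np.asarray(config.gene_baseline_log2)[:, None]
    x = baseline + rng_mr.normal(0.0, config.biological_sd_log2,
                                 (config.n_genes, config.n_cells))
    if config.module_genes and config.cluster_effect_log2 != 0.0:
        gene_pos = {g: j for j, g in enumerate(config.gene_ids)}
        module_idx = [gene_pos[g] for g in config.module_genes]
        x[np.ix_(module_idx, np.flatnonzero(labels == 2))] += config.cluster_effect_log2
    if config.target_edges:
        mirna_pos = {m: i for i, m in enumerate(config.mirna_ids)}
        gene_pos = {g: j for j, g in enumerate(config.gene_ids)}
        for mi, g, s in config.target_edges:
            x[gene_pos[g], :] -= s * delta[mirna_pos[mi], :]
    x_obs = x
    if config.tech_sd_log2 > 0:
        x_obs = x_obs + rng_mr.normal(0.0, config.tech_sd_log2, x.shape)
    if np.abs(x_obs).max() > _LOG2_CAP:
        raise ValueError("mRNA log2 values exceed the overflow cap")
    rpkm = np.exp2(x_obs)

    mirna_mat = ExpressionMatrix(
        pd.DataFrame(fractions, index=config.mirna_ids, columns=cells), unit="fraction"
    )
    mrna_mat = ExpressionMatrix(
        pd.DataFrame(rpkm, index=config.gene_ids, columns=cells), unit="rpkm"
    )
    truth = GroundTruth(
        target_edges=config.target_edges,
        cluster_labels=labels,
        mirna_deviations=pd.DataFrame(delta, index=config.mirna_ids, columns=cells),
        module_genes=config.module_genes,
    )
    return mirna_mat, mrna_mat, truth


def generate_half_cell_pair(
    cell_profile: np.ndarray, tech_sd_log2: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Split one log2 profile into two replicates with independent noise.

    Each replicate equals the input profile plus independent per-feature
    N(0, tech_sd^2) noise, mimicking the halving of a single-cell lysate
    into two separately processed libraries.
    """
    if tech_sd_log2 < 0:
        raise ValueError("tech_sd_log2 must be >= 0")
    profile = np.asarray(cell_profile, dtype=float)
    rng = np.random.default_rng(seed)
    a = profile + rng.normal(0.0, tech_sd_log2, profile.shape)
    b = profile + rng.normal(0.0, tech_sd_log2, profile.shape)
    return a, b


def median_half_cell_r2(
    tech_sd_log2: float,
    baseline_sd_log2: float = 2.5,
    n_features: int = 1000,
    n_pairs: int = 100,
    seed: int = 0,
) -> float:
    """Median squared Pearson correlation over simulated half-cell pairs."""
    rng = np.random.default_rng([int(seed), 11])
    r2s = np.empty(n_pairs)
    for p in range(n_pairs):
        profile = rng.normal(0.0, baseline_sd_log2, n_features)
        a, b = generate_half_cell_pair(profile, tech_sd_log2, seed=rng.integers(2**31))
        r = np.corrcoef(a, b)[0, 1]
        r2s[p] = r * r
    return float(np.median(r2s))


def tech_sd_for_r2(baseline_sd_log2: float, target_r2: float) -> float:
    """Closed-form technical SD giving a target replicate R^2.

    The correlation between two copies of the same latent profile, each with
    independent N(0, sd_t^2) noise, is r = sd_b^2 / (sd_b^2 + sd_t^2); solve
    r = sqrt(R^2) for sd_t.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must be in (0, 1)")
    r = float(np.sqrt(target_r2))
    return baseline_sd_log2 * float(np.sqrt((1.0 - r) / r))


def calibrate_tech_sd(
    target_r2: float = 0.93,
    baseline_sd_log2: float = 2.5,
    n_features: int = 1000,
    n_pairs: int = 100,
    seed: int = 0,
    tol: float = 0.002,
    max_iter: int = 40,
) -> float:
    """Bisection sweep for the technical SD whose median half-cell R^2 hits
    ``target_r2``.

    Median R^2 is monotone non-increasing in the technical SD, so bisection
    on [0, 10 * baseline_sd] converges; the empirical result agrees with the
    closed form of :func:`tech_sd_for_r2` up to Monte-Carlo error.
    """
    lo, hi = 0.0, 10.0 * baseline_sd_log2
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r2 = median_half_cell_r2(mid, baseline_sd_log2, n_features, n_pairs, seed)
        if abs(r2 - target_r2) < tol:
            return mid
        if r2 > target_r2:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_qpcr_groups(
    n_control: int,
    n_treated: int,
    sd_control: float,
    sd_treated: float,
    mean: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two Gaussian measurement vectors for variance-test fixtures."""
    if n_control < 1 or n_treated < 1:
        raise ValueError("each group needs at least one sample")
    if sd_control < 0 or sd_treated < 0:
        raise ValueError("SDs must be >= 0")
    rng = np.random.default_rng(seed)
    control = rng.normal(mean, sd_control, n_control)
    treated = rng.normal(mean, sd_treated, n_treated)
    return control, treated


def multinomial_counts(
    fractions: ExpressionMatrix, depth: int, seed: int = 0
) -> ExpressionMatrix:
    """Optionally resample fraction columns as multinomial read counts.

    Off the default path: the analysis operates on fractions directly; this
    exists for experiments needing integer counts at a given read depth.
    """
    if fractions.unit != "fraction":
        raise ValueError("multinomial_counts expects a fraction matrix")
    rng = np.random.default_rng(seed)
    vals = fractions.values
    cols = [rng.multinomial(depth, vals[:, c] / vals[:, c].sum())
            for c in range(vals.shape[1])]
    counts = np.stack(cols, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df = pd.DataFrame(counts, index=fractions.data.index,
                          columns=fractions.data.columns)
    return ExpressionMatrix(df, unit="counts")
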