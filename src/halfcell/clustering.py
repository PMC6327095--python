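"""Resampled consensus clustering and permutation differential expression.

Cells are clustered by average-linkage hierarchical clustering on the
Pearson dissimilarity (1 - r) of row-standardized log2 profiles. Stability
is assessed by repeating the clustering on random 80% subsamples of cells
(50 iterations by default) and recording, for every cell pair, how often
the two cells co-cluster relative to how often they were co-sampled.
Differential expression between two cell groups uses a Welch t statistic
with a global label-permutation null (5000 shuffles by default) and
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .matrix import ClusterAssignment, ExpressionMatrix


def zscore_rows(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each feature row to mean 0, sample SD 1.

    Constant rows cannot be standardized; they are set to all-zero and their
    feature IDs are returned as the second element.
    """
    if matrix.n_cells < 2:
        raise ValueError("row standardization requires at least 2 cells")
    vals = matrix.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant, :] = 1.0
    z = (vals - mean) / sd
    z[constant, :] = 0.0
    flagged = [f for f, c in zip(matrix.features, constant) if c]
    return pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns), flagged


def pearson_dissimilarity(columns: pd.DataFrame) -> pd.DataFrame:
    """Cell-by-cell distance d(a, b) = 1 - Pearson r of their profiles."""
    vals = np.asarray(columns, dtype=float)
    if vals.shape[0] < 3:
        raise ValueError("need at least 3 features for a correlation distance")
    sds = vals.std(axis=0)
    if (sds == 0).any():
        bad = [str(columns.columns[i]) for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant profile for cell(s) {bad}: correlation undefined")
    corr = np.corrcoef(vals, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=columns.columns, columns=columns.columns)


def average_linkage_cut(distance: pd.DataFrame, k: int) -> ClusterAssignment:
    """Cut an average-linkage (UPGMA) tree of the given dissimilarity at k."""
    n = distance.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    d = np.asarray(distance, dtype=float)
    d = 0.5 * (d + d.T)  # tolerate tiny float asymmetry
    np.fill_diagonal(d, 0.0)
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        tree = linkage(squareform(d, checks=False), method="average")
        labels = fcluster(tree, t=k, criterion="maxclust")
    return ClusterAssignment(k=int(labels.max()), labels=labels,
                             cells=[str(c) for c in distance.index])


@dataclass
class ConsensusMatrix:
    """Co-clustering frequencies from resampled clustering at one k."""

    cells: list[str]
    co_cluster_counts: np.ndarray
    co_sample_counts: np.ndarray
    consensus: np.ndarray  # co_cluster / co_sample, diagonal forced to 1

    def __post_init__(self) -> None:
        if (self.co_cluster_counts > self.co_sample_counts).any():
            raise ValueError("co-cluster counts exceed co-sample counts")
        if not np.allclose(self.consensus, self.consensus.T):
            raise ValueError("consensus matrix must be symmetric")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.consensus, index=self.cells, columns=self.cells)


@dataclass
class ConsensusResult:
    """Consensus matrices, final labels and mean within-cluster consensus
    for each examined k (k selection is left to the user)."""

    cells: list[str]
    consensus: dict[int, ConsensusMatrix] = field(default_factory=dict)
    labels: dict[int, ClusterAssignment] = field(default_factory=dict)
    within_cluster_consensus: dict[int, float] = field(default_factory=dict)


def consensus_cluster(
    matrix: ExpressionMatrix,
    k_range: list[int] | range,
    iterations: int = 50,
    sample_frac: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Resampled consensus clustering over a range of cluster numbers.

    Rows are z-scored once on the full matrix; each iteration draws
    ``ceil(sample_frac * n)`` cells without replacement, clusters them by
    average linkage on Pearson dissimilarity, and cuts the tree at each k.
    Final labels per k come from an average-linkage cut of 1 - consensus.
    """
    n = matrix.n_cells
    if n < 4:
        raise ValueError("consensus clustering needs at least 4 cells")
    if not 0 < sample_frac <= 1:
        raise ValueError("sample_frac must be in (0, 1]")
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 or k > n for k in ks):
        raise ValueError(f"k_range must lie within [2, {n}]")

    z, _ = zscore_rows(matrix)
    m = math.ceil(sample_frac * n)
    rng = np.random.default_rng(seed)
    co_sample = np.zeros((n, n), dtype=int)
    co_cluster = {k: np.zeros((n, n), dtype=int) for k in ks}

    for _ in range(iterations):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = z.iloc[:, idx]
        dist = pearson_dissimilarity(sub)
        co_sample[np.ix_(idx, idx)] += 1
        for k in ks:
            kk = min(k, m)
            assign = average_linkage_cut(dist, kk)
            same = assign.labels[:, None] == assign.labels[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same.astype(int)

    result = ConsensusResult(cells=matrix.cells)
    for k in ks:
        with np.errstate(invalid="ignore"):
            cons = np.where(co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cm = ConsensusMatrix(
            cells=matrix.cells,
            co_cluster_counts=co_cluster[k],
            co_sample_counts=co_sample,
            consensus=cons,
        )
        result.consensus[k] = cm
        dist = pd.DataFrame(1.0 - cons, index=matrix.data.columns,
                            columns=matrix.data.columns)
        np.fill_diagonal(dist.values, 0.0)
        assign = average_linkage_cut(dist, k)
        result.labels[k] = assign
        within = []
        for lab in range(1, assign.k + 1):
            members = np.flatnonzero(assign.labels == lab)
            if members.size > 1:
                block = cons[np.ix_(members, members)]
                off = block[~np.eye(members.size, dtype=bool)]
                within.append(off.mean())
        result.within_cluster_consensus[k] = float(np.mean(within)) if within else 1.0
    return result


def cluster_proportions(labels: np.ndarray | list[int]) -> dict[int, float]:
    """Percent of cells in each cluster, in ascending label order."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    out = {}
    for lab in sorted(set(labels.tolist())):
        out[int(lab)] = float(100.0 * np.mean(labels == lab))
    return out


def _welch_t(vals: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
    """Vectorized Welch t per feature row; degenerate rows get t = 0."""
    x1, x2 = vals[:, idx1], vals[:, idx2]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    t = np.zeros_like(m1)
    ok = denom > 0
    t[ok] = (m1[ok] - m2[ok]) / denom[ok]
    return t


def permutation_de(
    matrix: ExpressionMatrix,
    labels: np.ndarray | list,
    n_perm: int = 5000,
    seed: int = 0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Two-group differential expression with a label-permutation null.

    The observed statistic is the Welch (unequal-variance) t per feature;
    each permutation applies one global shuffle of the cell labels to all
    features, and the nominal p is the plain fraction of permutations whose
    |t| reaches the observed |t| (so p can be 0 at finite n_perm). q-values
    are Benjamini-Hochberg over all features. Zero-variance features get
    t = 0, p = 1.
    """
    labels = np.asarray(labels)
    if labels.size != matrix.n_cells:
        raise ValueError("labels length must match the number of cells")
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    idx1 = np.flatnonzero(labels == groups[0])
    idx2 = np.flatnonzero(labels == groups[1])
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError("each group needs at least 2 cells")
    vals = matrix.values
    if pooled:
        stat = _pooled_t
    else:
        stat = _welch_t
    t_obs = stat(vals, idx1, idx2)

    rng = np.random.default_rng(seed)
    n = labels.size
    exceed = np.zeros(vals.shape[0], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        p1, p2 = perm[: idx1.size], perm[idx1.size:]
        t_perm = stat(vals, p1, p2)
        # tolerance so permutations reproducing the observed split count as
        # ties despite summation-order rounding
        exceed += np.abs(t_perm) - np.abs(t_obs) >= -1e-9
    p_nominal = exceed / n_perm
    q = bh_fdr(p_nominal)
    return pd.DataFrame(
        {"feature": matrix.features, "t": t_obs, "p_nominal": p_nominal, "q": q}
    )


def _pooled_t(vals: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
    x1, x2 = vals[:, idx1], vals[:, idx2]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    sp2 = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n2 - 1) * x2.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = np.zeros_like(m1)
    ok = denom > 0
    t[ok] = (m1[ok] - m2[ok]) / denom[ok]
    return t


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
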