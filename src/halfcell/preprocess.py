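"""Normalization, flooring, read-category assignment and variability profiling.

miRNA counts are normalized to the fraction of each miRNA within all miRNA
reads of a cell. Because quantification can assign one read to several
precursor loci, per-cell fraction columns may legitimately sum to more than
1; no renormalization is performed. Expression floors (default 1e-4 for
miRNA fractions, 1e-3 for RPKM) are imposed before the log2 transform and
never followed by renormalization.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ConcordanceReport, ExpressionMatrix

MIRNA_FLOOR = 1e-4
MRNA_FLOOR = 1e-3

#: Sequential small-RNA mapping priority: a read is assigned to the first
#: category it maps to, in this order.
DEFAULT_CATEGORY_PRIORITY = (
    "miRNA", "snoRNA", "snRNA", "scRNA", "tRNA", "rRNA", "piRNA",
)


def normalize_mirna_fractions(
    counts: ExpressionMatrix, totals: Mapping[str, float] | pd.Series
) -> ExpressionMatrix:
    """Divide per-miRNA read counts by each cell's total miRNA reads.

    ``totals`` maps cell ID to the total miRNA-mapped reads of that cell
    (quantified independently of the per-miRNA counts, so column sums of the
    result may exceed 1 when multi-locus reads are double-counted).
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit {counts.unit!r}")
    totals = pd.Series(totals, dtype=float)
    scale = []
    for cell in counts.data.columns:
        if cell not in totals.index:
            raise ValueError(f"no total miRNA read count for cell {cell!r}")
        t = float(totals[cell])
        if not np.isfinite(t) or t <= 0:
            raise ValueError(f"total miRNA reads for cell {cell!r} must be > 0, got {t}")
        scale.append(t)
    frac = counts.data.astype(float).div(pd.Series(scale, index=counts.data.columns), axis=1)
    return ExpressionMatrix(frac, unit="fraction")


def floor_and_log2(matrix: ExpressionMatrix, floor: float) -> ExpressionMatrix:
    """Impose an expression floor, then log2-transform.

    Every value below ``floor`` is set to ``floor`` before taking log2, so
    the output minimum is ``log2(floor)``. Idempotent on already-floored
    linear data.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    if matrix.unit == "log2":
        raise ValueError("matrix is already log2-transformed")
    floored = matrix.data.clip(lower=floor)
    return ExpressionMatrix(np.log2(floored), unit="log2", floor_applied=floor)


def assign_read_category(
    match_flags: Mapping[str, bool],
    priority: Sequence[str] = DEFAULT_CATEGORY_PRIORITY,
) -> str:
    """First category in priority order with a positive mapping flag.

    Models sequential mapping of small-RNA reads: only reads unmapped at one
    step proceed to the next category. Returns ``"unmapped"`` when no
    category matched.
    """
    if len(set(priority)) != len(priority) or not priority:
        raise ValueError("priority must be a non-empty list of unique categories")
    unknown = set(match_flags) - set(priority)
    if unknown:
        raise ValueError(f"flags for unknown categories: {sorted(unknown)}")
    for category in priority:
        if match_flags.get(category, False):
            return category
    return "unmapped"


def variability_profile(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature mean and sample SD (n-1 denominator) across cells.

    The mean/SD scatter of log2 expression is the standard view of
    intercellular variability: lowly expressed features show inherently
    large log2 SDs, and features lying above the trend at comparable mean
    expression are the biologically variable ones.
    """
    if matrix.unit != "log2":
        raise ValueError("variability_profile expects log2 data")
    if matrix.n_cells < 2:
        raise ValueError("variability requires at least 2 cells")
    vals = matrix.values
    return pd.DataFrame(
        {
            "feature": matrix.features,
            "mean_log2": vals.mean(axis=1),
            "sd_log2": vals.std(axis=1, ddof=1),
        }
    )


def replicate_concordance(a: np.ndarray, b: np.ndarray) -> ConcordanceReport:
    """Pearson concordance between two half-cell replicate log2 profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("replicate vectors must be 1-D and equally long")
    finite = np.isfinite(a) & np.isfinite(b)
    a, b = a[finite], b[finite]
    if a.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("correlation undefined: both replicate vectors are constant")
    r = float(np.corrcoef(a, b)[0, 1])
    return ConcordanceReport(r=r, r_squared=r * r, n_features=int(a.size))


def detected_features(matrix: ExpressionMatrix, threshold: float = 0.0) -> pd.Series:
    """Per-cell count of features expressed above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (matrix.data > threshold).sum(axis=0)


def library_success_rate(
    mirna_pass: Sequence[bool], mrna_pass: Sequence[bool]
) -> float:
    """Percentage of cells whose miRNA *and* mRNA libraries both pass QC."""
    mirna_pass = np.asarray(mirna_pass, dtype=bool)
    mrna_pass = np.asarray(mrna_pass, dtype=bool)
    if mirna_pass.shape != mrna_pass.shape or mirna_pass.size == 0:
        raise ValueError("QC flag vectors must be non-empty and equally long")
    return float(100.0 * np.mean(mirna_pass & mrna_pass))
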