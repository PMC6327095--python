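"""Core expression-matrix container shared by all analysis stages.

Matrices are features x cells, matching the convention that each column of a
heatmap is a single cell. Values are tagged with a unit so downstream stages
can refuse data on the wrong scale (e.g. clustering requires log2 data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "fraction", "rpkm", "log2")


@dataclass
class ExpressionMatrix:
    """A feature x cell expression matrix with a unit tag.

    Parameters
    ----------
    data
        DataFrame with feature IDs as the index and cell IDs as columns.
    unit
        One of ``counts``, ``fraction``, ``rpkm`` (all non-negative linear
        scales) or ``log2`` (any real).
    floor_applied
        The expression floor that was imposed before a log2 transform, or
        ``None`` if no floor has been applied.
    """

    data: pd.DataFrame
    unit: str
    floor_applied: float | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell IDs: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        if self.unit != "log2" and (values < 0).any():
            raise ValueError(f"negative values are not allowed for unit {self.unit!r}")

    @property
    def features(self) -> list[str]:
        return [str(f) for f in self.data.index]

    @property
    def cells(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ConcordanceReport:
    """Pearson concordance between two replicate log2 profiles."""

    r: float
    r_squared: float
    n_features: int


@dataclass
class ClusterAssignment:
    """A hard partition of cells into ``k`` clusters labelled 1..k."""

    k: int
    labels: np.ndarray  # shape (n_cells,), integer labels in 1..k
    cells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(self.labels.tolist())
        if not present.issubset(set(range(1, self.k + 1))):
            raise ValueError(f"labels outside 1..{self.k}: {sorted(present)}")
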