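"""Readers and writers for the plain-text formats used across the pipeline.

Canonical matrix format: TSV, first column feature IDs (header ``feature``),
remaining columns one cell each. Gene sets use GMT (name, description,
members). Signatures use GRP (one probe per line). All writers produce
deterministic byte-identical output for identical inputs.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def read_matrix(path: str | Path, unit: str) -> ExpressionMatrix:
    """Parse a TSV expression matrix, reporting errors with line numbers."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: line 1: header must name at least one cell")
    cells = header[1:]
    seen_cells: set[str] = set()
    for c in cells:
        if c in seen_cells:
            raise ValueError(f"{path}: line 1: duplicate cell ID {c!r}")
        seen_cells.add(c)
    features: list[str] = []
    rows: list[list[float]] = []
    seen: dict[str, int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        fid = parts[0]
        if fid in seen:
            raise ValueError(
                f"{path}: line {lineno}: duplicate feature ID {fid!r} "
                f"(first seen on line {seen[fid]})"
            )
        seen[fid] = lineno
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
        if any(not np.isfinite(v) for v in rows[-1]):
            raise ValueError(f"{path}: line {lineno}: missing/non-finite value")
        features.append(fid)
    df = pd.DataFrame(rows, index=features, columns=cells, dtype=float)
    return ExpressionMatrix(df, unit=unit)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write a matrix in canonical TSV form (round-trips byte-identically)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("feature\t" + "\t".join(matrix.cells) + "\n")
        vals = matrix.values
        for i, fid in enumerate(matrix.features):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in vals[i]) + "\n")
    return path


def read_target_table(path: str | Path) -> pd.DataFrame:
    """Read a 3-column (mirna, gene, total_context_score) TSV."""
    df = pd.read_csv(path, sep="\t")
    required = ["mirna", "gene", "total_context_score"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: header must start with {required}")
    if df.duplicated(["mirna", "gene"]).any():
        dup = df[df.duplicated(["mirna", "gene"])].iloc[0]
        raise ValueError(f"{path}: duplicate pair ({dup['mirna']}, {dup['gene']})")
    if not np.all(np.isfinite(df["total_context_score"])):
        raise ValueError(f"{path}: non-finite context score")
    return df[required]


def write_target_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file into a name -> member-list map.

    Duplicate members within a set are removed with a warning; lines with
    fewer than three fields are rejected.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {lineno}: GMT lines need >= 3 fields")
        name, members = parts[0], parts[2:]
        unique = list(dict.fromkeys(members))
        if len(unique) != len(members):
            warnings.warn(f"{path}: line {lineno}: duplicate members in set {name!r}",
                          stacklevel=2)
        sets[name] = unique
    return sets


def read_probe_map(path: str | Path) -> pd.DataFrame:
    """Read a 2-column (symbol, probe) TSV; duplicate rows dropped with a
    warning."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs 2 columns (symbol, probe)")
    df = df.iloc[:, :2]
    df.columns = ["symbol", "probe"]
    if df.duplicated().any():
        warnings.warn(f"{path}: duplicate (symbol, probe) rows dropped", stacklevel=2)
        df = df.drop_duplicates()
    return df.reset_index(drop=True)


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a (sample, group, ct_target, ct_reference) TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "ct_target", "ct_reference"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: qPCR table must have columns {sorted(required)}")
    for col in ("ct_target", "ct_reference"):
        if not np.all(np.isfinite(df[col])) or (df[col] <= 0).any():
            raise ValueError(f"{path}: {col} must be finite and > 0")
    return df
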