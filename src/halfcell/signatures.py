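"""Connectivity-map query signatures from miRNA correlation rankings.

Genes whose correlation with a miRNA exceeds a cutoff (|r| > 0.45 by
default, strict) form the positive/negative signature of that miRNA; gene
symbols are mapped (many-to-many) to microarray probe IDs and written as
plain GRP files, one probe per line, ready to query a connectivity
database for perturbations mimicking or reversing the signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .enrichment import CorrelationRanking

SIGNATURE_CUTOFF = 0.45


@dataclass
class SignaturePair:
    mirna: str
    up: list[str]
    down: list[str]
    cutoff: float

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down signatures overlap")


@dataclass
class ProbeMap:
    """Many-to-many gene symbol to probe ID mapping."""

    table: pd.DataFrame  # columns: symbol, probe
    _index: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.table.duplicated(["symbol", "probe"]).any():
            raise ValueError("duplicate (symbol, probe) rows in probe map")
        self._index = {}
        for symbol, probe in self.table.itertuples(index=False):
            self._index.setdefault(str(symbol), []).append(str(probe))

    def probes_for(self, symbol: str) -> list[str]:
        return self._index.get(symbol, [])


def extract_signature(
    ranking: CorrelationRanking, cutoff: float = SIGNATURE_CUTOFF
) -> SignaturePair:
    """Split a ranking into up (r > cutoff) and down (r < -cutoff) lists.

    Boundary values exactly at +/-cutoff are excluded (strict inequality);
    ranking order is preserved in both lists.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    up = [g for g, r in zip(ranking.genes, ranking.r) if r > cutoff]
    down = [g for g, r in zip(ranking.genes, ranking.r) if r < -cutoff]
    if not up and not down:
        warnings.warn(f"empty signature at cutoff {cutoff}", stacklevel=2)
    return SignaturePair(mirna=ranking.mirna, up=up, down=down, cutoff=cutoff)


def map_to_probes(
    genes: list[str], probe_map: ProbeMap, first_only: bool = False
) -> tuple[list[str], list[str]]:
    """Expand gene symbols to probe IDs.

    All probes of a mappable symbol are emitted (or only the first with
    ``first_only``), deduplicated, in order of first occurrence. Returns
    (probes, unmapped_symbols).
    """
    probes: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for g in genes:
        ps = probe_map.probes_for(g)
        if not ps:
            unmapped.append(g)
            continue
        if first_only:
            ps = ps[:1]
        for p in ps:
            if p not in seen:
                seen.add(p)
                probes.append(p)
    return probes, unmapped


def write_grp(
    signature: SignaturePair, probe_map: ProbeMap, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>_up.grp`` / ``<prefix>_down.grp`` probe lists.

    One probe ID per line, no header, newline-terminated. An empty side
    produces an empty file with a warning.
    """
    if not signature.up and not signature.down:
        raise ValueError("signature is empty on both sides")
    out_prefix = Path(out_prefix)
    paths = []
    for side, genes in (("up", signature.up), ("down", signature.down)):
        probes, unmapped = map_to_probes(genes, probe_map)
        if unmapped:
            warnings.warn(f"{len(unmapped)} unmapped symbol(s) in {side} signature",
                          stacklevel=2)
        if not probes:
            warnings.warn(f"{side} GRP file is empty", stacklevel=2)
        path = out_prefix.parent / f"{out_prefix.name}_{side}.grp"
        path.write_text("".join(p + "\n" for p in probes))
        paths.append(path)
    return paths[0], paths[1]


def read_grp(path: str | Path) -> list[str]:
    """Read a GRP probe list back (inverse of :func:`write_grp`)."""
    return [line for line in Path(path).read_text().splitlines() if line]
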