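"""Transcript-abundance arithmetic: RPKM and gene-panel fold comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionRecord", "GenePanel", "rpkm", "rpkm_table", "panel_fold"]


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    count: int
    cds_length_bp: int
    rpkm: float


@dataclass(frozen=True)
class GenePanel:
    """A named set of genes (e.g. the adapted Entner-Doudoroff panel)."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"panel {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"panel {self.name!r} has duplicate gene ids")


def rpkm(count: float, cds_length_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of coding sequence per million mapped reads."""
    if cds_length_bp <= 0:
        raise ValueError(f"CDS length must be positive, got {cds_length_bp}")
    if total_mapped_reads <= 0:
        raise ValueError(f"library size must be positive, got {total_mapped_reads}")
    if count < 0:
        raise ValueError(f"read count must be non-negative, got {count}")
    return count / (cds_length_bp / 1e3) / (total_mapped_reads / 1e6)


def rpkm_table(counts: pd.DataFrame, total_mapped_reads: float | None = None) -> pd.DataFrame:
    """Add an ``rpkm`` column to a counts table (gene_id, count, cds_length_bp).

    ``total_mapped_reads`` defaults to the column sum of ``count``.
    """
    required = {"gene_id", "count", "cds_length_bp"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    total = float(counts["count"].sum()) if total_mapped_reads is None else total_mapped_reads
    out = counts.copy()
    out["rpkm"] = [
        rpkm(c, l, total) for c, l in zip(out["count"], out["cds_length_bp"])
    ]
    return out


def panel_fold(
    panel_a: Sequence[float] | Iterable[float],
    panel_b: Sequence[float] | Iterable[float],
    summary: str = "mean",
) -> float:
    """Fold ratio summary(panel_a) / summary(panel_b) of RPKM values."""
    a = np.asarray(list(panel_a), dtype=float)
    b = np.asarray(list(panel_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both panels must be non-empty")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("RPKM values must be non-negative")
    if summary == "mean":
        num, den = float(np.mean(a)), float(np.mean(b))
    elif summary == "median":
        num, den = float(np.median(a)), float(np.median(b))
    else:
        raise ValueError(f"unknown summary {summary!r}; use 'mean' or 'median'")
    if den == 0:
        raise ValueError("denominator panel summary is zero")
    return num / den
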