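"""Table and configuration I/O.

TSV dialect: tab-separated, UTF-8, header row required, "." decimal
separator. All floating-point values in emitted reports are formatted at
6 significant digits so that repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .balances import RateSet, YieldSet
from .formulas import Compound
from .labeling import NMRObservation

__all__ = [
    "TableFormatError",
    "read_rates_tsv",
    "read_yields_tsv",
    "read_nmr_tsv",
    "read_counts_tsv",
    "load_registry_yaml",
    "format_float",
    "write_tsv",
    "write_json",
]


class TableFormatError(ValueError):
    """Raised with file/line/column context when an input table is malformed."""


def _read_tsv(path: str | Path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise TableFormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing required columns {sorted(missing)}")
    return df


def _as_float(path: Path | str, row: int, column: str, text: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise TableFormatError(
            f"{path}: line {row + 2}, column {column!r}: not a number: {text!r}"
        ) from exc


def read_rates_tsv(path: str | Path, substrate: str = "galacturonate") -> RateSet:
    """Read biomass-specific rates from a compound/value/sd/unit table."""
    df = _read_tsv(path, {"compound", "value"})
    values: dict[str, float] = {}
    sd: dict[str, float] = {}
    for i, row in df.iterrows():
        name = row["compound"].strip()
        if not name:
            raise TableFormatError(f"{path}: line {i + 2}: empty compound name")
        values[name] = _as_float(path, i, "value", row["value"])
        if "sd" in df.columns and row["sd"].strip():
            sd[name] = _as_float(path, i, "sd", row["sd"])
    return RateSet(values=values, sd=sd, substrate=substrate)


def read_yields_tsv(path: str | Path, substrate: str = "galacturonate") -> YieldSet:
    """Read yields from a compound/value/sd/unit table (mixed Cmol/mol units)."""
    df = _read_tsv(path, {"compound", "value"})
    values: dict[str, float] = {}
    units: dict[str, str] = {}
    sd: dict[str, float] = {}
    for i, row in df.iterrows():
        name = row["compound"].strip()
        values[name] = _as_float(path, i, "value", row["value"])
        if "unit" in df.columns and row["unit"].strip():
            units[name] = row["unit"].strip()
        if "sd" in df.columns and row["sd"].strip():
            sd[name] = _as_float(path, i, "sd", row["sd"])
    return YieldSet(values=values, units=units, sd=sd, substrate=substrate)


def read_nmr_tsv(path: str | Path) -> list[NMRObservation]:
    """Read NMR observations (time_h, pct_methyl, pct_carbonyl; blank = missing)."""
    df = _read_tsv(path, {"time_h"})
    obs: list[NMRObservation] = []
    for i, row in df.iterrows():
        time_h = _as_float(path, i, "time_h", row["time_h"])
        def cell(col: str) -> float | None:
            if col not in df.columns or not str(row[col]).strip():
                return None
            return _as_float(path, i, col, row[col])
        obs.append(
            NMRObservation(
                time_h=time_h, pct_methyl=cell("pct_methyl"), pct_carbonyl=cell("pct_carbonyl")
            )
        )
    return obs


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene counts table (gene_id, count, cds_length_bp)."""
    df = _read_tsv(path, {"gene_id", "count", "cds_length_bp"})
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].str.strip(),
            "count": [
                _as_float(path, i, "count", v) for i, v in enumerate(df["count"])
            ],
            "cds_length_bp": [
                _as_float(path, i, "cds_length_bp", v)
                for i, v in enumerate(df["cds_length_bp"])
            ],
        }
    )
    return out


def load_registry_yaml(path: str | Path) -> dict[str, Compound]:
    """Load a compound registry (name → formula string) from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise TableFormatError(f"{path}: registry must be a mapping of name to formula")
    return {name: Compound.from_string(name, formula) for name, formula in raw.items()}


def format_float(x: Any) -> Any:
    """Format floats at 6 significant digits (determinism convention)."""
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


def _round_tree(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _round_tree(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v) for v in obj]
    return format_float(obj)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda v: f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_round_tree(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
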