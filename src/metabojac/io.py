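"""Strict readers and writers for the three table formats.

All tables are TSV with headers. Parsing is strict by design: malformed
numeric cells raise with a cell address instead of being silently coerced
to NaN, because silent missing values corrupt covariance estimates
invisibly downstream.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ssi import validate_yield_table
from .types import (
    METADATA_COLUMNS,
    MetaboliteMatrix,
    MetabolicNetwork,
    normalize_condition,
)

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_network",
    "write_network",
]


def _strict_float(raw: pd.Series, column: str) -> np.ndarray:
    """Convert a string column to float, naming the first bad cell."""
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        raise ValueError(
            f"non-numeric value {raw.iloc[row]!r} in column {column!r}, "
            f"data row {row}"
        )
    return out.to_numpy(dtype=float)


def read_abundance_table(path: str | Path) -> MetaboliteMatrix:
    """Read a wide abundance TSV into a validated MetaboliteMatrix.

    Required metadata columns: genotype, replicate, condition, time_point;
    every remaining column is a metabolite. Condition labels are
    normalized to {WW, DS}; duplicate observation keys and non-numeric
    abundances raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"abundance table missing column(s): {missing}")
    out = pd.DataFrame()
    out["genotype"] = df["genotype"].astype(str)
    out["replicate"] = _strict_float(df["replicate"], "replicate").astype(int)
    out["condition"] = df["condition"].map(normalize_condition)
    out["time_point"] = _strict_float(df["time_point"], "time_point").astype(int)
    for col in df.columns:
        if col in METADATA_COLUMNS:
            continue
        out[col] = _strict_float(df[col], col)
    return MetaboliteMatrix(frame=out)


def write_abundance_table(matrix: MetaboliteMatrix, path: str | Path) -> None:
    matrix.frame.to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read a genotype / Yp / Ys phenotype TSV (strict numeric parsing)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("genotype", "Yp", "Ys"):
        if col not in df.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    out = pd.DataFrame(
        {
            "genotype": df["genotype"].astype(str),
            "Yp": _strict_float(df["Yp"], "Yp"),
            "Ys": _strict_float(df["Ys"], "Ys"),
        }
    )
    return validate_yield_table(out)


def write_phenotype_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_network(path: str | Path, names: list[str] | None = None) -> MetabolicNetwork:
    """Read a directed edge-list TSV (columns: source, target).

    ``names`` fixes the node universe and ordering (typically the
    abundance table's metabolite columns); without it the ordering is
    first appearance in the file. Whether the nodes match the abundance
    table is checked at pipeline assembly, not here.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source", "target"):
        if col not in df.columns:
            raise ValueError(f"network edge list missing column {col!r}")
    edges = [(str(s), str(t)) for s, t in zip(df["source"], df["target"])]
    if names is None:
        seen: dict[str, None] = {}
        for s, t in edges:
            seen.setdefault(s)
            seen.setdefault(t)
        names = list(seen)
    return MetabolicNetwork(names=list(names), edges=edges)


def write_network(network: MetabolicNetwork, path: str | Path) -> None:
    pd.DataFrame(network.edges, columns=["source", "target"]).to_csv(
        path, sep="\t", index=False
    )
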