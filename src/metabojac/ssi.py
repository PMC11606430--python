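"""Stress susceptibility index (SSI) and tolerance-quadrant classification.

The SSI of Fischer & Maurer (1978) ranks genotypes by how much of the
panel-wide stress response they express. With Yp/Ys the genotype's mean
trait value (here: 100-seed weight, grams) under well-watered (WW) and
drought-stressed (DS) conditions, and MYp/MYs the panel grand means,

    SI    = 1 - MYs / MYp          (stress intensity, panel-level loss)
    SSI_i = (1 - Ys_i / Yp_i) / SI

so SSI = 1 marks a genotype losing exactly the panel-average fraction;
SSI < 1 marks relative tolerance, SSI > 1 relative susceptibility. The
Yp-weighted mean of SSI over the panel equals 1 identically.

The quadrant biplot crosses SSI against the stressed trait value: Q1
tolerant & high-yielding, Q2 tolerant & low-yielding, Q3 susceptible &
low-yielding, Q4 susceptible & high-yielding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SSIResult",
    "QuadrantAssignment",
    "validate_yield_table",
    "stress_intensity",
    "compute_ssi",
    "classify_quadrants",
]


@dataclass
class SSIResult:
    """Per-genotype SSI plus the panel constants it was computed from."""

    table: pd.DataFrame  # genotype, SSI, tolerant (bool)
    SI: float
    MYp: float
    MYs: float

    @property
    def ssi(self) -> pd.Series:
        return self.table.set_index("genotype")["SSI"]


@dataclass
class QuadrantAssignment:
    """Quadrant label per genotype and the thresholds that produced it."""

    table: pd.DataFrame  # genotype, SSI, Ys, quadrant
    ssi_threshold: float
    trait_threshold: float

    def members(self, quadrant: str) -> list[str]:
        return self.table.loc[self.table["quadrant"] == quadrant, "genotype"].tolist()


def validate_yield_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the genotype / Yp / Ys contract and return the table."""
    for col in ("genotype", "Yp", "Ys"):
        if col not in table.columns:
            raise ValueError(f"yield table missing column {col!r}")
    if table["genotype"].duplicated().any():
        dup = table.loc[table["genotype"].duplicated(), "genotype"].tolist()
        raise ValueError(f"duplicate genotype identifiers: {dup}")
    bad = table.loc[table["Yp"] <= 0, "genotype"].tolist()
    if bad:
        raise ValueError(f"non-positive Yp for genotype(s): {bad}")
    if (table["Ys"] < 0).any():
        bad = table.loc[table["Ys"] < 0, "genotype"].tolist()
        raise ValueError(f"negative Ys for genotype(s): {bad}")
    return table


def stress_intensity(table: pd.DataFrame) -> float:
    """Panel stress intensity SI = 1 - mean(Ys) / mean(Yp).

    SI <= 0 (no net stress) is returned as-is; ``compute_ssi`` rejects it,
    since the SSI is undefined for an unstressed panel.
    """
    validate_yield_table(table)
    if len(table) < 1:
        raise ValueError("yield table is empty")
    return float(1.0 - table["Ys"].mean() / table["Yp"].mean())


def compute_ssi(table: pd.DataFrame) -> SSIResult:
    """Per-genotype SSI = (1 - Ys/Yp) / SI with tolerance labels."""
    validate_yield_table(table)
    si = stress_intensity(table)
    if si <= 0:
        raise ValueError(
            f"no net stress in panel (SI = {si:.4g}); SSI undefined"
        )
    ssi = (1.0 - table["Ys"] / table["Yp"]) / si
    out = pd.DataFrame(
        {
            "genotype": table["genotype"].to_numpy(),
            "SSI": ssi.to_numpy(dtype=float),
            "tolerant": (ssi <= 1.0).to_numpy(),
        }
    )
    return SSIResult(
        table=out,
        SI=si,
        MYp=float(table["Yp"].mean()),
        MYs=float(table["Ys"].mean()),
    )


def classify_quadrants(
    ssi: SSIResult,
    table: pd.DataFrame,
    ssi_threshold: float = 1.0,
    trait_threshold_policy: str = "median",
    trait_threshold: float | None = None,
) -> QuadrantAssignment:
    """Assign each genotype to a quadrant of the SSI x stressed-trait biplot.

    Q1: SSI <= ssi_threshold and Ys >= trait_threshold (tolerant, high yield)
    Q2: SSI <= ssi_threshold and Ys <  trait_threshold
    Q3: SSI >  ssi_threshold and Ys <  trait_threshold
    Q4: SSI >  ssi_threshold and Ys >= trait_threshold

    A genotype exactly on a threshold goes to the tolerant / high-yield
    side. ``trait_threshold_policy`` chooses the seed-weight split:
    "median" (default), "mean", or "explicit" with ``trait_threshold``.
    """
    validate_yield_table(table)
    merged = ssi.table.merge(table[["genotype", "Ys"]], on="genotype", how="outer")
    if merged["SSI"].isna().any() or merged["Ys"].isna().any():
        raise ValueError("SSI result and yield table cover different genotypes")
    if trait_threshold_policy == "median":
        thr = float(table["Ys"].median())
    elif trait_threshold_policy == "mean":
        thr = float(table["Ys"].mean())
    elif trait_threshold_policy == "explicit":
        if trait_threshold is None:
            raise ValueError("explicit policy requires trait_threshold")
        thr = float(trait_threshold)
    else:
        raise ValueError(f"unknown trait_threshold_policy: {trait_threshold_policy!r}")

    tol = merged["SSI"] <= ssi_threshold
    high = merged["Ys"] >= thr
    quadrant = np.where(
        tol & high, "Q1", np.where(tol, "Q2", np.where(~high, "Q3", "Q4"))
    )
    out = merged[["genotype", "SSI", "Ys"]].copy()
    out["quadrant"] = quadrant
    return QuadrantAssignment(
        table=out, ssi_threshold=float(ssi_threshold), trait_threshold=thr
    )
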