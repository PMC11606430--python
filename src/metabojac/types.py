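"""Shared data containers: metabolite matrix and metabolic network.

Tables are thin wrappers around pandas DataFrames so that every module
speaks the same dialect: observations are rows keyed by
(genotype, replicate, condition, time_point), metabolites are columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["METADATA_COLUMNS", "CONDITIONS", "MetaboliteMatrix", "MetabolicNetwork"]

#: metadata columns every abundance table must carry, in canonical order
METADATA_COLUMNS = ("genotype", "replicate", "condition", "time_point")

#: recognised watering regimes
CONDITIONS = ("WW", "DS")

_CONDITION_ALIASES = {
    "ww": "WW",
    "well-watered": "WW",
    "well_watered": "WW",
    "control": "WW",
    "ds": "DS",
    "drought": "DS",
    "drought-stressed": "DS",
    "drought_stressed": "DS",
    "stress": "DS",
}


def normalize_condition(label: str) -> str:
    """Map a condition label to the canonical {WW, DS} vocabulary."""
    key = str(label).strip().lower()
    if key in _CONDITION_ALIASES:
        return _CONDITION_ALIASES[key]
    raise ValueError(f"unknown condition label: {label!r}")


@dataclass
class MetaboliteMatrix:
    """Wide table of relative metabolite abundances with sample metadata.

    ``frame`` holds the metadata columns (genotype, replicate, condition,
    time_point) followed by one column per metabolite. Values are positive
    relative abundances in arbitrary units (peak-area normalised) on the
    raw scale, or real-valued on the log scale after ``log_transform``
    (tracked by ``log_scale``).
    """

    frame: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing metadata column(s): {missing}")
        dupes = self.frame.duplicated(subset=list(METADATA_COLUMNS))
        if dupes.any():
            keys = self.frame.loc[dupes, list(METADATA_COLUMNS)].to_records(index=False)
            raise ValueError(f"duplicate observation keys: {list(keys)[:5]}")
        if len(self.metabolites) != len(set(self.metabolites)):
            raise ValueError("metabolite names must be unique")
        bad = set(self.frame["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition value(s): {sorted(bad)}")
        if not self.log_scale:
            vals = self.values
            if vals.size and np.any(vals <= 0):
                i, j = np.argwhere(vals <= 0)[0]
                raise ValueError(
                    "abundances must be positive; offending cell: "
                    f"row {i}, metabolite {self.metabolites[j]!r}"
                )

    @property
    def metabolites(self) -> list[str]:
        return [c for c in self.frame.columns if c not in METADATA_COLUMNS]

    @property
    def values(self) -> np.ndarray:
        return self.frame[self.metabolites].to_numpy(dtype=float)

    @property
    def n_observations(self) -> int:
        return len(self.frame)

    def subset(
        self,
        genotypes=None,
        condition: str | None = None,
        time_point: int | None = None,
    ) -> "MetaboliteMatrix":
        """Row-filtered copy; raises if the slice is empty."""
        sel = pd.Series(True, index=self.frame.index)
        if genotypes is not None:
            sel &= self.frame["genotype"].isin(set(genotypes))
        if condition is not None:
            sel &= self.frame["condition"] == condition
        if time_point is not None:
            sel &= self.frame["time_point"] == time_point
        sub = self.frame.loc[sel].reset_index(drop=True)
        if sub.empty:
            raise ValueError(
                f"no observations match condition={condition!r}, "
                f"time_point={time_point!r}"
            )
        return MetaboliteMatrix(frame=sub, log_scale=self.log_scale)


@dataclass
class MetabolicNetwork:
    """Directed metabolite network defining allowed Jacobian entries.

    An edge ``source -> target`` permits Jacobian entry (target, source):
    the rate of change of *target* may depend on the level of *source*.
    ``names`` fixes the variable ordering used for all matrices.
    """

    names: list[str]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("node names must be unique")
        known = set(self.names)
        for s, t in self.edges:
            if s not in known or t not in known:
                raise ValueError(f"edge ({s!r}, {t!r}) uses unknown node")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        """Export as a networkx DiGraph (nodes keep the canonical order)."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        g.add_edges_from(self.edges)
        return g
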