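"""Metabolite-to-SSI correlation screen.

Each replicate observation is paired with its genotype's SSI (replicates
inherit the genotype-level phenotype, so a 36-genotype x 3-replicate slice
yields n = 108 pairs), and a simple Pearson correlation of log-transformed
relative abundance against SSI is computed per metabolite, with two-sided
t-based p-values (df = n - 2), Benjamini--Hochberg adjusted q-values, and
the variance explained (r²).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ssi import SSIResult
from .types import MetaboliteMatrix

__all__ = ["log_transform", "correlate_to_ssi"]

_LOG_BASE = {"e": math.e, "10": 10.0, "2": 2.0}


def log_transform(
    matrix: MetaboliteMatrix,
    base: str = "e",
    nonpositive_policy: str = "error",
) -> MetaboliteMatrix:
    """Element-wise logarithm of the abundance columns.

    ``base`` is one of {"e", "10", "2"}; Pearson correlations downstream are
    invariant to the choice. Under ``nonpositive_policy="offset"``, a
    metabolite column containing any nonpositive value is shifted by half
    its smallest positive value before logging; under "error" (default) a
    nonpositive cell raises, naming metabolite and row.
    """
    if str(base) not in _LOG_BASE:
        raise ValueError(f"base must be one of {list(_LOG_BASE)}, got {base!r}")
    if nonpositive_policy not in ("error", "offset"):
        raise ValueError(f"unknown nonpositive_policy: {nonpositive_policy!r}")
    if matrix.log_scale:
        raise ValueError("matrix is already on the log scale")
    b = _LOG_BASE[str(base)]
    frame = matrix.frame.copy()
    for name in matrix.metabolites:
        col = frame[name].to_numpy(dtype=float)
        nonpos = col <= 0
        if np.any(nonpos):
            if nonpositive_policy == "error":
                row = int(np.argwhere(nonpos)[0][0])
                raise ValueError(
                    f"nonpositive abundance for metabolite {name!r} at row {row}"
                )
            positive = col[col > 0]
            if positive.size == 0:
                raise ValueError(
                    f"metabolite {name!r} has no positive values to offset from"
                )
            col = col + positive.min() / 2.0
        frame[name] = np.log(col) / np.log(b)
    return MetaboliteMatrix(frame=frame, log_scale=True)


def correlate_to_ssi(
    matrix: MetaboliteMatrix,
    ssi: SSIResult | pd.Series,
    condition: str | None = "DS",
    time_point: int | None = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite Pearson correlation against SSI on a data slice.

    Parameters
    ----------
    matrix
        Log-scale metabolite matrix.
    ssi
        ``SSIResult`` or a genotype-indexed Series of SSI values.
    condition, time_point
        Analysis slice; the defaults (drought, mid pod-filling harvest)
        are the primary screen. ``None`` disables a filter.
    alpha
        Significance level for the ``significant`` flag (raw p).

    Returns a DataFrame sorted by \\|r\\| descending with columns
    metabolite, n, r, r_squared, t_stat, p, q, significant, flag.
    Zero-variance metabolites are flagged "undefined" and excluded from
    the BH family with a warning.
    """
    if not matrix.log_scale:
        raise ValueError("correlate_to_ssi expects a log-scale matrix")
    ssi_map = ssi.ssi if isinstance(ssi, SSIResult) else ssi
    sub = matrix.subset(condition=condition, time_point=time_point)
    if len(sub.frame) < 3:
        raise ValueError("need at least 3 observations for correlation")
    missing = sorted(set(sub.frame["genotype"]) - set(ssi_map.index))
    if missing:
        raise ValueError(f"no SSI value for genotype(s): {missing}")
    y = sub.frame["genotype"].map(ssi_map).to_numpy(dtype=float)

    rows = []
    for name in sub.metabolites:
        x = sub.frame[name].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        xi, yi = x[ok], y[ok]
        n = xi.size
        if n < 3 or np.std(xi) == 0 or np.std(yi) == 0:
            warnings.warn(
                f"metabolite {name!r} has zero variance or <3 observations; "
                "correlation undefined",
                stacklevel=2,
            )
            rows.append(
                {"metabolite": name, "n": n, "r": np.nan, "r_squared": np.nan,
                 "t_stat": np.nan, "p": np.nan, "flag": "undefined"}
            )
            continue
        r, p = stats.pearsonr(xi, yi)
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) < 1.0:
            t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        else:
            t = math.inf if r > 0 else -math.inf
        rows.append(
            {"metabolite": name, "n": n, "r": r, "r_squared": r * r,
             "t_stat": t, "p": float(p), "flag": "ok"}
        )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok_mask = out["flag"] == "ok"
    if ok_mask.any():
        _, q, _, _ = multipletests(out.loc[ok_mask, "p"], method="fdr_bh")
        out.loc[ok_mask, "q"] = q
    out["significant"] = ok_mask & (out["p"] < alpha)
    out = out.reindex(
        out["r"].abs().sort_values(ascending=False, na_position="last").index
    ).reset_index(drop=True)
    return out[["metabolite", "n", "r", "r_squared", "t_stat", "p", "q",
                "significant", "flag"]]
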