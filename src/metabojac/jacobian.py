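"""Inverse inference of the biochemical Jacobian from metabolite covariance.

Near a metabolic steady state, small stochastic fluctuations of metabolite
concentrations behave like a linear (Ornstein--Uhlenbeck) system whose
stationary covariance ``C`` is tied to the Jacobian ``J`` of the reaction
network and the fluctuation-intensity (noise) matrix ``D`` by the Lyapunov
equation

    J C + C Jᵀ = -2 D.

The forward direction (``J, D -> C``) is a standard matrix equation. The
inverse direction (``C, D -> J``) is the scientific workhorse here: with a
metabolic network supplying a sparsity mask on ``J``, the Lyapunov equation
becomes an (over- or under-determined) linear system in the free Jacobian
entries, solved in the least-squares sense. Because the noise intensities
are not observable, the inversion is repeated for an ensemble of random
diagonal ``D`` draws and the entry-wise median is reported; comparing two
sample groups entry-by-entry on a log-ratio scale yields the differential
Jacobian, a map of which reaction elasticities dominate in which group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .types import MetaboliteMatrix, MetabolicNetwork, METADATA_COLUMNS

__all__ = [
    "CovarianceMatrix",
    "NoiseMatrix",
    "JacobianMask",
    "JacobianSolution",
    "JacobianEstimate",
    "DifferentialJacobian",
    "estimate_covariance",
    "draw_noise_matrix",
    "forward_lyapunov",
    "solve_inverse_jacobian",
    "monte_carlo_jacobian",
    "differential_jacobian",
    "classify_edges",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CovarianceMatrix:
    """Sample covariance of log abundances with variable names attached."""

    names: list[str]
    values: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("covariance must be square")
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names do not match covariance dimension")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class NoiseMatrix:
    """Diagonal fluctuation-intensity matrix D (off-diagonal entries are 0)."""

    diagonal: np.ndarray

    def __post_init__(self) -> None:
        self.diagonal = np.atleast_1d(np.asarray(self.diagonal, dtype=float))

    @property
    def n(self) -> int:
        return self.diagonal.shape[0]

    def full(self) -> np.ndarray:
        return np.diag(self.diagonal)


@dataclass
class JacobianMask:
    """Boolean matrix of structurally allowed Jacobian entries.

    Entry ``(i, j)`` is allowed when metabolite ``j`` appears in the rate
    law of a reaction consuming/producing metabolite ``i`` — i.e. the
    network has a directed edge ``j -> i`` — or on the diagonal, which is
    always free (every metabolite's own degradation/turnover).
    """

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("mask shape does not match names")
        # the diagonal is always structurally free
        np.fill_diagonal(self.values, True)

    @classmethod
    def from_network(cls, network: MetabolicNetwork) -> "JacobianMask":
        n = len(network.names)
        index = {name: i for i, name in enumerate(network.names)}
        values = np.eye(n, dtype=bool)
        for source, target in network.edges:
            values[index[target], index[source]] = True
        return cls(names=list(network.names), values=values)

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def n_free(self) -> int:
        return int(self.values.sum())


@dataclass
class JacobianSolution:
    """Single inverse-Lyapunov solve: masked J plus diagnostics."""

    J: np.ndarray
    residual_norm: float
    rank_deficiency: int
    names: list[str] = field(default_factory=list)


@dataclass
class JacobianEstimate:
    """Entry-wise median / IQR of J over a Monte-Carlo noise ensemble."""

    median: np.ndarray
    iqr: np.ndarray
    mask: JacobianMask
    n_iter: int
    seed: int
    residual_norms: np.ndarray = field(default_factory=lambda: np.array([]))
    rank_deficiency: int = 0

    @property
    def names(self) -> list[str]:
        return self.mask.names


@dataclass
class DifferentialJacobian:
    """Entry-wise log-ratio of two group Jacobians on a shared mask.

    ``dJ[i, j] = ln(|J1[i, j]| / |J2[i, j]|)`` for masked, well-defined
    entries; NaN elsewhere. ``sign_concordant`` records whether the two
    groups agree on the sign of the elasticity (the log-ratio of the raw
    signed entries is undefined otherwise), and ``mode`` is "activating"
    (shared sign > 0) or "inhibiting" (< 0) where concordant.
    """

    mask: JacobianMask
    dJ: np.ndarray
    sign_concordant: np.ndarray
    defined: np.ndarray
    mode: np.ndarray  # object array of {"activating","inhibiting",None}

    @property
    def names(self) -> list[str]:
        return self.mask.names


# ---------------------------------------------------------------------------
# covariance estimation
# ---------------------------------------------------------------------------

def estimate_covariance(
    matrix: MetaboliteMatrix | pd.DataFrame,
    genotypes: Sequence[str] | None = None,
    condition: str | None = None,
    time_point: int | None = None,
    metabolites: Sequence[str] | None = None,
) -> CovarianceMatrix:
    """Unbiased sample covariance of log abundances for a group slice.

    Parameters
    ----------
    matrix
        Log-scale metabolite matrix (observations x metabolites with the
        standard metadata columns).
    genotypes
        Genotype identifiers defining the group (e.g. the Q1 set); ``None``
        keeps all genotypes.
    condition, time_point
        Optional slice filters (e.g. ``"DS"``, ``2``).
    metabolites
        Optional subset of metabolite columns (e.g. the knowns + level-2
        identifications); default all columns.

    Every genotype x replicate observation in the slice enters the pooled
    covariance with ``n - 1`` normalisation. Metabolites with missing
    values in the slice are dropped with a warning.
    """
    df = matrix.frame if isinstance(matrix, MetaboliteMatrix) else matrix
    sel = pd.Series(True, index=df.index)
    if genotypes is not None:
        sel &= df["genotype"].isin(set(genotypes))
    if condition is not None:
        sel &= df["condition"] == condition
    if time_point is not None:
        sel &= df["time_point"] == time_point
    sub = df.loc[sel]
    if len(sub) < 2:
        raise ValueError(
            f"need at least 2 observations for covariance, got {len(sub)}"
        )
    cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    if metabolites is not None:
        missing = [m for m in metabolites if m not in cols]
        if missing:
            raise KeyError(f"metabolites not in matrix: {missing}")
        cols = list(metabolites)
    values = sub[cols]
    with_na = [c for c in cols if values[c].isna().any()]
    if with_na:
        warnings.warn(
            f"excluding {len(with_na)} metabolite(s) with missing values: "
            f"{with_na}",
            stacklevel=2,
        )
        cols = [c for c in cols if c not in with_na]
        values = values[cols]
    X = values.to_numpy(dtype=float)
    C = np.cov(X, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    C = (C + C.T) / 2.0
    return CovarianceMatrix(names=cols, values=C, n_samples=X.shape[0])


# ---------------------------------------------------------------------------
# noise draws
# ---------------------------------------------------------------------------

def draw_noise_matrix(
    n: int,
    rng: np.random.Generator,
    mode: str = "halfnormal",
) -> NoiseMatrix:
    """Draw a random diagonal noise matrix.

    ``mode="halfnormal"`` (default) takes absolute values of standard-normal
    draws, so every intensity is non-negative (mean sqrt(2/pi) ~ 0.798);
    ``mode="normal"`` keeps the raw signed draws for literal replication of
    the signed-normal convention.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    z = rng.standard_normal(n)
    if mode == "halfnormal":
        z = np.abs(z)
    elif mode != "normal":
        raise ValueError(f"unknown noise mode: {mode!r}")
    return NoiseMatrix(diagonal=z)


# ---------------------------------------------------------------------------
# forward Lyapunov (simulator backbone and test oracle)
# ---------------------------------------------------------------------------

def forward_lyapunov(J: np.ndarray, D: NoiseMatrix | np.ndarray) -> np.ndarray:
    """Stationary covariance C solving J C + C Jᵀ = -2 D for Hurwitz J."""
    J = np.atleast_2d(np.asarray(J, dtype=float))
    diag = D.diagonal if isinstance(D, NoiseMatrix) else np.diag(np.atleast_2d(D))
    if J.shape[0] != J.shape[1] or J.shape[0] != diag.shape[0]:
        raise ValueError("J and D dimensions do not agree")
    eig = np.linalg.eigvals(J)
    if np.max(eig.real) >= 0:
        raise ValueError("no stationary covariance: J is not Hurwitz")
    C = scipy.linalg.solve_continuous_lyapunov(J, -2.0 * np.diag(diag))
    return (C + C.T) / 2.0


# ---------------------------------------------------------------------------
# inverse solve
# ---------------------------------------------------------------------------

def _build_system(C: np.ndarray, mask: np.ndarray):
    """Assemble the masked Lyapunov least-squares system.

    One equation per unordered index pair (p, q), p <= q:

        sum_k J[p,k] C[k,q] + sum_k J[q,k] C[k,p] = -2 D[p,q]

    in the m free entries of J. Off-diagonal equations are weighted by
    sqrt(2) so the least-squares objective equals the Frobenius norm of the
    symmetric residual J C + C Jᵀ + 2 D (whose off-diagonal entries occur
    twice). Returns (A, free_idx, pair_rows) where ``pair_rows[(p, q)]`` is
    the equation row index and ``free_idx`` the (i, j) coordinates of the
    unknowns in column order.
    """
    n = C.shape[0]
    free_idx = np.argwhere(mask)
    m = free_idx.shape[0]
    pair_rows = {}
    r = 0
    for p in range(n):
        for q in range(p, n):
            pair_rows[(p, q)] = r
            r += 1
    A = np.zeros((r, m))
    for col, (i, j) in enumerate(free_idx):
        # unknown J[i, j] appears in every equation involving row i;
        # in the diagonal equation (i, i) both Lyapunov terms contribute,
        # doubling the coefficient
        for q in range(n):
            p, qq = (i, q) if i <= q else (q, i)
            coeff = 2.0 * C[j, q] if q == i else np.sqrt(2.0) * C[j, q]
            A[pair_rows[(p, qq)], col] += coeff
    return A, free_idx, pair_rows


def solve_inverse_jacobian(
    C: CovarianceMatrix | np.ndarray,
    D: NoiseMatrix,
    mask: JacobianMask | np.ndarray,
    rcond: float | None = None,
) -> JacobianSolution:
    """Least-squares solve of J C + C Jᵀ = -2 D for the masked Jacobian.

    Rank-deficient systems (the common case when the number of observations
    is below the number of metabolites) get the minimum-norm solution.
    ``residual_norm`` is the Frobenius norm of J C + C Jᵀ + 2 D and
    ``rank_deficiency`` the number of unresolved degrees of freedom.
    """
    names = C.names if isinstance(C, CovarianceMatrix) else None
    Cv = C.values if isinstance(C, CovarianceMatrix) else np.atleast_2d(np.asarray(C, float))
    Mv = mask.values if isinstance(mask, JacobianMask) else np.asarray(mask, bool)
    n = Cv.shape[0]
    if Mv.shape != (n, n) or D.n != n:
        raise ValueError("C, D and mask dimensions do not agree")
    if not Mv.diagonal().all():
        raise ValueError("mask diagonal must be free")
    if not np.any(Cv):
        raise ValueError("degenerate covariance: all entries zero")

    A, free_idx, pair_rows = _build_system(Cv, Mv)
    b = np.zeros(A.shape[0])
    for i in range(n):
        b[pair_rows[(i, i)]] = -2.0 * D.diagonal[i]
    sol, _, rank, _ = scipy.linalg.lstsq(A, b, cond=rcond, lapack_driver="gelsd")
    J = np.zeros((n, n))
    J[free_idx[:, 0], free_idx[:, 1]] = sol
    residual = np.linalg.norm(J @ Cv + Cv @ J.T + 2.0 * D.full(), ord="fro")
    return JacobianSolution(
        J=J,
        residual_norm=float(residual),
        rank_deficiency=int(free_idx.shape[0] - rank),
        names=list(names) if names is not None else [f"x{i+1}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# Monte-Carlo ensemble
# ---------------------------------------------------------------------------

def monte_carlo_jacobian(
    C: CovarianceMatrix | np.ndarray,
    mask: JacobianMask | np.ndarray,
    n_iter: int = 10_000,
    seed: int = 0,
    noise: str = "halfnormal",
) -> JacobianEstimate:
    """Entry-wise median Jacobian over an ensemble of random noise matrices.

    Each iteration draws a fresh diagonal ``D`` and solves the masked
    inverse Lyapunov problem; the per-entry median and interquartile range
    over iterations are returned. The solve is linear in ``D``, so the
    pseudoinverse of the (fixed) coefficient matrix is computed once and
    each draw reduces to a matrix-vector product — numerically identical
    to per-draw least squares.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    names = C.names if isinstance(C, CovarianceMatrix) else None
    Cv = C.values if isinstance(C, CovarianceMatrix) else np.atleast_2d(np.asarray(C, float))
    if not isinstance(mask, JacobianMask):
        mask = JacobianMask(
            names=list(names) if names is not None
            else [f"x{i+1}" for i in range(Cv.shape[0])],
            values=np.asarray(mask, bool),
        )
    n = Cv.shape[0]
    if mask.n != n:
        raise ValueError("mask dimension does not match covariance")
    if not np.any(Cv):
        raise ValueError("degenerate covariance: all entries zero")

    A, free_idx, pair_rows = _build_system(Cv, mask.values)
    P = scipy.linalg.pinv(A)  # (m x n_eq) minimum-norm least-squares operator
    rank = np.linalg.matrix_rank(A)
    diag_rows = np.array([pair_rows[(i, i)] for i in range(n)])
    # solution for a diagonal draw d: P @ b with b = -2 d on the diagonal rows
    solver = -2.0 * P[:, diag_rows]  # (m x n)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_iter, n))
    if noise == "halfnormal":
        z = np.abs(z)
    elif noise != "normal":
        raise ValueError(f"unknown noise mode: {noise!r}")
    samples = z @ solver.T  # (n_iter x m)

    med = np.median(samples, axis=0)
    q75, q25 = np.percentile(samples, [75, 25], axis=0)
    median = np.zeros((n, n))
    iqr = np.zeros((n, n))
    median[free_idx[:, 0], free_idx[:, 1]] = med
    iqr[free_idx[:, 0], free_idx[:, 1]] = q75 - q25

    # residuals per draw (diagnostic): ||J C + C Jᵀ + 2 D||_F via the system
    b_all = np.zeros((n_iter, A.shape[0]))
    b_all[:, diag_rows] = -2.0 * z
    resid = np.linalg.norm(samples @ A.T - b_all, axis=1)
    return JacobianEstimate(
        median=median,
        iqr=iqr,
        mask=mask,
        n_iter=n_iter,
        seed=seed,
        residual_norms=resid,
        rank_deficiency=int(free_idx.shape[0] - rank),
    )


# ---------------------------------------------------------------------------
# differential Jacobian and edge report
# ---------------------------------------------------------------------------

def differential_jacobian(
    J1: JacobianEstimate,
    J2: JacobianEstimate,
    epsilon_factor: float = 1e-9,
) -> DifferentialJacobian:
    """Entry-wise log-ratio dJ = ln(|J1| / |J2|) on the shared mask.

    Entries whose magnitude (in either group) falls below
    ``epsilon_factor x median(|masked entries|)`` are flagged undefined
    rather than producing infinities. Positive dJ means the group-1
    elasticity dominates; swapping the groups negates every entry.
    """
    if J1.mask.names != J2.mask.names or not np.array_equal(
        J1.mask.values, J2.mask.values
    ):
        raise ValueError("differential requires identical masks and ordering")
    mask = J1.mask
    mv = mask.values
    a = J1.median
    b = J2.median
    pooled = np.abs(np.concatenate([a[mv], b[mv]]))
    scale = np.median(pooled[pooled > 0]) if np.any(pooled > 0) else 1.0
    eps = epsilon_factor * scale
    defined = mv & (np.abs(a) > eps) & (np.abs(b) > eps)
    dJ = np.full(a.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        dJ[defined] = np.log(np.abs(a[defined]) / np.abs(b[defined]))
    concord = defined & (np.sign(a) == np.sign(b))
    mode = np.full(a.shape, None, dtype=object)
    mode[concord & (a > 0)] = "activating"
    mode[concord & (a < 0)] = "inhibiting"
    return DifferentialJacobian(
        mask=mask, dJ=dJ, sign_concordant=concord, defined=defined, mode=mode
    )


def classify_edges(
    diff: DifferentialJacobian,
    threshold: float = 0.0,
    group_labels: tuple[str, str] = ("group1", "group2"),
) -> pd.DataFrame:
    """Tidy table of masked entries with |dJ| >= threshold.

    Columns: source, target, dJ, dominant_group, mode, sign_concordant —
    the data behind a circular differential-flux plot. Sorted by |dJ|
    descending; ``source -> target`` follows the network edge direction
    (entry (i, j) of J is the elasticity of target i w.r.t. source j).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    names = diff.names
    rows = []
    for i, j in np.argwhere(diff.defined):
        v = diff.dJ[i, j]
        if abs(v) < threshold:
            continue
        rows.append(
            {
                "source": names[j],
                "target": names[i],
                "dJ": v,
                "dominant_group": group_labels[0] if v > 0 else group_labels[1],
                "mode": diff.mode[i, j],
                "sign_concordant": bool(diff.sign_concordant[i, j]),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["source", "target", "dJ", "dominant_group", "mode",
                 "sign_concordant"],
    )
    if len(out):
        out = out.reindex(
            out["dJ"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    return out
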