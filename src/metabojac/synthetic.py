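"""Synthetic data with known ground truth for every pipeline stage.

Three generators mirror the structure of the field study the pipeline is
designed for (a 36-genotype, 3-replicate, 2-condition, 3-harvest panel):

* ``make_toy_network`` builds a directed toy metabolic network together
  with a stable (Hurwitz) ground-truth Jacobian, diagonal noise matrix and
  the exact stationary covariance they imply, so inverse inference can be
  scored against a known answer.
* ``simulate_abundances`` draws stationary log-normal abundance samples
  whose log-scale covariance is exactly the system's ``C_true``.
* ``generate_yield_panel`` plants tolerant / susceptible genotype classes
  with distinct relative yield losses; ``generate_ssi_correlated_metabolome``
  plants a metabolite column with a chosen correlation to SSI.

All generators are deterministic in their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .jacobian import NoiseMatrix, forward_lyapunov
from .types import MetaboliteMatrix, MetabolicNetwork

__all__ = [
    "GroundTruthSystem",
    "PanelSpec",
    "make_toy_network",
    "simulate_abundances",
    "generate_yield_panel",
    "generate_ssi_correlated_metabolome",
]


@dataclass
class GroundTruthSystem:
    """A stable linear system and its exact stationary covariance.

    Invariants: ``J_true`` is Hurwitz and zero off the network mask (plus
    diagonal); ``C_true`` is symmetric positive definite and satisfies
    ``J_true C_true + C_true J_trueᵀ = -2 D_true``.
    """

    network: MetabolicNetwork
    J_true: np.ndarray
    D_true: NoiseMatrix
    C_true: np.ndarray

    @property
    def n(self) -> int:
        return self.network.n


@dataclass
class PanelSpec:
    """Design of a synthetic genotype yield panel.

    ``loss_tolerant`` / ``loss_susceptible`` are the mean relative
    100-seed-weight losses under drought for the two planted classes;
    ``cv_noise`` is the coefficient of variation of multiplicative
    genotype-level noise on the stressed yield.
    """

    n_genotypes: int = 36
    n_replicates: int = 3
    tolerant_fraction: float = 0.5
    loss_tolerant: float = 0.1
    loss_susceptible: float = 0.5
    cv_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.loss_tolerant < 1 and 0 <= self.loss_susceptible < 1):
            raise ValueError("losses must be in [0, 1)")
        if self.loss_tolerant >= self.loss_susceptible:
            raise ValueError("loss_tolerant must be < loss_susceptible")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 <= self.tolerant_fraction <= 1:
            raise ValueError("tolerant_fraction must be in [0, 1]")
        if self.n_genotypes < 1:
            raise ValueError("n_genotypes must be >= 1")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be >= 0")


def _topology_edges(
    n: int, topology: str, edge_prob: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    if topology == "chain":
        return [(i, i + 1) for i in range(n - 1)]
    if topology == "ring":
        if n == 1:
            return []
        return [(i, (i + 1) % n) for i in range(n)]
    if topology == "random":
        edges = []
        for i in range(n):
            for j in range(n):
                if i != j and rng.random() < edge_prob:
                    edges.append((i, j))
        return edges
    raise ValueError(f"unknown topology: {topology!r}")


def make_toy_network(
    n_nodes: int,
    topology: str = "chain",
    edge_prob: float = 0.3,
    seed: int = 0,
) -> GroundTruthSystem:
    """Toy network M1..Mn with a diagonally dominant (hence Hurwitz) Jacobian.

    Off-diagonal entries are drawn on the network's edges with random sign
    and magnitude in [0.2, 1.0]; each diagonal entry is set negative with
    magnitude exceeding its row's off-diagonal absolute sum (Gershgorin
    dominance guarantees all eigenvalues have negative real part). Noise
    intensities are drawn in [0.5, 1.5] and ``C_true`` is the exact forward
    Lyapunov solution.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"M{i+1}" for i in range(n_nodes)]
    idx_edges = _topology_edges(n_nodes, topology, edge_prob, rng)
    edges = [(names[s], names[t]) for s, t in idx_edges]
    network = MetabolicNetwork(names=names, edges=edges)

    J = np.zeros((n_nodes, n_nodes))
    for s, t in idx_edges:
        magnitude = rng.uniform(0.2, 1.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        J[t, s] = sign * magnitude
    row_sums = np.sum(np.abs(J), axis=1)
    for i in range(n_nodes):
        J[i, i] = -(row_sums[i] + rng.uniform(0.5, 1.5))
    D = NoiseMatrix(diagonal=rng.uniform(0.5, 1.5, size=n_nodes))
    C = forward_lyapunov(J, D)
    return GroundTruthSystem(network=network, J_true=J, D_true=D, C_true=C)


def simulate_abundances(
    system: GroundTruthSystem,
    n_samples: int,
    seed: int = 0,
    condition: str = "DS",
    time_point: int = 2,
    genotype: str = "SYN",
) -> MetaboliteMatrix:
    """Stationary abundance samples whose log-covariance is ``C_true``.

    Samples are drawn from the zero-mean multivariate normal with
    covariance ``C_true`` and exponentiated element-wise, so the pipeline's
    log transform recovers the Gaussian layer exactly. Metadata rows carry
    a single synthetic genotype with the replicate index counting samples.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    try:
        L = np.linalg.cholesky(system.C_true)
    except np.linalg.LinAlgError as exc:
        raise ValueError("unstable system: C_true not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, system.n))
    logs = z @ L.T
    frame = pd.DataFrame(np.exp(logs), columns=system.network.names)
    frame.insert(0, "time_point", time_point)
    frame.insert(0, "condition", condition)
    frame.insert(0, "replicate", np.arange(1, n_samples + 1))
    frame.insert(0, "genotype", genotype)
    return MetaboliteMatrix(frame=frame)


def generate_yield_panel(spec: PanelSpec) -> pd.DataFrame:
    """Yield panel with planted tolerant / susceptible classes.

    Baseline 100-seed weight Yp ~ Normal(25 g, 4 g) truncated at 5 g;
    Ys = Yp * (1 - class loss) * lognormal multiplicative noise with
    coefficient of variation ``cv_noise`` (exactly 1 when cv_noise = 0).
    Returns columns genotype, Yp, Ys, true_class for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genotypes
    n_tol = int(round(spec.tolerant_fraction * n))
    if n_tol == 0 or n_tol == n:
        warnings.warn(
            "tolerant_fraction rounds to an empty class; proceeding",
            stacklevel=2,
        )
    labels = np.array(
        ["tolerant"] * n_tol + ["susceptible"] * (n - n_tol), dtype=object
    )
    rng.shuffle(labels)
    yp = np.maximum(rng.normal(25.0, 4.0, size=n), 5.0)
    loss = np.where(labels == "tolerant", spec.loss_tolerant, spec.loss_susceptible)
    if spec.cv_noise > 0:
        sigma = np.sqrt(np.log1p(spec.cv_noise**2))
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)
    else:
        noise = np.ones(n)
    ys = yp * (1.0 - loss) * noise
    return pd.DataFrame(
        {
            "genotype": [f"G{i+1}" for i in range(n)],
            "Yp": yp,
            "Ys": ys,
            "true_class": labels,
        }
    )


def generate_ssi_correlated_metabolome(
    ssi: pd.Series,
    rho: float,
    n_replicates: int = 3,
    seed: int = 0,
    n_filler: int = 0,
    metabolite_name: str = "planted_metabolite",
    condition: str = "DS",
    time_point: int = 2,
) -> MetaboliteMatrix:
    """Metabolome whose planted column correlates with SSI at level ``rho``.

    Per observation (genotype g, replicate r) the planted log-value is
    ``rho * z_g + sqrt(1 - rho²) * eps`` where ``z_g`` is the genotype's
    standardized SSI (replicates inherit their genotype's phenotype) and
    eps is independent standard normal; values are exponentiated to the
    abundance scale. ``n_filler`` adds uncorrelated log-normal metabolites.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    if len(ssi) < 3:
        raise ValueError("need at least 3 genotypes")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    sd = float(np.std(ssi.to_numpy(dtype=float)))
    if sd == 0:
        raise ValueError("degenerate phenotype: SSI is constant")
    z = (ssi - ssi.mean()) / sd

    rng = np.random.default_rng(seed)
    rows = []
    for genotype, zg in z.items():
        for rep in range(1, n_replicates + 1):
            rows.append((genotype, rep, condition, time_point, zg))
    frame = pd.DataFrame(
        rows, columns=["genotype", "replicate", "condition", "time_point", "_z"]
    )
    n_obs = len(frame)
    eps = rng.standard_normal(n_obs)
    logval = rho * frame.pop("_z").to_numpy() + np.sqrt(1.0 - rho**2) * eps
    frame[metabolite_name] = np.exp(logval)
    for k in range(n_filler):
        frame[f"filler_{k+1}"] = np.exp(rng.standard_normal(n_obs))
    return MetaboliteMatrix(frame=frame)
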