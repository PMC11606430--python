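import numpy as np
import pandas as pd
import pytest

import metabojac as mj


@pytest.fixture
def toy_yield_table() -> pd.DataFrame:
    """Three-genotype panel with hand-checkable SSI values."""
    return pd.DataFrame(
        {"genotype": ["A", "B", "C"], "Yp": [20.0, 30.0, 50.0],
         "Ys": [10.0, 27.0, 40.0]}
    )


@pytest.fixture
def chain_system() -> mj.GroundTruthSystem:
    return mj.make_toy_network(4, topology="chain", seed=42)


@pytest.fixture
def panel_matrix():
    """36-genotype x 3-replicate synthetic study: yields + abundances.

    Observations are drawn per genotype from a shared stationary system so
    genotype group slices exist for covariance estimation.
    """
    panel = mj.generate_yield_panel(mj.PanelSpec(n_genotypes=36, seed=7))
    system = mj.make_toy_network(12, topology="random", edge_prob=0.08, seed=7)
    frames = []
    for gi, g in enumerate(panel["genotype"]):
        m = mj.simulate_abundances(system, n_samples=3, seed=7000 + gi, genotype=g)
        frames.append(m.frame)
    matrix = mj.MetaboliteMatrix(frame=pd.concat(frames, ignore_index=True))
    return panel, system, matrix


def hand_covariance(X: np.ndarray) -> np.ndarray:
    """Textbook two-pass sample covariance (oracle, n-1 normalisation)."""
    n, p = X.shape
    xbar = X.mean(axis=0)
    out = np.zeros((p, p))
    for a in range(p):
        for b in range(p):
            out[a, b] = np.sum((X[:, a] - xbar[a]) * (X[:, b] - xbar[b])) / (n - 1)
    return out
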