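"""Lyapunov forward/inverse solves, Monte-Carlo ensemble, differential J."""

import numpy as np
import pandas as pd
import pytest

import metabojac as mj
from metabojac.jacobian import (
    CovarianceMatrix,
    JacobianMask,
    NoiseMatrix,
    draw_noise_matrix,
    forward_lyapunov,
    solve_inverse_jacobian,
)

from conftest import hand_covariance


def _full_mask(n):
    return JacobianMask(names=[f"x{i+1}" for i in range(n)],
                        values=np.ones((n, n), dtype=bool))


class TestForwardLyapunov:
    def test_identity_system(self):
        C = forward_lyapunov(-np.eye(3), NoiseMatrix(np.ones(3)))
        np.testing.assert_allclose(C, np.eye(3), atol=1e-12)

    def test_decoupled_diagonal_closed_form(self):
        a = np.array([1.0, 2.5, 0.7])
        d = np.array([0.3, 1.1, 2.0])
        C = forward_lyapunov(-np.diag(a), NoiseMatrix(d))
        np.testing.assert_allclose(C, np.diag(d / a), atol=1e-12)

    def test_two_by_two_against_hand_assembled_system(self):
        """Oracle: the 3-equation linear system in (c11, c12, c22)."""
        J = np.array([[-2.0, 0.5], [-0.3, -1.5]])
        d = np.array([1.2, 0.8])
        # equations: row (p,q) of J C + C J^T = -2 D expanded by hand
        A = np.array(
            [
                [2 * J[0, 0], 2 * J[0, 1], 0.0],          # (0,0)
                [J[1, 0], J[0, 0] + J[1, 1], J[0, 1]],    # (0,1)
                [0.0, 2 * J[1, 0], 2 * J[1, 1]],          # (1,1)
            ]
        )
        b = np.array([-2 * d[0], 0.0, -2 * d[1]])
        c11, c12, c22 = np.linalg.solve(A, b)
        expected = np.array([[c11, c12], [c12, c22]])
        np.testing.assert_allclose(
            forward_lyapunov(J, NoiseMatrix(d)), expected, atol=1e-12
        )

    def test_non_hurwitz_rejected(self):
        with pytest.raises(ValueError, match="no stationary covariance"):
            forward_lyapunov(np.array([[1.0]]), NoiseMatrix([1.0]))


class TestNoiseMatrix:
    def test_off_diagonal_zero_and_reproducible(self):
        d1 = draw_noise_matrix(5, np.random.default_rng(3))
        d2 = draw_noise_matrix(5, np.random.default_rng(3))
        full = d1.full()
        assert np.all(full[~np.eye(5, dtype=bool)] == 0)
        np.testing.assert_array_equal(d1.diagonal, d2.diagonal)
        assert np.all(d1.diagonal >= 0)

    def test_halfnormal_mean(self):
        rng = np.random.default_rng(0)
        draws = np.concatenate(
            [draw_noise_matrix(100, rng).diagonal for _ in range(1000)]
        )
        assert np.mean(draws) == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    def test_signed_mode_keeps_negatives(self):
        rng = np.random.default_rng(1)
        d = draw_noise_matrix(1000, rng, mode="normal")
        assert (d.diagonal < 0).any()


class TestInverseSolve:
    def test_one_dimensional(self):
        sol = solve_inverse_jacobian(np.array([[0.5]]), NoiseMatrix([1.0]),
                                     np.array([[True]]))
        np.testing.assert_allclose(sol.J, [[-2.0]], atol=1e-12)
        assert sol.residual_norm < 1e-12

    def test_identity_covariance_full_mask(self):
        """C = I, D = I: minimum-norm picks the symmetric solution J = -I."""
        n = 4
        sol = solve_inverse_jacobian(np.eye(n), NoiseMatrix(np.ones(n)),
                                     np.ones((n, n), dtype=bool))
        np.testing.assert_allclose(sol.J, -np.eye(n), atol=1e-10)

    @pytest.mark.parametrize(
        "topology,n",
        [("chain", n) for n in (2, 3, 5, 8, 10)]
        # a 2-ring has a full mask (4 unknowns, 3 equations): unidentifiable
        + [("ring", n) for n in (3, 5, 8, 10)],
    )
    def test_round_trip_recovers_planted_jacobian(self, topology, n):
        system = mj.make_toy_network(n, topology=topology, seed=n * 13 + 1)
        mask = JacobianMask.from_network(system.network)
        C = CovarianceMatrix(system.network.names, system.C_true, 0)
        sol = solve_inverse_jacobian(C, system.D_true, mask)
        scale = np.max(np.abs(system.J_true))
        assert np.max(np.abs(sol.J - system.J_true)) / scale < 1e-8
        assert np.all(sol.J[~mask.values] == 0)

    def test_residual_local_optimality(self):
        """No single-entry perturbation of J decreases the residual."""
        system = mj.make_toy_network(5, topology="random", edge_prob=0.4, seed=5)
        mask = JacobianMask.from_network(system.network)
        C = system.C_true
        D = NoiseMatrix(np.full(5, 0.9))
        sol = solve_inverse_jacobian(
            CovarianceMatrix(system.network.names, C, 0), D, mask
        )
        rng = np.random.default_rng(0)

        def resid(J):
            return np.linalg.norm(J @ C + C @ J.T + 2 * D.full(), "fro")

        base = resid(sol.J)
        for i, j in np.argwhere(mask.values):
            for _ in range(3):
                J2 = sol.J.copy()
                J2[i, j] += rng.normal(scale=1e-3)
                assert resid(J2) >= base - 1e-12

    def test_degenerate_covariance_rejected(self):
        with pytest.raises(ValueError, match="degenerate covariance"):
            solve_inverse_jacobian(np.zeros((2, 2)), NoiseMatrix([1.0, 1.0]),
                                   np.ones((2, 2), dtype=bool))

    def test_rank_deficiency_surfaced(self):
        """A rank-1 covariance cannot pin down a full mask."""
        v = np.array([[1.0], [2.0]])
        C = v @ v.T
        sol = solve_inverse_jacobian(C, NoiseMatrix([1.0, 1.0]),
                                     np.ones((2, 2), dtype=bool))
        assert sol.rank_deficiency > 0


class TestCovarianceEstimation:
    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(3, 4))
        frame = pd.DataFrame(X, columns=[f"m{i}" for i in range(4)])
        frame.insert(0, "time_point", 2)
        frame.insert(0, "condition", "DS")
        frame.insert(0, "replicate", [1, 2, 3])
        frame.insert(0, "genotype", "G1")
        C = mj.estimate_covariance(frame)
        np.testing.assert_allclose(C.values, hand_covariance(X), atol=1e-12)
        assert C.n_samples == 3

    def test_duplicated_column_gives_rank_one_block(self):
        frame = pd.DataFrame({"genotype": "G1", "replicate": [1, 2, 3],
                              "condition": "DS", "time_point": 2,
                              "a": [1.0, 2.0, 4.0], "b": [1.0, 2.0, 4.0]})
        C = mj.estimate_covariance(frame)
        assert len(set(np.round(C.values.ravel(), 12))) == 1

    def test_simulated_slice_approaches_truth(self):
        system = mj.make_toy_network(5, topology="ring", seed=9)
        m = mj.simulate_abundances(system, n_samples=100_000, seed=1)
        logs = np.log(m.values)
        frame = m.frame.copy()
        frame[m.metabolites] = logs
        C = mj.estimate_covariance(frame)
        rel = np.abs(C.values - system.C_true) / np.max(np.abs(system.C_true))
        assert np.max(rel) < 0.05

    def test_too_few_observations_rejected(self):
        frame = pd.DataFrame({"genotype": ["G1"], "replicate": [1],
                              "condition": ["DS"], "time_point": [2],
                              "a": [1.0]})
        with pytest.raises(ValueError, match="at least 2"):
            mj.estimate_covariance(frame)

    def test_missing_values_excluded_with_warning(self):
        frame = pd.DataFrame({"genotype": "G1", "replicate": [1, 2, 3],
                              "condition": "DS", "time_point": 2,
                              "a": [1.0, 2.0, 3.0],
                              "b": [1.0, np.nan, 3.0]})
        with pytest.warns(UserWarning, match="missing"):
            C = mj.estimate_covariance(frame)
        assert C.names == ["a"]


class TestMonteCarlo:
    def test_single_iteration_equals_direct_solve(self, chain_system):
        mask = JacobianMask.from_network(chain_system.network)
        C = CovarianceMatrix(chain_system.network.names, chain_system.C_true, 0)
        est = mj.monte_carlo_jacobian(C, mask, n_iter=1, seed=17)
        D = draw_noise_matrix(chain_system.n, np.random.default_rng(17))
        sol = solve_inverse_jacobian(C, D, mask)
        np.testing.assert_allclose(est.median, sol.J, atol=1e-9)

    def test_seeded_determinism(self, chain_system):
        mask = JacobianMask.from_network(chain_system.network)
        C = CovarianceMatrix(chain_system.network.names, chain_system.C_true, 0)
        e1 = mj.monte_carlo_jacobian(C, mask, n_iter=300, seed=5)
        e2 = mj.monte_carlo_jacobian(C, mask, n_iter=300, seed=5)
        np.testing.assert_array_equal(e1.median, e2.median)
        np.testing.assert_array_equal(e1.iqr, e2.iqr)

    def test_scale_equivariance(self, chain_system):
        """C -> alpha C scales the median Jacobian by 1/alpha at fixed seed."""
        mask = JacobianMask.from_network(chain_system.network)
        names = chain_system.network.names
        alpha = 2.7
        e1 = mj.monte_carlo_jacobian(
            CovarianceMatrix(names, chain_system.C_true, 0), mask,
            n_iter=200, seed=4)
        e2 = mj.monte_carlo_jacobian(
            CovarianceMatrix(names, alpha * chain_system.C_true, 0), mask,
            n_iter=200, seed=4)
        np.testing.assert_allclose(e2.median, e1.median / alpha, atol=1e-10)

    def test_iqr_nonnegative_and_masked(self, chain_system):
        mask = JacobianMask.from_network(chain_system.network)
        C = CovarianceMatrix(chain_system.network.names, chain_system.C_true, 0)
        est = mj.monte_carlo_jacobian(C, mask, n_iter=100, seed=0)
        assert np.all(est.iqr >= 0)
        assert np.all(est.median[~mask.values] == 0)


class TestDifferentialJacobian:
    def _estimate(self, median, mask):
        return mj.JacobianEstimate(median=median, iqr=np.zeros_like(median),
                                   mask=mask, n_iter=1, seed=0)

    def test_identical_groups_give_zero(self):
        mask = _full_mask(3)
        J = np.array([[-1.0, 0.5, 0.0], [0.2, -2.0, 0.1], [0.0, -0.3, -1.5]])
        diff = mj.differential_jacobian(self._estimate(J, mask),
                                        self._estimate(J.copy(), mask))
        np.testing.assert_allclose(diff.dJ[diff.defined], 0.0, atol=1e-12)
        assert diff.sign_concordant[diff.defined].all()

    def test_hand_value_and_dominance(self):
        mask = _full_mask(1)
        diff = mj.differential_jacobian(
            self._estimate(np.array([[2.0]]), mask),
            self._estimate(np.array([[1.0]]), mask))
        assert diff.dJ[0, 0] == pytest.approx(np.log(2.0))
        edges = mj.classify_edges(diff)
        assert edges.loc[0, "dominant_group"] == "group1"

    def test_antisymmetry(self):
        mask = _full_mask(2)
        rng = np.random.default_rng(8)
        A = rng.normal(size=(2, 2))
        B = rng.normal(size=(2, 2))
        d1 = mj.differential_jacobian(self._estimate(A, mask),
                                      self._estimate(B, mask))
        d2 = mj.differential_jacobian(self._estimate(B, mask),
                                      self._estimate(A, mask))
        np.testing.assert_allclose(d1.dJ[d1.defined], -d2.dJ[d2.defined],
                                   atol=1e-12)

    def test_sign_discordance_flagged_not_logged(self):
        mask = _full_mask(1)
        diff = mj.differential_jacobian(
            self._estimate(np.array([[2.0]]), mask),
            self._estimate(np.array([[-1.0]]), mask))
        assert not diff.sign_concordant[0, 0]
        assert diff.mode[0, 0] is None
        assert np.isfinite(diff.dJ[0, 0])  # magnitude ratio still defined

    def test_near_zero_denominator_flagged_undefined(self):
        mask = _full_mask(1)
        diff = mj.differential_jacobian(
            self._estimate(np.array([[2.0]]), mask),
            self._estimate(np.array([[0.0]]), mask))
        assert not diff.defined[0, 0]
        assert np.isnan(diff.dJ[0, 0])

    def test_mask_mismatch_rejected(self):
        m1 = _full_mask(2)
        m2 = JacobianMask(names=["x1", "x2"],
                          values=np.eye(2, dtype=bool))
        with pytest.raises(ValueError, match="identical masks"):
            mj.differential_jacobian(
                self._estimate(np.eye(2), m1), self._estimate(np.eye(2), m2))


class TestClassifyEdges:
    def test_threshold_zero_reports_all_defined(self):
        mask = _full_mask(2)
        J1 = np.array([[-1.0, 0.5], [0.2, -2.0]])
        J2 = np.array([[-2.0, 0.25], [0.1, -2.0]])
        diff = mj.differential_jacobian(
            mj.JacobianEstimate(J1, np.zeros_like(J1), mask, 1, 0),
            mj.JacobianEstimate(J2, np.zeros_like(J2), mask, 1, 0))
        edges = mj.classify_edges(diff, threshold=0.0)
        assert len(edges) == int(diff.defined.sum())

    def test_threshold_above_max_gives_empty(self):
        mask = _full_mask(2)
        J = np.array([[-1.0, 0.5], [0.2, -2.0]])
        diff = mj.differential_jacobian(
            mj.JacobianEstimate(J, np.zeros_like(J), mask, 1, 0),
            mj.JacobianEstimate(J.copy(), np.zeros_like(J), mask, 1, 0))
        assert mj.classify_edges(diff, threshold=0.1).empty

    def test_planted_differential_edges_dominate_report(self):
        """Two-group system with three edges doubled: exactly those edges
        exceed the ln2 - eps threshold (planted ground truth oracle)."""
        system = mj.make_toy_network(6, topology="random", edge_prob=0.35,
                                     seed=11)
        mask = JacobianMask.from_network(system.network)
        offdiag = np.argwhere(mask.values & ~np.eye(6, dtype=bool))
        chosen = [tuple(e) for e in offdiag[:3]]
        J2 = system.J_true.copy()
        for i, j in chosen:
            J2[i, j] *= 2.0
        for i in range(6):  # restore diagonal dominance
            row = np.sum(np.abs(J2[i])) - np.abs(J2[i, i])
            if -J2[i, i] <= row:
                J2[i, i] = -(row + 0.5)
        C1 = mj.forward_lyapunov(system.J_true, system.D_true)
        C2 = mj.forward_lyapunov(J2, system.D_true)
        names = system.network.names
        e1 = mj.monte_carlo_jacobian(CovarianceMatrix(names, C1, 0), mask,
                                     n_iter=200, seed=21)
        e2 = mj.monte_carlo_jacobian(CovarianceMatrix(names, C2, 0), mask,
                                     n_iter=200, seed=21)
        diff = mj.differential_jacobian(e1, e2)
        edges = mj.classify_edges(diff, threshold=np.log(2) - 0.2)
        reported = {(names.index(t), names.index(s))
                    for s, t in zip(edges["source"], edges["target"])
                    if s != t}
        assert set(chosen) <= reported
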