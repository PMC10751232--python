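"""Unit and property tests for the fused joint graphical lasso solver."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import stabjgl as sj
from conftest import random_spd
from oracles import fused_objective, fused_prox_oracle, jgl_objective


class TestEmpiricalCovariance:
    def test_orthogonal_centered_columns(self):
        X = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        cov = sj.empirical_covariance([X], standardize=False)
        np.testing.assert_allclose(cov.S[0], np.eye(2) * 2 / 3)

    def test_standardized_diagonal_is_unit(self, rng):
        X = rng.normal(size=(30, 6)) * rng.uniform(0.1, 50, size=6)
        cov = sj.empirical_covariance([X], standardize=True)
        np.testing.assert_allclose(np.diag(cov.S[0]), 1.0)

    def test_large_sample_recovers_inverse_precision(self):
        theta = np.array(
            [[2.0, -0.6, 0.0], [-0.6, 2.0, -0.5], [0.0, -0.5, 2.0]]
        )
        X = sj.sample_gaussian(theta, n=100_000, seed=5)
        cov = sj.empirical_covariance([X], standardize=False)
        assert np.max(np.abs(cov.S[0] - np.linalg.inv(theta))) < 0.05

    def test_zero_variance_column_rejected(self):
        X = np.ones((5, 2))
        X[:, 0] = np.arange(5)
        with pytest.raises(ValueError, match="zero-variance"):
            sj.empirical_covariance([X], standardize=True)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="columns"):
            sj.empirical_covariance([rng.normal(size=(5, 3)), rng.normal(size=(5, 4))])


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x,t,expected",
        [(0.5, 0.2, 0.3), (-0.1, 0.2, 0.0), (0.3, 0.0, 0.3), (-0.7, 0.2, -0.5)],
    )
    def test_values(self, x, t, expected):
        assert sj.soft_threshold(x, t) == pytest.approx(expected)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            sj.soft_threshold(1.0, -0.1)


class TestFusedProx:
    def test_equal_inputs_reduce_to_soft_threshold(self):
        np.testing.assert_allclose(sj.fused_prox([0.5, 0.5], 0.2, 0.3), [0.3, 0.3])

    def test_dominant_fusion_forces_mean(self):
        np.testing.assert_allclose(sj.fused_prox([1.0, -1.0], 0.0, 10.0), [0.0, 0.0])

    def test_two_group_example_matches_oracle(self):
        # frozen from the box-constrained least-squares dual oracle
        np.testing.assert_allclose(sj.fused_prox([0.9, 0.1], 0.05, 0.1), [0.75, 0.15])

    @pytest.mark.parametrize("K", [2, 3, 4, 5])
    def test_matches_dual_oracle(self, K, rng):
        for _ in range(40):
            z = rng.normal(0, 1, K)
            a1, a2 = rng.uniform(0, 0.5, 2)
            mine = sj.fused_prox(z, a1, a2)
            orc = fused_prox_oracle(z, a1, a2)
            np.testing.assert_allclose(mine, orc, atol=1e-6)

    @given(
        st.lists(st.floats(-3, 3), min_size=1, max_size=6),
        st.floats(0, 1),
        st.floats(0, 1),
    )
    def test_never_beaten_by_small_perturbations(self, z, a1, a2):
        z = np.asarray(z)
        v = sj.fused_prox(z, a1, a2)
        base = fused_objective(v, z, a1, a2)
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert base <= fused_objective(v + rng.normal(0, 1e-3, len(z)), z, a1, a2) + 1e-12


class TestThetaStep:
    def test_identity_case(self):
        out = sj.theta_step(np.eye(2), np.eye(2), 1, 1.0)
        np.testing.assert_allclose(out, np.eye(2))

    def test_stationarity_and_positive_definiteness(self, rng):
        for _ in range(10):
            S = random_spd(rng, 4)
            A = rng.normal(size=(4, 4))
            A = (A + A.T) / 2
            n_k, step = 7, 2.5
            out = sj.theta_step(S, A, n_k, step)
            assert np.linalg.eigvalsh(out)[0] > 0
            resid = n_k * (np.linalg.inv(out) - S) - step * (out - A)
            assert np.max(np.abs(resid)) < 1e-8

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            sj.theta_step(np.array([[1.0, 0.5], [0.0, 1.0]]), np.eye(2), 1, 1.0)


class TestFitJGL:
    def test_large_lambda1_empties_graph(self, rng):
        X = rng.normal(size=(60, 8))
        cov = sj.empirical_covariance([X])
        lam1 = 10 * np.max(np.abs(cov.S[0] - np.diag(np.diag(cov.S[0]))))
        ps = sj.fit_jgl(cov, sj.PenaltyPair(lam1, 0.0))
        gs = sj.graph_from_precision(ps)
        assert gs.edge_sets[0] == set()

    def test_identical_inputs_give_identical_estimates(self, rng):
        X = rng.normal(size=(50, 6))
        cov = sj.empirical_covariance([X, X.copy()])
        ps = sj.fit_jgl(cov, sj.PenaltyPair(0.2, 0.05))
        np.testing.assert_allclose(ps.theta[0], ps.theta[1], atol=1e-10)

    def test_matches_independent_glasso_solution(self, rng):
        from sklearn.covariance import graphical_lasso

        X = rng.normal(size=(50, 5))
        cov = sj.empirical_covariance([X])
        ps = sj.fit_jgl(cov, sj.PenaltyPair(0.1, 0.0), tol=1e-9, max_iter=3000)
        _, prec = graphical_lasso(
            cov.S[0], alpha=0.1, tol=1e-10, max_iter=2000, mode="lars"
        )
        np.testing.assert_allclose(ps.theta[0], prec, atol=1e-4)
        # and our objective is no worse than the reference solution's
        assert jgl_objective(ps.theta, cov.S, [1], 0.1, 0.0) <= jgl_objective(
            [prec], cov.S, [1], 0.1, 0.0
        ) + 1e-8

    def test_strong_fusion_equalizes_groups(self, rng):
        X = [rng.normal(size=(40, 5)), rng.normal(size=(60, 5))]
        cov = sj.empirical_covariance(X)
        ps = sj.fit_jgl(cov, sj.PenaltyPair(0.05, 1000.0), tol=1e-7, max_iter=2000)
        assert np.max(np.abs(ps.theta[0] - ps.theta[1])) < 1e-3

    def test_outputs_positive_definite_and_symmetric(self, rng):
        X = [rng.normal(size=(30, 6)) for _ in range(3)]
        cov = sj.empirical_covariance(X)
        ps = sj.fit_jgl(cov, sj.PenaltyPair(0.3, 0.02))
        for th in ps.theta:
            np.testing.assert_allclose(th, th.T)
            assert np.linalg.eigvalsh(th)[0] > 0

    def test_sparsity_monotone_in_lambda1(self, rng):
        scn = sj.make_scenario(K=2, p=15, n=(60, 60), fraction_shared=1.0, seed=3)
        cov = sj.empirical_covariance(scn.data)
        counts, state = [], None
        for lam1 in np.linspace(0.01, 1.0, 10):
            ps, state = sj.fit_jgl(
                cov, sj.PenaltyPair(lam1, 0.01), init=state, return_state=True
            )
            counts.append(sum(len(e) for e in sj.graph_from_precision(ps).edge_sets))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_sample_size_weighting_rescales_penalty(self, rng):
        # w_k = n_k with penalty n*lam matches w_k = 1 with penalty lam
        X = rng.normal(size=(40, 5))
        cov = sj.empirical_covariance([X])
        a = sj.fit_jgl(cov, sj.PenaltyPair(0.2, 0.0), tol=1e-8, max_iter=2000)
        b = sj.fit_jgl(
            cov, sj.PenaltyPair(0.2 * 40, 0.0), weights="sample_size",
            tol=1e-8, max_iter=2000,
        )
        np.testing.assert_allclose(a.theta[0], b.theta[0], atol=1e-5)


class TestGraphFromPrecision:
    def test_diagonal_precision_has_no_edges(self):
        ps = sj.PrecisionSet([np.diag([1.0, 2.0, 3.0])])
        gs = sj.graph_from_precision(ps)
        assert gs.edge_sets[0] == set()
        assert gs.sparsity[0] == 0.0

    def test_boundary_entry_is_not_an_edge(self):
        th = np.eye(3)
        th[0, 1] = th[1, 0] = 1e-4
        gs = sj.graph_from_precision(sj.PrecisionSet([th]), zero_tol=1e-4)
        assert gs.edge_sets[0] == set()
        gs2 = sj.graph_from_precision(sj.PrecisionSet([th]), zero_tol=0.99e-4)
        assert gs2.edge_sets[0] == {(0, 1)}

    def test_sparsity_definition(self):
        th = np.eye(4)
        th[0, 1] = th[1, 0] = 0.5
        th[2, 3] = th[3, 2] = -0.5
        gs = sj.graph_from_precision(sj.PrecisionSet([th]))
        assert gs.sparsity[0] == pytest.approx(2 * 2 / (16 - 4))
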