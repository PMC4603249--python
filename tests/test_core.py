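"""Unit and property tests for the rank-one PMD solver and its primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import svd

import scca
from scca.core import CrossCovOperator, DegenerateDirectionError, _power_init

from conftest import l1_project_bisection_oracle


# ---------------------------------------------------------------------------
# standardization


class TestStandardize:
    def test_affine_example(self):
        vm = scca.standardize_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(vm.data[:, 0], [-1.0, 0.0, 1.0])
        assert vm.standardized

    def test_column_moments(self):
        rng = np.random.default_rng(0)
        vm = scca.standardize_columns(rng.normal(5.0, 3.0, size=(4, 3)))
        assert np.all(np.abs(vm.data.mean(axis=0)) < 1e-8)
        assert np.all(np.abs(vm.data.std(axis=0, ddof=1) - 1.0) < 1e-6)

    def test_constant_column_dropped_and_recorded(self):
        X = np.column_stack([[1.0, 2, 3], [5.0, 5, 5], [0.0, 1, 4]])
        vm = scca.standardize_columns(X, feature_ids=np.array(["a", "b", "c"]))
        assert vm.p == 2
        assert list(vm.dropped_ids) == ["b"]
        assert list(vm.retained_idx) == [0, 2]
        # weight re-inflation puts explicit zeros at dropped positions
        full = scca.inflate_weights(np.array([0.6, 0.8]), vm)
        np.testing.assert_allclose(full, [0.6, 0.0, 0.8])

    def test_errors(self):
        with pytest.raises(ValueError, match="no informative"):
            scca.standardize_columns(np.ones((3, 2)))
        with pytest.raises(ValueError, match="non-finite"):
            scca.standardize_columns(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ---------------------------------------------------------------------------
# soft threshold / L1 projection


@pytest.mark.parametrize(
    "a, delta, nonneg, expected",
    [
        ([2.0, -1.0, 0.3], 0.5, False, [1.5, -0.5, 0.0]),
        ([2.0, -1.0, 0.3], 0.5, True, [1.5, 0.0, 0.0]),
        ([2.0, -1.0, 0.3], 0.0, False, [2.0, -1.0, 0.3]),
    ],
)
def test_soft_threshold_definition(a, delta, nonneg, expected):
    np.testing.assert_allclose(
        scca.soft_threshold(np.array(a), delta, nonnegative=nonneg), expected
    )


class TestL1Project:
    def test_inactive_constraint_is_plain_normalization(self):
        w = scca.l1_project(np.array([3.0, 4.0]), np.sqrt(2.0))
        np.testing.assert_allclose(w, [0.6, 0.8])

    def test_boundary_tie_breaks_to_lowest_index(self):
        w = scca.l1_project(np.array([1.0, 1.0]), 1.0)
        np.testing.assert_allclose(w, [1.0, 0.0])

    def test_matches_scalar_bisection_oracle(self):
        a = np.array([5.0, 3.0, 1.0])
        w = scca.l1_project(a, 1.2)
        assert abs(np.abs(w).sum() - 1.2) < 1e-4
        np.testing.assert_allclose(w, l1_project_bisection_oracle(a, 1.2), atol=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("nonneg", [False, True])
    def test_random_instances_match_oracle(self, seed, nonneg):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 60))
        a = rng.standard_normal(p) * rng.uniform(0.5, 10)
        if nonneg and not (a > 0).any():
            a[0] = 1.0
        s = float(rng.uniform(1.0, np.sqrt(p)))
        w = scca.l1_project(a, s, nonnegative=nonneg)
        ref = l1_project_bisection_oracle(a, s, nonnegative=nonneg)
        np.testing.assert_allclose(w, ref, atol=1e-6)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateDirectionError):
            scca.l1_project(np.zeros(4), 1.5)
        with pytest.raises(DegenerateDirectionError):
            scca.l1_project(np.array([-1.0, -2.0]), 1.5, nonnegative=True)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        data=st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=2, max_size=40
        ),
        frac=st.floats(0.0, 1.0),
        nonneg=st.booleans(),
    )
    def test_constraint_invariants(self, data, frac, nonneg):
        a = np.asarray(data)
        a_eff = np.maximum(a, 0) if nonneg else a
        if np.linalg.norm(a_eff) == 0:
            return
        s = 1.0 + frac * (np.sqrt(a.size) - 1.0)
        w = scca.l1_project(a, s, nonnegative=nonneg)
        assert abs(np.linalg.norm(w) - 1.0) < 1e-6
        assert np.abs(w).sum() <= s + 1e-6
        if nonneg:
            assert np.all(w >= 0)


# ---------------------------------------------------------------------------
# rank-one solver


class TestRank1:
    def test_self_correlation(self, make_null_pair):
        v1, _ = make_null_pair(n=30, p1=8, p2=8, seed=3)
        params = scca.SparsityParams(1.0, 1.0, nonnegative=False)
        comp = scca.scca_rank1(v1, v1, params)
        assert comp.q == pytest.approx(1.0, abs=1e-6)

    def test_unpenalized_limit_matches_svd(self, make_null_pair):
        v1, v2 = make_null_pair(n=50, p1=4, p2=4, seed=7)
        params = scca.SparsityParams(1.0, 1.0, nonnegative=False,
                                     max_iter=2000, tol=1e-10)
        comp = scca.scca_rank1(v1, v2, params)
        U, S, Vt = svd(v1.data.T @ v2.data)
        np.testing.assert_allclose(np.abs(comp.u), np.abs(U[:, 0]), atol=1e-5)
        np.testing.assert_allclose(np.abs(comp.v), np.abs(Vt[0]), atol=1e-5)
        assert abs(abs(comp.q_raw) - S[0]) < 1e-5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_ascends(self, make_signal_pair, seed):
        v1, v2, _ = make_signal_pair(n=40, p1=60, p2=60, s1=8, s2=8, seed=seed)
        trace: list = []
        scca.scca_rank1(v1, v2, scca.SparsityParams(0.5, 0.5),
                        objective_trace=trace)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-10)

    def test_component_satisfies_constraints(self, make_signal_pair):
        v1, v2, _ = make_signal_pair(n=40, p1=50, p2=70, seed=5)
        for c1, c2 in [(0.3, 0.6), (0.5, 0.5), (1.0, 0.4)]:
            comp = scca.scca_rank1(v1, v2, scca.SparsityParams(c1, c2))
            assert np.linalg.norm(comp.u) <= 1 + 1e-8
            assert np.linalg.norm(comp.v) <= 1 + 1e-8
            assert np.abs(comp.u).sum() <= c1 * np.sqrt(v1.p) + 1e-6
            assert np.abs(comp.v).sum() <= c2 * np.sqrt(v2.p) + 1e-6
            assert np.all(comp.u >= 0) and np.all(comp.v >= 0)
            assert -1 <= comp.q <= 1

    def test_nonnegative_mode_degenerates_on_anticorrelated_views(self):
        # a purely negative association admits no nonnegative direction pair
        rng = np.random.default_rng(0)
        latent = rng.standard_normal(30)
        X1 = np.outer(latent, np.ones(5)) + 0.01 * rng.standard_normal((30, 5))
        X2 = -np.outer(latent, np.ones(6)) + 0.01 * rng.standard_normal((30, 6))
        v1 = scca.standardize_columns(X1)
        v2 = scca.standardize_columns(X2)
        comp = scca.scca_rank1(v1, v2, scca.SparsityParams(1.0, 1.0))
        assert comp.degenerate
        assert comp.q == 0.0
        assert comp.n_nonzero_u == 0

    def test_sparsity_increases_as_budget_shrinks(self, make_signal_pair):
        # empirical, not guaranteed: nnz(u) non-increasing as c1 decreases
        for seed in (0, 1, 2):
            v1, v2, _ = make_signal_pair(n=50, p1=120, p2=120, s1=6, s2=6,
                                         seed=seed)
            op = CrossCovOperator(v1.data, v2.data)
            v0 = _power_init(op)
            nnz = []
            for c1 in (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3):
                comp = scca.scca_rank1(
                    v1, v2, scca.SparsityParams(c1, 0.5), operator=op, init=v0
                )
                nnz.append(comp.n_nonzero_u)
            assert all(a >= b for a, b in zip(nnz, nnz[1:])), (seed, nnz)


# ---------------------------------------------------------------------------
# deflation


class TestDeflation:
    def test_single_component_equals_rank1(self, make_signal_pair):
        v1, v2, _ = make_signal_pair(seed=4)
        params = scca.SparsityParams(0.6, 0.6)
        comps, state = scca.fit_scca(v1, v2, params, n_components=1)
        direct = scca.scca_rank1(v1, v2, params)
        np.testing.assert_array_equal(comps[0].u, direct.u)
        np.testing.assert_array_equal(comps[0].v, direct.v)
        assert len(state) == 1

    def test_deflation_removes_single_factor(self, make_signal_pair):
        v1, v2, _ = make_signal_pair(n=40, p1=20, p2=20, s1=20, s2=20,
                                     noise_sd=0.0, seed=9)
        params = scca.SparsityParams(1.0, 1.0, nonnegative=False)
        comps, _ = scca.fit_scca(v1, v2, params, n_components=2)
        assert abs(comps[1].q_raw) < 1e-6 * abs(comps[0].q_raw)

    def test_matrix_free_matches_explicit(self, make_signal_pair):
        v1, v2, _ = make_signal_pair(n=30, p1=25, p2=35, s1=4, s2=6, seed=2,
                                     n_factors=2)
        params = scca.SparsityParams(0.7, 0.7)
        dense, _ = scca.fit_scca(v1, v2, params, n_components=3,
                                 materialize=True)
        free, _ = scca.fit_scca(v1, v2, params, n_components=3,
                                materialize=False)
        assert len(dense) == len(free)
        for a, b in zip(dense, free):
            np.testing.assert_allclose(a.u, b.u, atol=1e-8)
            np.testing.assert_allclose(a.v, b.v, atol=1e-8)
            assert a.q_raw == pytest.approx(b.q_raw, abs=1e-8)

    def test_deflated_product_contract(self, make_signal_pair):
        # Z_def w == X1'(X2 w) - sum_i q_i u_i (v_i' w), checked both routes
        v1, v2, _ = make_signal_pair(n=30, p1=20, p2=30, seed=8)
        params = scca.SparsityParams(0.8, 0.8)
        comps, state = scca.fit_scca(v1, v2, params, n_components=2)
        Z = v1.data.T @ v2.data
        for q_raw, u, v in state.components:
            Z = Z - q_raw * np.outer(u, v)
        op = CrossCovOperator(v1.data, v2.data, state=state, materialize=False)
        rng = np.random.default_rng(0)
        for _ in range(5):
            w2 = rng.standard_normal(v2.p)
            w1 = rng.standard_normal(v1.p)
            np.testing.assert_allclose(op.matvec(w2), Z @ w2, atol=1e-8)
            np.testing.assert_allclose(op.rmatvec(w1), Z.T @ w1, atol=1e-8)


# ---------------------------------------------------------------------------
# canonical correlation


class TestCanonicalCorrelation:
    def test_perfect_and_anti_correlation(self, make_null_pair):
        v1, _ = make_null_pair(n=20, p1=6, p2=6, seed=1)
        u = np.ones(6) / np.sqrt(6)
        assert scca.canonical_correlation(v1, u, v1, u) == pytest.approx(1.0)
        assert scca.canonical_correlation(v1, u, v1, -u) == pytest.approx(-1.0)

    def test_independent_projections_are_near_zero(self):
        X1, X2 = scca.generate_null_views(1000, 5, 5, seed=42)
        v1 = scca.standardize_columns(X1)
        v2 = scca.standardize_columns(X2)
        u = np.ones(5) / np.sqrt(5)
        q = scca.canonical_correlation(v1, u, v2, u)
        assert abs(q) < 0.1

    def test_zero_variance_projection_flagged(self, make_null_pair):
        v1, v2 = make_null_pair(n=20, p1=6, p2=6, seed=1)
        q = scca.canonical_correlation(v1, np.zeros(6), v2, np.ones(6))
        assert np.isnan(q)
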