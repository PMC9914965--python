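"""PLSR, permutation importance and geographical-detector correctness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vegattr import (GridSpec, build_sample_table, classify_interaction,
                     discretize, gd_analysis, interaction_q, plsr_fit,
                     q_statistic, rf_importance)
from vegattr.attribution import SampleTable, StrataAssignment, _split_indices
from vegattr.preprocess import MaskLayer
from vegattr.trend import TrendResult


def make_table(X, y, seed=0, names=None):
    names = names or [f"f{j}" for j in range(X.shape[1])]
    data = pd.DataFrame(X, columns=names)
    data["response"] = y
    data["pattern"] = np.where(y > 0, "increase", "decrease")
    tr, te = _split_indices(len(y), 0.7, seed)
    return SampleTable(data, names, "NDVI", tr, te, seed)


def _trend_result(beta):
    beta = np.asarray(beta, dtype=float)
    grid = GridSpec(*beta.shape, origin_y=beta.shape[0] * 250.0)
    shape = beta.shape
    sig = np.isfinite(beta)
    return TrendResult(grid, beta, np.zeros(shape), np.zeros(shape),
                       np.zeros(shape), sig,
                       np.where(np.isfinite(beta), 0, -1).astype(np.int8),
                       0.05)


class TestSampleTable:
    def test_hand_counted_rows_with_mask(self, rng):
        beta = rng.normal(0.001, 0.002, (4, 4))
        trend = _trend_result(beta)
        keep = np.ones((4, 4), dtype=bool)
        keep[0, 0] = keep[3, 3] = False
        mask = MaskLayer(trend.grid, keep, "test")
        covs = {"Pop": rng.random((4, 4)), "Temp": rng.random((4, 4))}
        table = build_sample_table(trend, covs, mask, seed=1)
        assert table.n == 14

    def test_all_positive_slopes_empty_decrease_errors(self, rng):
        trend = _trend_result(np.full((3, 3), 0.002))
        table = build_sample_table(trend, {"Pop": rng.random((3, 3))})
        with pytest.raises(ValueError, match="decrease"):
            table.subset("decrease")
        assert table.subset("increase").n == 9

    def test_70_30_split_of_ten_rows(self, rng):
        trend = _trend_result(rng.normal(0, 1, (2, 5)))
        table = build_sample_table(trend, {"Pop": rng.random((2, 5))})
        assert len(table.train_idx) == 7 and len(table.test_idx) == 3
        assert not set(table.train_idx) & set(table.test_idx)

    def test_incomplete_covariates_dropped(self, rng):
        beta = rng.normal(0, 1, (3, 3))
        cov = rng.random((3, 3))
        cov[1, 1] = np.nan
        table = build_sample_table(_trend_result(beta), {"Pop": cov})
        assert table.n == 8

    def test_pattern_consistent_with_response_sign(self, rng):
        trend = _trend_result(rng.normal(0, 1, (5, 5)))
        table = build_sample_table(trend, {"Pop": rng.random((5, 5))})
        inc = table.data[table.data["pattern"] == "increase"]
        assert (inc["response"] > 0).all()


class TestPLSR:
    def test_single_causal_covariate_r2_one(self, rng):
        # orthogonal design (after centering): one latent direction carries
        # all of y
        raw = rng.standard_normal((60, 4))
        X, _ = np.linalg.qr(raw - raw.mean(axis=0))
        y = 3.0 * X[:, 2]
        model = plsr_fit(X, y, n_components=1)
        assert model.r2 == pytest.approx(1.0, abs=1e-10)
        assert model.ranking()[0] == "x2"
        assert model.coefficient_weight[2] == max(model.coefficient_weight)

    def test_full_rank_equals_least_squares(self, rng):
        for _ in range(5):
            X = rng.standard_normal((50, 5))
            y = X @ rng.standard_normal(5) + rng.standard_normal(50)
            model = plsr_fit(X, y, n_components=5)
            Xs = (X - X.mean(0)) / X.std(0)
            ys = (y - y.mean()) / y.std()
            beta_ols = np.linalg.lstsq(Xs, ys, rcond=None)[0]
            np.testing.assert_allclose(model.coefficients, beta_ols,
                                       atol=1e-8)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.standard_normal((40, 6))
        y = X @ rng.standard_normal(6) + 0.1 * rng.standard_normal(40)
        model = plsr_fit(X, y, n_components=4)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_matches_power_iteration_oracle_on_toy_matrix(self):
        """Independent oracle: dominant-eigenvector extraction with the same
        deflation scheme, on a 4x2 matrix."""
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 3.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        Xs = (X - X.mean(0)) / X.std(0)
        ys = (y - y.mean()) / y.std()
        # oracle: w is the dominant eigenvector of X'y y'X, i.e. X'y/|X'y|
        w_oracle = Xs.T @ ys
        M = np.outer(w_oracle, w_oracle)
        v = np.array([1.0, 0.3])
        for _ in range(200):
            v = M @ v
            v /= np.linalg.norm(v)
        t_oracle = Xs @ v
        model = plsr_fit(X, y, n_components=1)
        np.testing.assert_allclose(np.abs(model.x_weights[:, 0]), np.abs(v),
                                   atol=1e-10)
        np.testing.assert_allclose(np.abs(model.scores[:, 0]),
                                   np.abs(t_oracle), atol=1e-9)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.cross_decomposition import PLSRegression
        X = rng.standard_normal((80, 6))
        y = X @ rng.standard_normal(6) + 0.3 * rng.standard_normal(80)
        model = plsr_fit(X, y, n_components=3)
        sk = PLSRegression(n_components=3, scale=True).fit(X, y)
        # same standardized coefficients up to the response scaling
        sk_coef = (sk.coef_.ravel() * X.std(axis=0, ddof=1)) / y.std(ddof=1)
        np.testing.assert_allclose(model.coefficients, sk_coef, atol=1e-6)

    def test_zero_variance_covariate_dropped_with_warning(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 1] = 4.2
        y = X[:, 0]
        with pytest.warns(UserWarning, match="zero-variance"):
            model = plsr_fit(X, y, n_components=2)
        assert model.covariate_names == ["x0", "x2"]
        assert model.dropped == ["x1"]


class TestRFImportance:
    def test_causal_factor_ranked_first(self, rng):
        X = rng.standard_normal((1500, 10))
        y = 2.0 * X[:, 0] + rng.standard_normal(1500)
        table = make_table(X, y, seed=4)
        res = rf_importance(table, n_trees=150, seed=4)
        assert res.ranking()[0] == "f0"
        assert res.r2 > 0.5

    def test_pure_noise_importances_near_zero(self, rng):
        """Null importances fluctuate around zero; averaged over replicates
        every factor stays inside the no-structure band."""
        acc = np.zeros(6)
        for seed in range(3):
            X = rng.standard_normal((800, 6))
            y = rng.standard_normal(800)  # response independent of X
            res = rf_importance(make_table(X, y, seed=seed), n_trees=200,
                                seed=seed)
            acc += res.inc_mse_pct
        assert np.abs(acc / 3).max() < 3.0

    def test_duplicated_causal_covariate_both_outrank_noise(self, rng):
        X = rng.standard_normal((1500, 8))
        X[:, 1] = X[:, 0]  # exact duplicate of the causal covariate
        y = 2.0 * X[:, 0] + 0.5 * rng.standard_normal(1500)
        res = rf_importance(make_table(X, y, seed=3), n_trees=200, seed=3)
        ranked = res.ranking()
        assert set(ranked[:2]) == {"f0", "f1"}

    def test_reproducible_under_seed(self, rng):
        X = rng.standard_normal((300, 5))
        y = X[:, 0] + rng.standard_normal(300)
        t = make_table(X, y, seed=8)
        a = rf_importance(t, n_trees=50, seed=8)
        b = rf_importance(t, n_trees=50, seed=8)
        np.testing.assert_array_equal(a.inc_mse_pct, b.inc_mse_pct)
        assert a.rmse == b.rmse

    def test_m_try_clipped_with_warning(self, rng):
        X = rng.standard_normal((200, 2))
        y = X[:, 0]
        with pytest.warns(UserWarning, match="m_try"):
            res = rf_importance(make_table(X, y), n_trees=20, m_try=4)
        assert res.m_try == 2


class TestDiscretize:
    def test_uniform_quantile_strata_balanced(self):
        s = discretize(np.arange(1, 101, dtype=float), L=5)
        assert s.L == 5
        np.testing.assert_array_equal(s.counts, [20] * 5)

    def test_constant_covariate_single_flagged_stratum(self):
        s = discretize(np.full(10, 3.3), L=4)
        assert s.L == 1 and s.flagged_constant

    def test_duplicate_edges_collapse(self):
        s = discretize(np.array([1.0, 1, 1, 1, 2, 3]), L=3)
        assert s.L == 2
        np.testing.assert_array_equal(np.sort(s.counts), [2, 4])

    def test_small_strata_merged(self):
        # one extreme value would form a singleton stratum
        values = np.concatenate([np.ones(10), np.full(10, 2.0), [100.0]])
        s = discretize(values, L=3, method="equal_interval")
        assert (s.counts >= 2).all()

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.arange(10.0), L=1)
        with pytest.raises(ValueError):
            discretize(np.arange(10.0), method="kmeans")


class TestQStatistic:
    def test_hand_example_q_0_8(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        strata = StrataAssignment.from_labels([0, 0, 1, 1])
        res = q_statistic(y, strata)
        assert res.ssw == pytest.approx(1.0)
        assert res.sst == pytest.approx(5.0)
        assert res.q == pytest.approx(0.8)

    def test_single_stratum_q_zero(self, rng):
        y = rng.normal(size=20)
        assert q_statistic(y, StrataAssignment.from_labels(
            np.zeros(20, dtype=int))).q == 0.0

    def test_singleton_strata_q_one(self, rng):
        y = rng.normal(size=10)
        assert q_statistic(y, StrataAssignment.from_labels(
            np.arange(10))).q == 1.0

    def test_q_in_unit_interval_random_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            y = rng.normal(size=n)
            labels = rng.integers(0, rng.integers(2, 6), n)
            q = q_statistic(y, StrataAssignment.from_labels(labels)).q
            assert 0.0 <= q <= 1.0

    def test_invariant_under_stratum_relabeling(self, rng):
        y = rng.normal(size=30)
        labels = rng.integers(0, 4, 30)
        q1 = q_statistic(y, StrataAssignment.from_labels(labels)).q
        q2 = q_statistic(y, StrataAssignment.from_labels(9 - labels)).q
        assert q1 == pytest.approx(q2)

    def test_monotone_under_refinement(self, rng):
        for _ in range(50):
            y = rng.normal(size=60)
            coarse = rng.integers(0, 3, 60)
            refined = coarse * 4 + rng.integers(0, 3, 60)
            qc = q_statistic(y, StrataAssignment.from_labels(coarse)).q
            qr = q_statistic(y, StrataAssignment.from_labels(refined)).q
            assert qr >= qc - 1e-12

    def test_degenerate_sst_zero_gives_q_zero(self):
        assert q_statistic(np.full(6, 2.0),
                           StrataAssignment.from_labels([0, 0, 1, 1, 2, 2])
                           ).q == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            q_statistic(np.ones(5), StrataAssignment.from_labels([0, 1]))


class TestInteraction:
    def test_self_interaction_idempotent(self, rng):
        y = rng.normal(size=40)
        s = StrataAssignment.from_labels(rng.integers(0, 4, 40))
        assert interaction_q(y, s, s).q == pytest.approx(q_statistic(y, s).q)

    def test_xor_construction(self):
        """y depends only on the XOR of two binary strata: singly invisible,
        jointly deterministic."""
        a = np.array([0, 0, 1, 1] * 25)
        b = np.array([0, 1, 0, 1] * 25)
        y = (a != b).astype(float)
        sa = StrataAssignment.from_labels(a)
        sb = StrataAssignment.from_labels(b)
        q1 = q_statistic(y, sa).q
        q2 = q_statistic(y, sb).q
        q12 = interaction_q(y, sa, sb).q
        assert q1 == pytest.approx(0.0, abs=1e-12)
        assert q2 == pytest.approx(0.0, abs=1e-12)
        assert q12 == pytest.approx(1.0)
        assert classify_interaction(q1, q2, q12) == "nonlinear_enhance"

    def test_refining_either_never_decreases_q12(self, rng):
        y = rng.normal(size=80)
        a = rng.integers(0, 3, 80)
        b = rng.integers(0, 3, 80)
        b_ref = b * 3 + rng.integers(0, 2, 80)
        base = interaction_q(y, StrataAssignment.from_labels(a),
                             StrataAssignment.from_labels(b)).q
        ref = interaction_q(y, StrataAssignment.from_labels(a),
                            StrataAssignment.from_labels(b_ref)).q
        assert ref >= base - 1e-12


class TestClassifyInteraction:
    @pytest.mark.parametrize("q1,q2,q12,expected", [
        (0.3, 0.4, 0.9, "nonlinear_enhance"),   # 0.9 > 0.7
        (0.3, 0.4, 0.2, "nonlinear_weaken"),    # below both
        (0.3, 0.4, 0.35, "univariate_weaken"),  # between
        (0.3, 0.4, 0.5, "bivariate_enhance"),   # above max, below sum
        (0.2, 0.3, 0.5, "independent"),         # exactly the sum
        (0.5, 0.5, 0.5, "bivariate_enhance"),   # q12 = max boundary rule
    ])
    def test_rule_table(self, q1, q2, q12, expected):
        assert classify_interaction(q1, q2, q12) == expected

    @given(q1=st.floats(0, 1), q2=st.floats(0, 1), q12=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_total_and_single_valued(self, q1, q2, q12):
        cat = classify_interaction(q1, q2, q12)
        assert cat in ("nonlinear_weaken", "univariate_weaken",
                       "bivariate_enhance", "independent",
                       "nonlinear_enhance")

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_interaction(-0.1, 0.5, 0.5)


class TestEngineAgreement:
    def test_all_engines_agree_on_strong_causal_factor(self, rng):
        """With one dominant driver, PLSR weights, %IncMSE and q all rank
        it first."""
        n = 2000
        X = rng.standard_normal((n, 6))
        y = 1.5 * X[:, 3] + 0.3 * rng.standard_normal(n)
        table = make_table(X, y, seed=6)
        pls = plsr_fit(table.X, table.y, 2, table.covariate_names)
        imp = rf_importance(table, n_trees=150, seed=6)
        gd = gd_analysis(table, L=5)
        singles = gd[gd["factor_b"] == ""].set_index("factor_a")["q"]
        assert pls.ranking()[0] == "f3"
        assert imp.ranking()[0] == "f3"
        assert singles.idxmax() == "f3"
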