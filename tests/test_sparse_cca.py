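import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exfoliomics import sparse_cca
from exfoliomics.sparse_cca import (
    budget_from_fraction,
    cca_score_table,
    deflate,
    fit_sparse_cca,
    l1_bounded_unit_vector,
    loo_cv_tune,
    soft_threshold,
    sparse_cca_pair,
    standardize_columns,
)


def random_pair(rng, n=10, p=20, q=30):
    x = pd.DataFrame(rng.normal(size=(n, p)))
    y = pd.DataFrame(rng.normal(size=(n, q)))
    return x, y


class TestStandardize:
    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.normal(size=(50, 4)))
        z = (raw - raw.mean()) / raw.std(ddof=0)
        out, dropped = standardize_columns(z)
        assert dropped == []
        assert np.allclose(out.to_numpy(), z.to_numpy(), atol=1e-12)

    def test_constant_column_dropped(self):
        raw = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        out, dropped = standardize_columns(raw)
        assert dropped == ["b"]
        assert list(out.columns) == ["a"]

    def test_all_constant_rejected(self):
        raw = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            standardize_columns(raw)

    def test_population_sd_convention(self):
        out, _ = standardize_columns(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        expected = np.array([-1.0, 0.0, 1.0]) * np.sqrt(3.0 / 2.0)
        assert np.allclose(out["a"].to_numpy(), expected)


class TestSoftThreshold:
    def test_examples(self):
        assert soft_threshold(np.array([3.0]), 1.0)[0] == 2.0
        assert soft_threshold(np.array([-0.5]), 1.0)[0] == 0.0

    def test_lambda_zero_identity(self):
        a = np.array([1.0, -2.0, 0.0])
        assert np.array_equal(soft_threshold(a, 0.0), a)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0]), -0.1)

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=20),
        st.floats(0, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_shrinks_toward_zero(self, vals, lam):
        a = np.array(vals)
        s = soft_threshold(a, lam)
        assert np.all(np.abs(s) <= np.abs(a) + 1e-12)
        assert np.all(np.sign(s[s != 0]) == np.sign(a[s != 0]))


class TestL1BoundedUnitVector:
    def test_inactive_budget_returns_normalized(self):
        a = np.array([3.0, -4.0])
        w = l1_bounded_unit_vector(a, np.sqrt(2))
        assert np.allclose(w, a / 5.0)

    def test_budget_one_max_sparsity(self):
        a = np.array([1.0, -5.0, 2.0])
        w = l1_bounded_unit_vector(a, 1.0)
        assert np.allclose(w, [0.0, -1.0, 0.0], atol=1e-6)

    def test_unit_norm_and_budget(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=30)
            c = 0.5 * np.sqrt(30)
            w = l1_bounded_unit_vector(a, c)
            assert np.linalg.norm(w) == pytest.approx(1.0)
            assert np.abs(w).sum() <= c + 1e-6

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=40)
        c = 0.5 * np.sqrt(40)
        w = l1_bounded_unit_vector(a, c)
        # fine lambda grid oracle: best feasible normalized soft-threshold
        best_obj = -np.inf
        for lam in np.linspace(0, np.abs(a).max() * 0.999, 10000):
            s = soft_threshold(a, lam)
            norm = np.linalg.norm(s)
            if norm == 0:
                continue
            cand = s / norm
            if np.abs(cand).sum() <= c + 1e-9:
                best_obj = max(best_obj, float(a @ cand))
        assert a @ w >= best_obj - 1e-6

    def test_infeasible_budget_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            l1_bounded_unit_vector(np.array([1.0, 1.0]), 0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            l1_bounded_unit_vector(np.zeros(3), 1.0)


class TestSparseCCAPair:
    def test_single_column_perfect(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=12)
        x = pd.DataFrame({"a": col})
        y = pd.DataFrame({"b": col})
        fit = fit_sparse_cca(x, y, 1.0, 1.0, n_components=1)
        assert np.allclose(np.abs(fit.u.to_numpy()), 1.0)
        assert fit.score_correlation[0] == pytest.approx(1.0)

    def test_inactive_budgets_match_svd(self):
        rng = np.random.default_rng(4)
        x, y = random_pair(rng)
        xs, _ = standardize_columns(x)
        ys, _ = standardize_columns(y)
        m = xs.to_numpy().T @ ys.to_numpy()
        u, v, d, conv = sparse_cca_pair(
            m, np.sqrt(20), np.sqrt(30), tol=1e-12, max_iter=5000
        )
        top = np.linalg.svd(m, compute_uv=False)[0]
        assert d == pytest.approx(top, abs=1e-8)

    def test_objective_monotone_ascent(self):
        rng = np.random.default_rng(5)
        x, y = random_pair(rng)
        xs, _ = standardize_columns(x)
        ys, _ = standardize_columns(y)
        m = xs.to_numpy().T @ ys.to_numpy()
        b1, b2 = 1.3, 1.5
        _, _, vt = np.linalg.svd(m, full_matrices=False)
        v = vt[0]
        objectives = []
        for _ in range(30):
            u = l1_bounded_unit_vector(m @ v, b1)
            v = l1_bounded_unit_vector(m.T @ u, b2)
            objectives.append(float(u @ m @ v))
        # slack matches the 1e-8 bisection tolerance on the L1 constraint
        assert all(b >= a - 1e-6 for a, b in zip(objectives, objectives[1:]))

    def test_constraints_satisfied_on_fits(self):
        rng = np.random.default_rng(6)
        for c1, c2 in [(0.2, 0.2), (0.5, 0.7), (1.0, 1.0)]:
            x, y = random_pair(rng)
            fit = fit_sparse_cca(x, y, c1, c2, n_components=2)
            b1 = budget_from_fraction(c1, x.shape[1])
            b2 = budget_from_fraction(c2, y.shape[1])
            for k in range(2):
                u = fit.u.iloc[:, k].to_numpy()
                v = fit.v.iloc[:, k].to_numpy()
                assert np.linalg.norm(u) <= 1 + 1e-8
                assert np.linalg.norm(v) <= 1 + 1e-8
                assert np.abs(u).sum() <= b1 + 1e-6
                assert np.abs(v).sum() <= b2 + 1e-6

    def test_sign_convention(self):
        rng = np.random.default_rng(7)
        x, y = random_pair(rng)
        fit = fit_sparse_cca(x, y, 0.5, 0.5)
        for k in range(fit.n_components):
            u = fit.u.iloc[:, k].to_numpy()
            first_nonzero = u[np.nonzero(u)[0][0]]
            assert first_nonzero > 0

    def test_objective_non_increasing_over_components(self):
        rng = np.random.default_rng(8)
        x, y = random_pair(rng)
        fit = fit_sparse_cca(x, y, 1.0, 1.0, n_components=3)
        assert fit.d[0] >= fit.d[1] - 1e-8
        assert fit.d[1] >= fit.d[2] - 1e-8


class TestDeflate:
    def test_rank_one_annihilated(self):
        u = np.array([0.6, 0.8])
        v = np.array([1.0, 0.0, 0.0])
        m = 5.0 * np.outer(u, v)
        assert np.allclose(deflate(m, u, v, 5.0), 0.0)

    def test_projection_identity(self):
        rng = np.random.default_rng(9)
        m = rng.normal(size=(6, 7))
        u, v, d, _ = sparse_cca_pair(m, np.sqrt(6), np.sqrt(7), tol=1e-12,
                                     max_iter=5000)
        m2 = deflate(m, u, v, d)
        assert abs(u @ m2 @ v) < 1e-8

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            deflate(np.eye(3), np.ones(2), np.ones(3), 1.0)


class TestLOOTuning:
    def test_single_grid_point_returned(self):
        rng = np.random.default_rng(10)
        x, y = random_pair(rng, n=6, p=5, q=5)
        best, table = loo_cv_tune(x, y, grid=[(0.4, 0.6)])
        assert best == (0.4, 0.6)
        assert len(table) == 1

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(11)
        x, y = random_pair(rng, n=2, p=3, q=3)
        with pytest.raises(ValueError, match="n >= 3"):
            loo_cv_tune(x, y)

    def test_sparse_correlated_block_support_recovery(self):
        # 10 of 200 variables share a latent factor (r ~ 0.9): the tuned fit
        # should place most loading mass on the true support
        rng = np.random.default_rng(12)
        n, p, active = 20, 200, 10
        z = rng.normal(size=n)
        x = rng.normal(size=(n, p))
        y = rng.normal(size=(n, p))
        x[:, :active] = 0.9 * z[:, None] + 0.44 * rng.normal(size=(n, active))
        y[:, :active] = 0.9 * z[:, None] + 0.44 * rng.normal(size=(n, active))
        x, y = pd.DataFrame(x), pd.DataFrame(y)
        grid = [(a, a) for a in (0.05, 0.1, 0.2, 0.3, 0.5)]
        best, _ = loo_cv_tune(x, y, grid=grid)
        fit = fit_sparse_cca(x, y, *best, n_components=1)
        u = np.abs(fit.u.to_numpy().ravel())
        v = np.abs(fit.v.to_numpy().ravel())
        assert u[:active].sum() / u.sum() >= 0.8
        assert v[:active].sum() / v.sum() >= 0.8

    def test_independent_data_low_heldout_correlation(self):
        rng = np.random.default_rng(13)
        crits = []
        for _ in range(5):
            x, y = random_pair(rng, n=12, p=30, q=30)
            xs, ys = sparse_cca.loo_heldout_scores(x, y, 0.3, 0.3)
            crits.append(abs(np.corrcoef(xs, ys)[0, 1]))
        assert np.median(crits) < 0.5


class TestScoreTable:
    def _fit_and_meta(self):
        rng = np.random.default_rng(14)
        n = 4
        x = pd.DataFrame(rng.normal(size=(n, 6)), index=[f"x{i}" for i in range(n)])
        y = pd.DataFrame(rng.normal(size=(n, 5)), index=[f"y{i}" for i in range(n)])
        fit = fit_sparse_cca(x, y, 1.0, 1.0, n_components=2)
        meta = pd.DataFrame(
            {
                "source": ["A"] * n + ["B"] * n,
                "group": ["control", "control", "NSAID", "NSAID"] * 2,
                "subject": [f"m{i}" for i in range(n)] * 2,
            },
            index=[f"x{i}" for i in range(n)] + [f"y{i}" for i in range(n)],
        )
        return fit, meta, x, y

    def test_scores_zero_mean(self):
        fit, meta, x, y = self._fit_and_meta()
        assert abs(fit.x_scores.iloc[:, 0].mean()) < 1e-8
        assert abs(fit.y_scores.iloc[:, 0].mean()) < 1e-8

    def test_table_matches_direct_multiplication(self):
        fit, meta, x, y = self._fit_and_meta()
        table = cca_score_table(
            fit, meta, [f"x{i}" for i in range(4)], [f"y{i}" for i in range(4)]
        )
        xs, _ = standardize_columns(x)
        direct = xs.to_numpy() @ fit.u.to_numpy()
        assert np.allclose(table.loc["x0", ["comp1", "comp2"]], direct[0])
        assert table.loc["x0", "partner_comp1"] == pytest.approx(
            fit.y_scores.iloc[0, 0]
        )

    def test_missing_partner_sample_rejected(self):
        fit, meta, *_ = self._fit_and_meta()
        with pytest.raises(ValueError, match="missing"):
            cca_score_table(fit, meta, ["x0", "x1", "x2", "x3"],
                            ["y0", "y1", "y2", "zzz"])


class TestBudgetMapping:
    def test_endpoints(self):
        assert budget_from_fraction(1.0, 16) == pytest.approx(4.0)
        assert budget_from_fraction(1e-9, 16) == pytest.approx(1.0, abs=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            budget_from_fraction(0.0, 4)
        with pytest.raises(ValueError):
            budget_from_fraction(1.2, 4)
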