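import numpy as np
import pandas as pd
import pytest
from scipy import stats

import diffnet as dn
from diffnet.preprocess import EmptyExperimentError, PreprocessError

from conftest import make_condition, make_table


class TestFilterAndImpute:
    def test_feature_above_threshold_dropped(self):
        # observed in 69% of samples -> missing 31% > 30% -> dropped
        vals = np.ones((2, 100))
        vals[0, :31] = np.nan
        X = make_table(vals)
        out, report = dn.filter_and_impute(X, 0.30)
        assert report.dropped_features == ["F1"]
        assert list(out.index) == ["F2"]

    def test_median_imputation(self):
        X = make_table([[1.0, 2.0, np.nan, 4.0]])
        out, report = dn.filter_and_impute(X, 0.30)
        assert out.iloc[0, 2] == 2.0  # median of {1,2,4}
        assert report.imputed_cells == [("F1", "S3")]

    def test_no_missing_is_identity(self):
        X = make_table(np.arange(12).reshape(3, 4) + 1.0)
        out, report = dn.filter_and_impute(X)
        pd.testing.assert_frame_equal(out, X)
        assert report.dropped_features == [] and report.imputed_cells == []

    def test_all_dropped_raises(self):
        X = make_table(np.full((2, 4), np.nan))
        with pytest.raises(EmptyExperimentError):
            dn.filter_and_impute(X, 0.30)

    def test_all_missing_feature_surviving_threshold_raises(self):
        X = make_table(np.full((1, 4), np.nan))
        with pytest.raises(PreprocessError, match="F1"):
            dn.filter_and_impute(X, 1.0)


class TestAdjustCovariates:
    def test_independent_feature_is_min_shifted(self, rng):
        row = rng.normal(size=50)
        cov = pd.DataFrame({"z": np.zeros(50)}, index=[f"S{j + 1}" for j in range(50)])
        # all-zero covariate column is rank-deficient together with intercept
        with pytest.raises(PreprocessError):
            dn.adjust_covariates(make_table(row[None, :]), cov)
        # orthogonal covariate: residuals = centered row, then min-shifted
        z = rng.normal(size=50)
        X = make_table(row[None, :])
        cov = pd.DataFrame({"z": z - z.mean()}, index=X.columns)
        fitted = np.polyfit(z, row, 1)
        assert abs(fitted[0]) < 1  # generic random slope, just not degenerate
        out = dn.adjust_covariates(X, cov)
        assert out.to_numpy().min() == 0.0

    def test_exactly_linear_feature_becomes_zero(self):
        z = np.linspace(0, 1, 20)
        X = make_table((2 + 3 * z)[None, :])
        cov = pd.DataFrame({"z": z}, index=X.columns)
        out = dn.adjust_covariates(X, cov)
        assert np.allclose(out.to_numpy(), 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariate(self, rng):
        # oracle: OLS normal equations via an independent lstsq solve
        z = rng.normal(size=60)
        y = rng.normal(size=60)
        X = make_table(y[None, :])
        cov = pd.DataFrame({"z": z}, index=X.columns)
        out = dn.adjust_covariates(X, cov).to_numpy()[0]
        D = np.column_stack([np.ones(60), z])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        oracle = y - D @ beta
        assert np.allclose(out, oracle - oracle.min(), atol=1e-10)
        assert abs((out - out.mean()) @ z) < 1e-8 * np.abs(z).sum()

    def test_too_few_samples_raises(self):
        X = make_table(np.ones((1, 2)))
        cov = pd.DataFrame({"z": [0.0, 1.0]}, index=X.columns)
        with pytest.raises(PreprocessError):
            dn.adjust_covariates(X, cov)


class TestCreateExperiment:
    def test_natural_log(self):
        e = np.e
        X = make_table([[1, e, e**2, 1], [2, 3, 2, 5]])
        exp = dn.create_experiment(X, make_condition(2, 2))
        assert np.allclose(exp.X_log[0], [0, 1, 2, 0])

    def test_standardized_blocks(self, small_exp):
        for lvl in small_exp.condition_levels:
            block = small_exp.X_std[lvl]
            assert np.allclose(block.mean(axis=1), 0, atol=1e-8)
            assert np.allclose(block.std(axis=1), 1, atol=1e-8)

    def test_standardization_idempotent(self, small_exp):
        from diffnet.preprocess import _standardize_rows

        block = small_exp.X_std[small_exp.control]
        again = _standardize_rows(block)
        assert np.abs(again - block).max() < 1e-8

    def test_already_scaled_blocks_differential(self, rng):
        X = make_table(rng.normal(size=(3, 10)))
        exp = dn.create_experiment(X, make_condition(5, 5), already_scaled=True)
        with pytest.raises(PreprocessError):
            dn.differential_expression(exp)

    def test_nonpositive_values_rejected(self):
        X = make_table([[1.0, 0.0, 2.0, 3.0]])
        with pytest.raises(PreprocessError, match="S2"):
            dn.create_experiment(X, make_condition(2, 2))

    def test_wrong_level_count(self, rng):
        X = make_table(rng.uniform(1, 2, size=(2, 6)))
        cond = pd.Series(["a", "a", "b", "b", "c", "c"], index=X.columns)
        with pytest.raises(PreprocessError):
            dn.create_experiment(X, cond)

    def test_control_is_first_declared_level(self, rng):
        X = make_table(rng.uniform(1, 2, size=(2, 6)))
        cond = pd.Series(["x", "x", "y", "y", "y", "x"], index=X.columns)
        exp = dn.create_experiment(X, cond, condition_levels=("y", "x"))
        assert exp.control == "y" and exp.case == "x"

    def test_no_nan_downstream(self, rng):
        vals = rng.uniform(1, 5, size=(4, 20))
        vals[1, 3] = np.nan
        X, _ = dn.filter_and_impute(make_table(vals))
        exp = dn.create_experiment(X, make_condition(10, 10))
        assert np.isfinite(exp.X_log).all()
        for block in exp.X_std.values():
            assert np.isfinite(block).all()
        ns = dn.differential_expression(exp)
        assert np.isfinite(ns.p).all() and np.isfinite(ns.q).all()


class TestDiagnostics:
    def test_duplicated_feature_gives_zero_eigenvalue(self, rng):
        base = rng.uniform(1, 2, size=(3, 30))
        vals = np.vstack([base, base[0:1] * 1.0])
        exp = dn.create_experiment(make_table(vals), make_condition(15, 15))
        rep = dn.diagnose_conditioning(exp)
        for lvl in exp.condition_levels:
            assert rep.min_eigenvalue[lvl] < 1e-10
        assert rep.aggregation_recommended

    def test_independent_features_well_conditioned(self, rng):
        # oracle: direct eigendecomposition, n >> m puts all eigenvalues near 1
        vals = np.exp(rng.standard_normal((5, 5000)))
        exp = dn.create_experiment(make_table(vals), make_condition(2500, 2500))
        rep = dn.diagnose_conditioning(exp)
        for lvl in exp.condition_levels:
            oracle = np.linalg.eigvalsh(np.corrcoef(exp.log_block(lvl)))[::-1]
            assert np.allclose(rep.eigenvalues[lvl], oracle, atol=1e-10)
            assert np.all(np.abs(rep.eigenvalues[lvl] - 1) < 0.2)
        assert not rep.aggregation_recommended

    def test_single_feature(self, rng):
        vals = rng.uniform(1, 2, size=(1, 20))
        exp = dn.create_experiment(make_table(vals), make_condition(10, 10))
        rep = dn.diagnose_conditioning(exp)
        for lvl in exp.condition_levels:
            assert rep.eigenvalues[lvl].tolist() == [1.0]
        assert not rep.aggregation_recommended

    def test_constant_feature_raises(self, rng):
        # pre-scaled input bypasses standardization, so the constant row
        # first surfaces in the correlation diagnostics
        vals = rng.normal(size=(2, 10))
        vals[0] = 3.0
        exp = dn.create_experiment(
            make_table(vals), make_condition(5, 5), already_scaled=True
        )
        with pytest.raises(PreprocessError, match="F1"):
            dn.diagnose_conditioning(exp)

    def test_eigenvalues_sorted_descending(self, small_exp):
        rep = dn.diagnose_conditioning(small_exp)
        for ev in rep.eigenvalues.values():
            assert np.all(np.diff(ev) <= 1e-12)
            assert rep.condition_number[small_exp.control] >= 1.0


class TestDifferentialExpression:
    def test_identical_groups_give_null_stats(self):
        block = np.tile([[1.0, 2.0, 3.0]], (2, 1))
        X = make_table(np.hstack([block, block]))
        exp = dn.create_experiment(X, make_condition(3, 3))
        ns = dn.differential_expression(exp)
        assert np.allclose(ns.t, 0) and np.allclose(ns.p, 1)

    def test_separated_groups_tiny_p(self, rng):
        ctrl = np.zeros(4) + rng.normal(0, 1e-6, 4)
        case = np.ones(4) + rng.normal(0, 1e-6, 4)
        X = make_table(np.exp(np.concatenate([ctrl, case]))[None, :])
        exp = dn.create_experiment(X, make_condition(4, 4))
        ns = dn.differential_expression(exp)
        assert ns.p[0] < 1e-6
        # closed-form pooled-variance oracle
        sp2 = (3 * ctrl.var(ddof=1) + 3 * case.var(ddof=1)) / 6
        t_oracle = (case.mean() - ctrl.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), 6)
        assert np.isclose(ns.t[0], t_oracle, atol=1e-10)
        assert np.isclose(ns.p[0], p_oracle, atol=1e-10)

    def test_matches_manual_pooled_t_on_random_fixtures(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(3, 12, size=2)
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            X = make_table(np.concatenate([a, b])[None, :])
            exp = dn.create_experiment(
                X, make_condition(n1, n2), already_log=True
            )
            ns = dn.differential_expression(exp)
            sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
            t_oracle = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            p_oracle = 2 * stats.t.sf(abs(t_oracle), n1 + n2 - 2)
            assert np.isclose(ns.t[0], t_oracle, atol=1e-10)
            assert np.isclose(ns.p[0], p_oracle, atol=1e-10)

    def test_sign_convention_case_minus_control(self):
        ctrl = np.array([0.9, 1.0, 1.1])
        case = np.array([1.9, 2.0, 2.1])
        X = make_table(np.concatenate([ctrl, case])[None, :])
        exp = dn.create_experiment(X, make_condition(3, 3), already_log=True)
        ns = dn.differential_expression(exp)
        assert ns.mean_difference[0] == pytest.approx(1.0)

    def test_bh_invariants(self, rng):
        vals = np.exp(rng.standard_normal((20, 30)))
        exp = dn.create_experiment(make_table(vals), make_condition(15, 15))
        ns = dn.differential_expression(exp)
        assert np.all(ns.q >= ns.p - 1e-15)
        # monotone: ordering by p equals ordering by q up to ties
        order_p = np.argsort(ns.p, kind="mergesort")
        assert np.all(np.diff(ns.q[order_p]) >= -1e-15)

    def test_small_condition_raises(self, rng):
        vals = rng.uniform(1, 2, size=(2, 20))
        X = make_table(vals)
        cond = pd.Series(["a"] + ["b"] * 19, index=X.columns)
        with pytest.raises(PreprocessError):
            dn.create_experiment(X, cond)
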