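"""Statistical engine: OLS, encompassing model, Welch/paired t, Holm."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from evopool.compare import (
    compare_predictors,
    encompassing_test,
    holm_correction,
    ols_fit,
    paired_t,
    welch_t,
)

# the classic unequal-variance two-sample dataset used to exercise Welch's test
WELCH_A = [27.5, 21, 19, 23.6, 17, 17.9, 16.9, 20.1, 21.9, 22.6, 23.1, 19.6, 19, 21.7, 21.4]
WELCH_B = [27.1, 22, 20.8, 23.4, 23.4, 23.5, 25.8, 22, 24.8, 20.2, 21.9, 22.1, 22.9, 30.5]


class TestOlsFit:
    def test_exact_linear_response(self):
        x = np.arange(10.0)
        fit = ols_fit(3.0 + 2.0 * x, x)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients[1] == pytest.approx(2.0)

    def test_orthogonal_response_zero_slope(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # even function: orthogonal to x
        fit = ols_fit(y, x)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        fit = ols_fit(y, x)
        design = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(fit.coefficients, beta, atol=1e-10)
        resid = y - design @ beta
        assert fit.residual_ss == pytest.approx(float(resid @ resid), abs=1e-10)

    def test_collinear_design_rejected(self):
        x = np.arange(6.0)
        with pytest.raises(np.linalg.LinAlgError):
            ols_fit(np.ones(6), np.column_stack([x, 2 * x]))

    def test_r_squared_definition(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        fit = ols_fit(y, x)
        total_ss = np.sum((y - y.mean()) ** 2)
        assert fit.r_squared == pytest.approx(1 - fit.residual_ss / total_ss)


class TestEncompassing:
    def test_degenerate_perfect_predictor(self):
        rng = np.random.default_rng(7)
        pi = rng.normal(size=30)
        noise = rng.normal(size=30)
        res = encompassing_test(pi.copy(), pi, noise)
        assert res.partial_f["pi"] > 1e4
        assert res.partial_p["F"] > 0.01

    def test_identical_predictors_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(np.linalg.LinAlgError):
            encompassing_test(x, x, x)

    def test_partial_f_equals_squared_t(self):
        """Algebraic identity: drop-one partial F = (coefficient t)^2."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        pi = rng.normal(size=40)
        f = 0.5 * pi + rng.normal(size=40)
        y = pi - f + rng.normal(size=40)
        res = encompassing_test(y, pi, f)
        fit = sm.OLS(y, sm.add_constant(np.column_stack([pi, f]))).fit()
        assert res.partial_f["pi"] == pytest.approx(float(fit.tvalues[1] ** 2), abs=1e-8)
        assert res.partial_f["F"] == pytest.approx(float(fit.tvalues[2] ** 2), abs=1e-8)

    def test_combined_r2_at_least_single_r2(self):
        rng = np.random.default_rng(9)
        pi = rng.normal(size=50)
        f = rng.normal(size=50)
        y = pi + 0.3 * f + rng.normal(size=50)
        combined = encompassing_test(y, pi, f).combined
        assert combined.r_squared >= ols_fit(y, pi).r_squared - 1e-12
        assert combined.r_squared >= ols_fit(y, f).r_squared - 1e-12

    def test_reported_df(self):
        rng = np.random.default_rng(10)
        res = encompassing_test(
            rng.normal(size=87), rng.normal(size=87), rng.normal(size=87)
        )
        assert res.df == (1, 84)


class TestWelch:
    def test_identical_samples_t_zero(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)

    def test_shifted_sample_direction(self):
        res = welch_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.t_statistic < -5

    def test_textbook_pair_matches_hand_formulas(self):
        a, b = np.asarray(WELCH_A), np.asarray(WELCH_B)
        res = welch_t(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_oracle = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_oracle = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        assert res.t_statistic == pytest.approx(t_oracle, abs=1e-10)
        assert res.df == pytest.approx(df_oracle, abs=1e-10)
        # frozen values from the hand evaluation above
        assert res.t_statistic == pytest.approx(-2.7078, abs=1e-4)
        assert res.df == pytest.approx(26.9527, abs=1e-4)

    def test_df_reduces_to_pooled_under_equal_variance_and_size(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [11.0, 12.0, 13.0, 14.0]  # same spread, equal n
        res = welch_t(a, b)
        assert res.df == pytest.approx(len(a) + len(b) - 2)

    def test_df_bounds(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0, 3, 15)
        res = welch_t(a, b)
        assert min(len(a), len(b)) - 1 <= res.df <= len(a) + len(b) - 2


class TestPairedT:
    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(12)
        before = rng.normal(size=10)
        t, df, p = paired_t(before, before + rng.normal(size=10))
        assert df == 9

    def test_zero_mean_differences(self):
        t, _, _ = paired_t([0.0, 0.0, 0.0, 0.0], [1.0, -1.0, 1.0, -1.0])
        assert t == pytest.approx(0.0)

    def test_identical_vectors_flagged(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_correction([0.03], m=1)[0] == pytest.approx(0.03)

    def test_hand_worked_three_values(self):
        adj = holm_correction([0.01, 0.04, 0.03], m=3)
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_all_ones_stay_one(self):
        assert np.all(holm_correction([1.0, 1.0, 1.0]) == 1.0)

    def test_family_larger_than_list(self):
        adj = holm_correction([0.001, 0.002], m=10)
        assert np.allclose(adj, [0.01, 0.018])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        adj = holm_correction(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_correction([0.5, 1.5])


class TestComparePredictors:
    def _frames(self, n_per_group=8, seed=0):
        rng = np.random.default_rng(seed)
        rows_m, rows_d, rows_s, rows_v = [], [], [], []
        for group, relhet in (("OB", 1.0), ("Low", 0.85), ("Medium", 0.7), ("High", 0.5)):
            for i in range(n_per_group):
                lid = f"{group}{i}"
                rh = relhet + rng.normal(0, 0.05)
                rows_m.append({"line_id": lid, "group": group, "extinction_gen": -1})
                rows_d.append({"line_id": lid, "pi_relative": rh, "pi_sum": 100 * rh, "n_snps": 100})
                rows_s.append({"line_id": lid, "trait": "productivity",
                               "slope": 0.2 * rh + rng.normal(0, 0.02)})
                rows_v.append({"line_id": lid, "medium": "stress",
                               "delta": 0.3 * rh + rng.normal(0, 0.03)})
        return (pd.DataFrame(rows_s), pd.DataFrame(rows_v),
                pd.DataFrame(rows_d), pd.DataFrame(rows_m))

    def test_diversity_coupled_response_favours_pi(self):
        s, v, d, m = self._frames()
        rep = compare_predictors(s, v, d, m)["comparison"]
        piv = rep.set_index(["response", "predictor"])["r_squared"]
        assert piv[("slope_productivity", "pi")] > piv[("slope_productivity", "F")]

    def test_refuses_tiny_cohorts(self):
        s, v, d, m = self._frames(n_per_group=2)
        with pytest.raises(ValueError, match="eligible"):
            compare_predictors(s, v, d, m)

    def test_rank_productivity_option(self):
        """Spearman-style rank transform leaves the panel well-formed and
        keeps the diversity-coupled ordering."""
        s, v, d, m = self._frames(seed=3)
        rep = compare_predictors(s, v, d, m, rank_productivity=True)["comparison"]
        piv = rep.set_index(["response", "predictor"])
        assert 0 <= piv.loc[("slope_productivity", "pi"), "r_squared"] <= 1
        assert (
            piv.loc[("slope_productivity", "pi"), "r_squared"]
            > piv.loc[("slope_productivity", "F"), "r_squared"]
        )

    def test_family_size_inflates_holm(self):
        s, v, d, m = self._frames(seed=4)
        small = compare_predictors(s, v, d, m)["contrasts"]
        big = compare_predictors(s, v, d, m, family_size=66)["contrasts"]
        assert (big["p_holm"] >= small["p_holm"] - 1e-15).all()

    def test_contrast_table_structure(self):
        s, v, d, m = self._frames()
        con = compare_predictors(s, v, d, m)["contrasts"]
        assert set(con["contrast"]) >= {"OB_vs_Low", "OB_vs_Medium", "OB_vs_High"}
        assert (con["p_holm"] >= con["p"] - 1e-15).all()
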