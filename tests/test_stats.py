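"""First-principles statistics against independent oracles.

Oracles: extended-precision textbook formulas and scipy/statsmodels
reference implementations for Welch/Pearson, exact combinatorial
enumeration (math.comb rationals) for Fisher, and explicit projection
matrices for the ANOVA decomposition.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ploidyflux.stats import (
    anova_two_way,
    fisher_exact_2x2,
    linear_regression_f,
    partial_correlation,
    welch_t,
)


def fisher_oracle(table):
    """Brute-force two-sided Fisher p by exact rational enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2

    def prob(k):
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(N, c1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return float(sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs))


class TestWelchT:
    def test_identical_samples_null(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_formula_high_precision(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = welch_t(x, y)
        # independent evaluation of the defining formulas
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / 3 + vy / 6
        t_ref = (x.mean() - y.mean()) / math.sqrt(se2)
        df_ref = se2**2 / ((vx / 3) ** 2 / 2 + (vy / 6) ** 2 / 5)
        assert res.statistic == pytest.approx(t_ref, abs=1e-10)
        assert res.df == pytest.approx(df_ref, abs=1e-10)
        # cross-check against scipy's reference implementation
        t_sp, p_sp = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(t_sp, abs=1e-12)
        assert res.p_value == pytest.approx(p_sp, abs=1e-12)

    def test_one_sided_is_half_two_sided_in_favored_tail(self, rng):
        x = rng.normal(1.0, 1.0, 10)
        y = rng.normal(0.0, 1.0, 12)
        two = welch_t(x, y, "two")
        if two.statistic > 0:
            one = welch_t(x, y, "greater")
        else:
            one = welch_t(x, y, "less")
        assert one.p_value == pytest.approx(two.p_value / 2, rel=1e-12)

    def test_equal_variance_equal_n_approaches_pooled_df(self, rng):
        x = rng.normal(0, 1, 50)
        y = x + 1e-9 * rng.normal(0, 1, 50)  # near-identical spread
        res = welch_t(x, y)
        assert res.df == pytest.approx(98, abs=0.1)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestPartialCorrelation:
    def test_perfect_dependence(self, rng):
        x = rng.normal(0, 1, 30)
        z = rng.normal(0, 1, 30)
        res = partial_correlation(x, x.copy(), z)
        assert res.estimate == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_conditional_independence_construction(self, rng):
        n = 10000
        z = rng.normal(0, 1, n)
        x = z + rng.normal(0, 1, n)
        y = z + rng.normal(0, 1, n)
        res = partial_correlation(x, y, z)
        assert abs(res.estimate) < 3 / math.sqrt(n)
        # without the control, x and y are strongly correlated
        raw = partial_correlation(x, y)
        assert raw.estimate > 0.3

    def test_no_controls_reduces_to_pearson(self, rng):
        x = rng.normal(0, 1, 25)
        y = 0.5 * x + rng.normal(0, 1, 25)
        res = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.estimate == pytest.approx(r_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_collinear_controls_rejected(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        z = rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, y, np.column_stack([z, 2 * z]))


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_diagonal_table_matches_enumeration(self):
        res = fisher_exact_2x2([[3, 0], [0, 3]])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.p_value == pytest.approx(fisher_oracle([[3, 0], [0, 3]]), abs=1e-12)

    def test_transpose_invariance(self, rng):
        for _ in range(20):
            t = rng.integers(1, 12, (2, 2))
            assert fisher_exact_2x2(t).p_value == pytest.approx(
                fisher_exact_2x2(t.T).p_value, abs=1e-12
            )

    def test_all_margins_up_to_twelve_match_enumeration(self):
        # full sweep over small tables: implementation (hypergeom pmf sums)
        # vs exact rational enumeration
        count = 0
        for a, b, c, d in itertools.product(range(0, 7), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            if max(a + b, c + d, a + c, b + d) > 12:
                continue
            tbl = [[a, b], [c, d]]
            assert fisher_exact_2x2(tbl).p_value == pytest.approx(
                fisher_oracle(tbl), abs=1e-10
            )
            count += 1
        assert count > 500

    def test_one_sided_matches_scipy(self, rng):
        for _ in range(10):
            t = rng.integers(1, 10, (2, 2))
            for tail, alt in (("greater", "greater"), ("less", "less")):
                _, p_ref = sps.fisher_exact(t, alternative=alt)
                assert fisher_exact_2x2(t, tail).p_value == pytest.approx(p_ref, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 3]])


class TestLinearRegressionF:
    def test_exact_fit_flagged(self):
        x = np.arange(10.0)
        res = linear_regression_f(x, 2 * x + 1)
        assert res.note == "exact fit"
        assert res.p_value == 0.0
        assert res.estimate == pytest.approx(2.0)

    def test_slope_recovery(self, rng):
        x = np.linspace(0, 10, 50)
        y = 2 * x + rng.normal(0, 1e-6, 50)
        assert linear_regression_f(x, y).estimate == pytest.approx(2.0, abs=1e-6)

    def test_f_equals_t_squared(self, rng):
        x = rng.normal(0, 1, 40)
        y = 0.3 * x + rng.normal(0, 1, 40)
        res = linear_regression_f(x, y)
        # slope t-test from the classical formulas
        n = x.size
        xc = x - x.mean()
        slope = float(xc @ (y - y.mean()) / (xc @ xc))
        resid = (y - y.mean()) - slope * xc
        s2 = float(resid @ resid) / (n - 2)
        t_slope = slope / math.sqrt(s2 / float(xc @ xc))
        assert res.statistic == pytest.approx(t_slope**2, rel=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_regression_f(np.ones(5), np.arange(5.0))


class TestAnovaTwoWay:
    @staticmethod
    def _balanced(rng, n_cell=5, effects=True):
        levels_a = ["x", "y"]
        levels_b = ["u", "v", "w"]
        rows = []
        for a in levels_a:
            for b in levels_b:
                for _ in range(n_cell):
                    mu = 0.0
                    if effects:
                        mu = (1.0 if a == "y" else 0.0) + {"u": 0, "v": 0.5, "w": 1.0}[b]
                    rows.append((a, b, mu + rng.normal(0, 1)))
        df = pd.DataFrame(rows, columns=["A", "B", "y"])
        return df

    def test_constant_response_all_null(self):
        y = np.ones(20)
        A = np.repeat(["a", "b"], 10)
        B = np.tile(np.repeat(["u", "v"], 5), 2)
        out = anova_two_way(y, A, B)
        terms = out[out["term"] != "residual"]
        assert np.allclose(terms["F"], 0.0)
        assert np.allclose(terms["p"], 1.0)

    def test_additive_construction_zero_interaction(self):
        A = np.repeat(["a", "b"], 10)
        B = np.tile(np.repeat(["u", "v"], 5), 2)
        y = (A == "b") * 2.0 + (B == "v") * 3.0
        out = anova_two_way(y, A, B)
        ss_ab = out.loc[out["term"] == "A:B", "ss"].iloc[0]
        assert ss_ab == pytest.approx(0.0, abs=1e-10)

    def test_matches_projection_matrix_decomposition(self, rng):
        # oracle: explicit hat-matrix sums of squares on the balanced design
        df = self._balanced(rng)
        y = df["y"].to_numpy()
        A = pd.get_dummies(df["A"], drop_first=False).to_numpy(float)
        B = pd.get_dummies(df["B"], drop_first=False).to_numpy(float)
        AB = np.einsum("ni,nj->nij", A, B).reshape(len(df), -1)

        def proj(X):
            return X @ np.linalg.pinv(X.T @ X) @ X.T

        n = len(df)
        one = np.ones((n, 1))
        P0, PA, PB, PAB = proj(one), proj(A), proj(B), proj(AB)
        ss_a = float(y @ (PA - P0) @ y)
        ss_b = float(y @ (PB - P0) @ y)
        ss_ab = float(y @ (PAB - PA - PB + P0) @ y)
        ss_res = float(y @ (np.eye(n) - PAB) @ y)

        out = anova_two_way(df["y"], df["A"], df["B"]).set_index("term")
        assert out.loc["A", "ss"] == pytest.approx(ss_a, abs=1e-8)
        assert out.loc["B", "ss"] == pytest.approx(ss_b, abs=1e-8)
        assert out.loc["A:B", "ss"] == pytest.approx(ss_ab, abs=1e-8)
        assert out.loc["residual", "ss"] == pytest.approx(ss_res, abs=1e-8)
        # F ratios from the oracle SS
        ms_res = ss_res / out.loc["residual", "df"]
        assert out.loc["A", "F"] == pytest.approx(
            (ss_a / out.loc["A", "df"]) / ms_res, rel=1e-8
        )

    def test_unbalanced_rejected(self, rng):
        df = self._balanced(rng)
        df = df.iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            anova_two_way(df["y"], df["A"], df["B"])

    def test_p_values_in_unit_interval(self, rng):
        df = self._balanced(rng, effects=False)
        out = anova_two_way(df["y"], df["A"], df["B"])
        terms = out[out["term"] != "residual"]
        assert np.all((terms["p"] >= 0) & (terms["p"] <= 1))
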