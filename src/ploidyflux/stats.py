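"""Inferential procedures used on the assay outputs, from first principles.

Everything here is computed directly from the defining formulas (with
scipy supplying only the reference distributions), so each procedure can
be checked against an independent oracle: Welch's t with Satterthwaite
degrees of freedom, partial correlation via residual-on-residual Pearson
correlation, Fisher's exact 2x2 test by hypergeometric enumeration with
the probability-ordering two-sided rule, the simple-regression F test,
and balanced two-way ANOVA with sequential sums of squares.

No multiple-testing correction is applied anywhere; callers that run
families of tests should note that in their reports.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import TestResult

__all__ = [
    "welch_t",
    "partial_correlation",
    "fisher_exact_2x2",
    "linear_regression_f",
    "anova_two_way",
]

_TAILS = ("two", "greater", "less")


def _t_pvalue(t: float, df: float, tail: str) -> float:
    if tail == "two":
        return float(2.0 * sps.t.sf(abs(t), df))
    if tail == "greater":
        return float(sps.t.sf(t, df))
    if tail == "less":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"tail must be one of {_TAILS}")


def welch_t(x, y, tail: str = "two") -> TestResult:
    """Welch two-sample t-test (unequal variances, Satterthwaite df).

    ``estimate`` is the mean difference x - y. With df = 1 designs (two
    replicates per group) the test runs but carries a low-power note.
    Zero variance in both samples gives t = 0, p = 1 when the means agree
    and is an error otherwise (the statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = float(x.mean() - y.mean())
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if diff == 0.0:
            return TestResult(0.0, float(nx + ny - 2), 1.0, tail, 0.0,
                              note="zero variance; identical means")
        raise ValueError("zero variance with unequal means: t undefined")
    t = diff / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    note = "df <= 1: very low power" if df <= 1.0 + 1e-9 else ""
    return TestResult(float(t), float(df), _t_pvalue(t, df, tail), tail, diff, note=note)


def _residualise(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(x, y, z=None, tail: str = "two") -> TestResult:
    """Correlation of x and y after removing linear effects of controls z.

    ``z`` is an (n,) or (n, k) array of controls, or None (k = 0), in
    which case this is exactly the Pearson correlation t-test. The
    statistic is t = r * sqrt((n-2-k)/(1-r^2)) with df = n-2-k;
    ``estimate`` is the partial r. Perfectly collinear controls raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if z is None:
        Zc = np.empty((n, 0))
    else:
        Zc = np.asarray(z, dtype=float)
        if Zc.ndim == 1:
            Zc = Zc[:, None]
    k = Zc.shape[1]
    if n < k + 3:
        raise ValueError("need n >= k + 3 observations")
    Z = np.column_stack([np.ones(n), Zc])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear controls")
    rx = _residualise(x, Z)
    ry = _residualise(y, Z)
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise ValueError("zero residual variance; correlation undefined")
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt(df / (1.0 - r**2))
    return TestResult(float(t), float(df), _t_pvalue(t, df, tail), tail, r)


def fisher_exact_2x2(table, tail: str = "two") -> TestResult:
    """Fisher's exact test for a 2x2 count table.

    Conditions on both margins; p-values sum hypergeometric probabilities
    over the support. The two-sided p uses probability ordering (all
    tables at most as probable as the observed one), matching R's
    ``fisher.test``. ``estimate`` is the sample odds ratio; ``statistic``
    and ``df`` report the observed top-left count and the support size.
    """
    tbl = np.asarray(table)
    if tbl.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tbl < 0) or not np.issubdtype(tbl.dtype, np.integer):
        tbl_f = np.asarray(table, dtype=float)
        if np.any(tbl_f < 0) or np.any(tbl_f != np.round(tbl_f)):
            raise ValueError("counts must be non-negative integers")
        tbl = tbl_f.astype(int)
    a, b = int(tbl[0, 0]), int(tbl[0, 1])
    c, d = int(tbl[1, 0]), int(tbl[1, 1])
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin: test undefined")
    N = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, N, c1, r1)
    p_obs = float(sps.hypergeom.pmf(a, N, c1, r1))
    if tail == "two":
        p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    elif tail == "greater":
        p = float(pmf[support >= a].sum())
    elif tail == "less":
        p = float(pmf[support <= a].sum())
    else:
        raise ValueError(f"tail must be one of {_TAILS}")
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return TestResult(float(a), float(support.size - 1), min(p, 1.0), tail, odds)


def linear_regression_f(x, y) -> TestResult:
    """Simple linear regression F-test (df 1, n-2); estimate is the slope.

    An exact fit (zero residual sum of squares) reports p = 0 with the
    note "exact fit" rather than dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_model = float(((fitted - y.mean()) ** 2).sum())
    ss_resid = float(((y - fitted) ** 2).sum())
    df_resid = n - 2
    if ss_total == 0.0:
        return TestResult(0.0, float(df_resid), 1.0, "two", float(beta[1]),
                          note="constant response")
    if ss_resid <= 1e-14 * ss_total:
        return TestResult(math.inf, float(df_resid), 0.0, "two", float(beta[1]),
                          note="exact fit")
    F = ss_model / (ss_resid / df_resid)
    p = float(sps.f.sf(F, 1, df_resid))
    return TestResult(float(F), float(df_resid), p, "two", float(beta[1]))


def anova_two_way(
    response, factor_a, factor_b, interaction: bool = True
) -> pd.DataFrame:
    """Balanced two-way ANOVA with sequential sums of squares.

    Requires every (A, B) cell to hold the same number of observations
    (sequential and marginal sums of squares coincide on balanced
    layouts); unbalanced designs raise with a pointer to a regression
    formulation. Returns a table with one row per term (A, B, optionally
    A:B, residual) carrying df, sum of squares, F and p. A constant
    response yields F = 0, p = 1 for every term.
    """
    y = np.asarray(response, dtype=float)
    A = np.asarray(factor_a)
    B = np.asarray(factor_b)
    if not (y.size == A.size == B.size):
        raise ValueError("response and factors must share one length")
    lev_a, ia = np.unique(A, return_inverse=True)
    lev_b, ib = np.unique(B, return_inverse=True)
    if lev_a.size < 2 or lev_b.size < 2:
        raise ValueError("need >= 2 levels per factor")
    cells = np.zeros((lev_a.size, lev_b.size), dtype=int)
    np.add.at(cells, (ia, ib), 1)
    if cells.min() < 1 or np.unique(cells).size != 1:
        raise ValueError(
            "unbalanced design: fit the equivalent regression model instead"
        )
    n_cell = int(cells[0, 0])
    N = y.size
    grand = y.mean()

    mean_a = np.array([y[ia == i].mean() for i in range(lev_a.size)])
    mean_b = np.array([y[ib == j].mean() for j in range(lev_b.size)])
    cell_mean = np.zeros_like(cells, dtype=float)
    for i in range(lev_a.size):
        for j in range(lev_b.size):
            cell_mean[i, j] = y[(ia == i) & (ib == j)].mean()

    ss_a = float(n_cell * lev_b.size * ((mean_a - grand) ** 2).sum())
    ss_b = float(n_cell * lev_a.size * ((mean_b - grand) ** 2).sum())
    ss_cells = float(n_cell * ((cell_mean - grand) ** 2).sum())
    ss_ab = max(ss_cells - ss_a - ss_b, 0.0)
    ss_total = float(((y - grand) ** 2).sum())
    ss_within = max(ss_total - ss_cells, 0.0)

    terms = [("A", ss_a, lev_a.size - 1), ("B", ss_b, lev_b.size - 1)]
    if interaction:
        terms.append(("A:B", ss_ab, (lev_a.size - 1) * (lev_b.size - 1)))
        ss_res, df_res = ss_within, N - lev_a.size * lev_b.size
    else:
        ss_res = ss_within + ss_ab
        df_res = N - lev_a.size * lev_b.size + (lev_a.size - 1) * (lev_b.size - 1)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (add replication)")
    ms_res = ss_res / df_res

    rows = []
    for name, ss, df in terms:
        if ms_res == 0.0:
            F, p = (0.0, 1.0) if ss <= 1e-12 * max(ss_total, 1.0) else (math.inf, 0.0)
        else:
            F = (ss / df) / ms_res
            p = float(sps.f.sf(F, df, df_res))
        rows.append({"term": name, "df": df, "ss": ss, "F": F, "p": p})
    rows.append({"term": "residual", "df": df_res, "ss": ss_res, "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)
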