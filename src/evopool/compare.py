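"""Comparing diversity against bottleneck history as response predictors.

The headline inference: does measured nucleotide diversity (pi) or the
expected inbreeding coefficient (F) from bottleneck history better
predict a line's evolutionary response?  Each predictor gets a
single-predictor OLS fit (R^2, overall F-test); the two non-nested
models are then embedded in a combined encompassing regression
(response ~ pi + F), and each predictor's added explanatory value is
tested by the Wald / partial-F test for dropping it from the combined
model — for a single linear restriction in OLS the Wald statistic equals
the partial F, which equals the squared coefficient t.  Group contrasts
use Welch's t-tests with Holm step-down ("sequential Bonferroni")
correction; the paired t-test covers before/after viability of the
outbred controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pedigree import EXPECTED_F

__all__ = [
    "RegressionFit",
    "EncompassingResult",
    "WelchResult",
    "ols_fit",
    "encompassing_test",
    "welch_t",
    "paired_t",
    "holm_correction",
    "compare_predictors",
]

#: Condition number above which a design is treated as singular.
_COND_LIMIT = 1e10


@dataclass
class RegressionFit:
    coefficients: np.ndarray  # intercept first
    residual_ss: float
    df_residual: int
    r_squared: float
    f_statistic: float
    p_value: float


@dataclass
class EncompassingResult:
    """Combined fit (response ~ pi + F) with per-predictor drop tests."""

    combined: RegressionFit
    partial_f: dict[str, float]  # predictor -> partial-F for dropping it
    partial_p: dict[str, float]
    df: tuple[int, int]  # (1, n - 3)


@dataclass
class WelchResult:
    t_statistic: float
    df: float
    p_value: float


def _design(predictors: np.ndarray) -> np.ndarray:
    x = np.asarray(predictors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return sm.add_constant(x, has_constant="add")


def ols_fit(response: Sequence[float], predictors: np.ndarray) -> RegressionFit:
    """OLS of a response on one or two predictor columns (plus intercept)."""
    y = np.asarray(response, dtype=float)
    x = _design(predictors)
    if y.size <= x.shape[1]:
        raise ValueError(f"need n > {x.shape[1]} observations, got {y.size}")
    if np.linalg.cond(x) > _COND_LIMIT:
        raise np.linalg.LinAlgError("singular design: collinear predictors")
    fit = sm.OLS(y, x).fit()
    return RegressionFit(
        coefficients=np.asarray(fit.params),
        residual_ss=float(fit.ssr),
        df_residual=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
    )


def encompassing_test(
    response: Sequence[float],
    pi_values: Sequence[float],
    f_values: Sequence[float],
    names: tuple[str, str] = ("pi", "F"),
) -> EncompassingResult:
    """Encompassing-model comparison of two single-predictor models.

    Fits response ~ pi + F and, for each predictor, the partial-F for
    dropping it: (RSS_reduced - RSS_full) / (RSS_full / (n - 3)), on
    df (1, n - 3).
    """
    y = np.asarray(response, dtype=float)
    pi = np.asarray(pi_values, dtype=float)
    f = np.asarray(f_values, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    combined = ols_fit(y, np.column_stack([pi, f]))
    df2 = n - 3
    partial_f, partial_p = {}, {}
    for name, kept in zip(names, (f, pi)):
        reduced = ols_fit(y, kept)
        num = reduced.residual_ss - combined.residual_ss
        fstat = num / (combined.residual_ss / df2)
        partial_f[name] = float(fstat)
        partial_p[name] = float(stats.f.sf(fstat, 1, df2))
    return EncompassingResult(
        combined=combined, partial_f=partial_f, partial_p=partial_p, df=(1, df2)
    )


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t_statistic=float(res.statistic), df=float(res.df), p_value=float(res.pvalue)
    )


def paired_t(before: Sequence[float], after: Sequence[float]) -> tuple[float, int, float]:
    """Paired two-sample t-test: one-sample t on the differences, df = n - 1."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size:
        raise ValueError("paired vectors must have equal length")
    if b.size < 2:
        raise ValueError("need >= 2 pairs")
    d = a - b
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), int(b.size - 1), float(res.pvalue)


def holm_correction(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Holm (1979) step-down adjusted p-values.

    ``m`` is the family size; it may exceed the number of p-values
    supplied (the remaining family members are simply not reported).
    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) p_(j)) in ascending
    order, mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValueError(f"family size {m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum(1.0, (m - np.arange(p.size)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


def _merge_eligible(
    diversity: pd.DataFrame,
    manifest: pd.DataFrame,
    expected_f: Mapping[str, float],
) -> pd.DataFrame:
    """Line-level predictor frame restricted to non-extinct, pi-bearing lines."""
    man = manifest.copy()
    ext = man["extinction_gen"].fillna(-1)
    man["extinct"] = ext.astype(float) > 0
    merged = man.merge(diversity, on="line_id", how="inner")
    merged["expected_f"] = merged["group"].map(expected_f)
    if merged["expected_f"].isna().any():
        missing = sorted(merged.loc[merged["expected_f"].isna(), "group"].unique())
        raise ValueError(f"no expected F for group(s) {missing}")
    return merged[~merged["extinct"]].reset_index(drop=True)


def compare_predictors(
    slopes: pd.DataFrame,
    viability_changes: pd.DataFrame,
    diversity: pd.DataFrame,
    manifest: pd.DataFrame,
    expected_f: Mapping[str, float] | None = None,
    alpha: float = 0.05,
    min_lines: int = 10,
    family_size: int | None = None,
    rank_productivity: bool = False,
) -> dict[str, pd.DataFrame]:
    """Full pi-vs-F comparison report over the eligible lines.

    Eligible lines are those that never went extinct and have a diversity
    estimate.  For each slope trait and each viability medium the report
    carries both single-predictor fits (R^2, overall F on df (1, n-2))
    and the encompassing partial-F of each predictor on df (1, n-3).
    Group contrasts are Welch t-tests of pi across inbreeding levels and
    between extinct and surviving lines, Holm-corrected as one family of
    size ``family_size`` (defaults to the number of contrasts).

    ``rank_productivity=True`` rank-transforms response and predictors for
    the productivity slope before fitting, the linear-model analogue of a
    Spearman correlation (productivity distributions are often skewed).

    Returns {"comparison": ..., "contrasts": ..., "eligible": ...}.
    """
    expected_f = EXPECTED_F if expected_f is None else expected_f
    eligible = _merge_eligible(diversity, manifest, expected_f)
    if len(eligible) < min_lines:
        raise ValueError(
            f"only {len(eligible)} eligible lines (< {min_lines}); refusing "
            "to fit the predictor comparison on so few"
        )

    responses: list[tuple[str, pd.DataFrame]] = []
    for trait, sub in slopes.groupby("trait"):
        responses.append((f"slope_{trait}", sub.rename(columns={"slope": "response"})))
    for medium, sub in viability_changes.groupby("medium"):
        responses.append(
            (f"viability_delta_{medium}", sub.rename(columns={"delta": "response"}))
        )

    rows = []
    for name, sub in responses:
        d = eligible.merge(sub[["line_id", "response"]], on="line_id", how="inner")
        if len(d) < min_lines:
            continue
        y = d["response"].to_numpy()
        pi = d["pi_relative"].to_numpy()
        f = d["expected_f"].to_numpy()
        if rank_productivity and name == "slope_productivity":
            y, pi, f = (stats.rankdata(v) for v in (y, pi, f))
        enc = encompassing_test(y, pi, f)
        for pred, x in (("pi", pi), ("F", f)):
            fit = ols_fit(y, x)
            rows.append(
                {
                    "response": name,
                    "predictor": pred,
                    "n": len(d),
                    "coef": fit.coefficients[1],
                    "r_squared": fit.r_squared,
                    "f_statistic": fit.f_statistic,
                    "df1": 1,
                    "df2": fit.df_residual,
                    "p_value": fit.p_value,
                    "partial_f": enc.partial_f[pred],
                    "partial_df2": enc.df[1],
                    "partial_p": enc.partial_p[pred],
                }
            )
    comparison = pd.DataFrame(rows)

    # Welch contrasts of pi: inbreeding levels vs outbred, extinct vs survived
    man = manifest.copy()
    man["extinct"] = man["extinction_gen"].fillna(-1).astype(float) > 0
    full = man.merge(diversity, on="line_id", how="inner")
    contrasts = []
    ob = full.loc[full["group"] == "OB", "pi_relative"].to_numpy()
    for grp in ("Low", "Medium", "High"):
        vals = full.loc[full["group"] == grp, "pi_relative"].to_numpy()
        if ob.size >= 2 and vals.size >= 2:
            res = welch_t(ob, vals)
            contrasts.append(("OB_vs_" + grp, res))
    ext = full.loc[full["extinct"], "pi_relative"].to_numpy()
    sur = full.loc[~full["extinct"], "pi_relative"].to_numpy()
    if ext.size >= 2 and sur.size >= 2:
        contrasts.append(("extinct_vs_survived", welch_t(ext, sur)))
    cdf = pd.DataFrame(
        {
            "contrast": [c for c, _ in contrasts],
            "t": [r.t_statistic for _, r in contrasts],
            "df": [r.df for _, r in contrasts],
            "p": [r.p_value for _, r in contrasts],
        }
    )
    if len(cdf):
        m = max(len(cdf), family_size) if family_size else len(cdf)
        cdf["p_holm"] = holm_correction(cdf["p"].to_numpy(), m=m)
        cdf["significant"] = cdf["p_holm"] < alpha
    return {"comparison": comparison, "contrasts": cdf, "eligible": eligible}
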