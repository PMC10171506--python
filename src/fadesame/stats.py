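"""Statistical layer: group comparisons, correlations, dependent-correlation
tests, FADE+SAME multiple regressions and Holm-Bonferroni correction.

Group comparisons are independent-samples t tests (Student pooled or Welch),
computable either from raw vectors or from printed summary cells
(mean, SD, n) — the two paths are algebraically identical. The "auto" form
follows the common Levene gate: Welch when Levene's test on the raw data is
significant at .05, pooled otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Printed summary cell of one variable in one group: mean, SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group n must be >= 2")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


def levene_test(*groups) -> tuple[float, float]:
    """Levene's W on absolute deviations from group means, with its F-based p."""
    if len(groups) < 2:
        raise ValueError("Levene's test needs at least 2 groups")
    clean = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[np.isfinite(g)]
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
        clean.append(g)
    w, p = stats.levene(*clean, center="mean")
    return float(w), float(p)


def _t_from_summaries(
    a: GroupSummary, b: GroupSummary, form: str
) -> tuple[float, float]:
    if form == "student":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    elif form == "welch":
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        raise ValueError(f"unknown t-test form: {form!r}")
    if se == 0:
        raise ValueError("zero standard error; groups are degenerate")
    return (a.mean - b.mean) / se, df


def two_sample_t(a, b, form: str = "student") -> tuple[float, float, float]:
    """Independent-samples t test from raw vectors or summary cells.

    ``form`` is "student" (pooled variance), "welch", or "auto" (raw input
    only): Welch whenever Levene's test on the raw data has p < .05.
    Returns (t, df, two-sided p).
    """
    summaries = isinstance(a, GroupSummary) and isinstance(b, GroupSummary)
    if not summaries:
        x = np.asarray(a, dtype=float)
        y = np.asarray(b, dtype=float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if x.size < 2 or y.size < 2:
            raise ValueError("each group needs at least 2 values")
        if form == "auto":
            _, p_lev = levene_test(x, y)
            form = "welch" if p_lev < 0.05 else "student"
        a = GroupSummary(float(x.mean()), float(x.std(ddof=1)), int(x.size))
        b = GroupSummary(float(y.mean()), float(y.std(ddof=1)), int(y.size))
    elif form == "auto":
        raise ValueError("'auto' requires raw data (Levene's test needs them)")
    t, df = _t_from_summaries(a, b, form)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p, pairwise-complete."""
    x, y = _pairwise_complete(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b with two-sided p, pairwise-complete."""
    x, y = _pairwise_complete(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def dependent_r_compare(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Meng-Rosenthal-Rubin z test for two dependent correlations.

    Compares the correlations of two predictors (correlated ``r12`` with
    each other) with a common criterion, both estimated on the same ``n``
    cases:

        z = (atanh(r1) - atanh(r2)) * sqrt((n - 3) / (2 * (1 - r12) * h)),
        h = (1 - f * rbar2) / (1 - rbar2),  rbar2 = (r1^2 + r2^2) / 2,
        f = min(1, (1 - r12) / (2 * (1 - rbar2))).

    Returns (z, two-sided p).
    """
    for r in (r1, r2, r12):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must be in (-1, 1)")
    if n < 4:
        raise ValueError("n must be >= 4")
    rbar2 = (r1**2 + r2**2) / 2.0
    f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt(
        (n - 3) / (2.0 * (1.0 - r12) * h)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class RegressionResult:
    """One multiple-regression model of an outcome on (FADE, SAME)."""

    dependent: str
    n: int
    r_squared: float
    f_value: float
    df1: int
    df2: int
    p_model: float
    coef: dict[str, dict[str, float]]  # per predictor: beta, t, p
    holm_significant: bool | None = None
    n_models_corrected: int | None = None


def fade_same_regression(
    y, fade, same, dependent: str = "outcome", predictors=("fade", "same")
) -> RegressionResult:
    """OLS of an outcome on two imaging scores with intercept.

    Rows with any missing value are dropped (pairwise-complete per model).
    Reports the model F, R-squared and per-coefficient t tests for the
    unique contribution of each score.
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.asarray(fade, float), np.asarray(same, float)])
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[keep], X[keep]
    n = y.size
    if n <= X.shape[1] + 1:
        raise ValueError("too few complete cases for the regression")
    Xc = sm.add_constant(X)
    if np.linalg.cond(Xc) > 1e10:
        raise ValueError("predictors are (nearly) collinear")
    fit = sm.OLS(y, Xc).fit()
    coef = {
        name: {
            "beta": float(fit.params[i + 1]),
            "t": float(fit.tvalues[i + 1]),
            "p": float(fit.pvalues[i + 1]),
        }
        for i, name in enumerate(predictors)
    }
    return RegressionResult(
        dependent=dependent,
        n=int(n),
        r_squared=float(fit.rsquared),
        f_value=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        p_model=float(fit.f_pvalue),
        coef=coef,
    )


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm's step-down correction: (adjusted p values, reject flags).

    Sorted ascending, the i-th smallest p is multiplied by (N - i + 1); the
    adjusted value is the running maximum of these, capped at 1. Rejections
    proceed while the adjusted p stays at or below alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(np.maximum.accumulate(p[order] * (n - np.arange(n))), 1.0)
    adjusted = np.empty(n)
    adjusted[order] = adj_sorted
    reject = adjusted <= alpha
    return adjusted, reject


def holm_correct_models(
    results: list[RegressionResult], alpha: float = 0.05
) -> list[RegressionResult]:
    """Flag each model's Holm-corrected significance within its family."""
    if not results:
        return results
    adjusted, reject = holm_bonferroni([r.p_model for r in results], alpha=alpha)
    for r, rej in zip(results, reject):
        r.holm_significant = bool(rej)
        r.n_models_corrected = len(results)
    return results
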