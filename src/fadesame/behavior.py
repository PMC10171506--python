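"""Behavioral measures: A' recognition performance, n-back corrected hit
rates, and the extreme-outlier exclusion rule.

A' here is the area under the empirical receiver-operating characteristic
traced by cumulative hit and false-alarm rates across the confidence
criteria of a 5-point recognition rating, which equals the pairwise
concordance P(r_old > r_new) + 0.5 * P(r_old = r_new). It is 0.5 at chance
and 1 for perfect separation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def a_prime(ratings: pd.DataFrame) -> float:
    """Empirical ROC area of a recognition rating table.

    ``ratings`` needs columns ``status`` ("old" / "new") and ``rating``
    (integers 1..5, 5 = most confidently old). The ROC is traced by the
    cumulative proportion of old (hits) and new (false alarms) items rated
    at or above criteria 5, 4, 3, 2, closed with the (0, 0) and (1, 1)
    endpoints, and integrated with the trapezoidal rule.
    """
    if "status" not in ratings.columns or "rating" not in ratings.columns:
        raise ValueError("rating table requires 'status' and 'rating' columns")
    status = ratings["status"].to_numpy()
    r = ratings["rating"].to_numpy()
    old = r[status == "old"]
    new = r[status == "new"]
    if old.size == 0 or new.size == 0:
        raise ValueError("need at least one old and one new trial")
    hit = [0.0]
    fa = [0.0]
    for crit in (5, 4, 3, 2):
        hit.append((old >= crit).mean())
        fa.append((new >= crit).mean())
    hit.append(1.0)
    fa.append(1.0)
    return float(np.trapezoid(hit, fa))


def a_prime_concordance(ratings: pd.DataFrame) -> float:
    """Brute-force pairwise-concordance form of A' (the normative identity).

    P(r_old > r_new) + 0.5 * P(r_old = r_new) over all old-new pairs.
    Quadratic in the number of trials; kept as an independent oracle for the
    trapezoidal implementation.
    """
    status = ratings["status"].to_numpy()
    r = ratings["rating"].to_numpy(dtype=float)
    old = r[status == "old"]
    new = r[status == "new"]
    if old.size == 0 or new.size == 0:
        raise ValueError("need at least one old and one new trial")
    diff = old[:, None] - new[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (old.size * new.size))


def corrected_hit_rate(
    hits: int, n_targets: int, false_alarms: int, n_lures: int
) -> float:
    """N-back corrected hit rate: 100 * (hit rate - false-alarm rate).

    May be negative when false alarms outnumber hits proportionally (as
    happens for hard n-back levels in older adults).
    """
    if min(hits, n_targets, false_alarms, n_lures) < 0:
        raise ValueError("counts must be non-negative")
    if n_targets == 0 or n_lures == 0:
        raise ValueError("denominators must be positive")
    return 100.0 * (hits / n_targets - false_alarms / n_lures)


def iqr_outlier_filter(values, factor: float = 3.0) -> np.ndarray:
    """Retained-mask of the extreme-outlier rule x > Q3 + factor*IQR (or < Q1 - ...).

    Quartiles use linear interpolation of order statistics (the common
    "type 7" convention) over the non-missing values; the rule is a strict
    inequality, so with zero IQR nothing is excluded. Missing values pass
    through as retained (they stay missing, they are not excluded). The
    caller applies the filter separately per age group.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise ValueError("need at least 4 non-missing values to form quartiles")
    q1, q3 = np.percentile(x[finite], [25, 75])
    iqr = q3 - q1
    retained = np.ones(x.shape, dtype=bool)
    retained[finite] = ~(
        (x[finite] > q3 + factor * iqr) | (x[finite] < q1 - factor * iqr)
    )
    return retained


def apply_outlier_filter_by_group(
    table: pd.DataFrame,
    variables: list[str],
    group_col: str = "age_group",
    factor: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set extreme outliers to missing, separately per age group.

    Returns the filtered table and a count of exclusions per variable/group.
    """
    out = table.copy()
    records = []
    for g, sub in table.groupby(group_col):
        for var in variables:
            vals = sub[var].to_numpy(dtype=float)
            if np.isfinite(vals).sum() < 4:
                continue
            retained = iqr_outlier_filter(vals, factor=factor)
            n_removed = int((~retained).sum())
            if n_removed:
                idx = sub.index[~retained]
                out.loc[idx, var] = np.nan
            records.append({"age_group": g, "variable": var, "n_excluded": n_removed})
    return out, pd.DataFrame(records)
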