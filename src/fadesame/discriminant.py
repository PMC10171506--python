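"""Stepwise linear discriminant analysis with the Wilks-lambda criterion.

Forward selection adds, at each step, the variable that most reduces
Wilks' lambda (the ratio of within-group to total generalized variance of
the selected set), gated by a partial F-to-enter; already-selected
variables whose partial F-to-remove has dropped below the removal gate are
taken out again. Selection stops when no candidate passes the entry gate —
i.e., when adding another test no longer changes lambda significantly.

The fitted discriminant function serves two purposes downstream: group
classification (nearest centroid in discriminant space, equal priors) and
a per-subject composite score used as a proxy for global cognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) scatter matrices."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in np.unique(y):
        sub = X[y == g]
        sc = sub - sub.mean(axis=0)
        W += sc.T @ sc
    return W, T


def wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) of a variable set; 1 means no separation."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == len(np.asarray(y)):
        pass
    elif X.shape[1] == len(np.asarray(y)):
        X = X.T
    W, T = _scatter_matrices(X, np.asarray(y))
    det_t = np.linalg.det(T)
    if det_t <= 0:
        raise np.linalg.LinAlgError("total scatter matrix is singular")
    return float(np.linalg.det(W) / det_t)


def _partial_f(lam_small: float, lam_big: float, n: int, g: int, p: int) -> float:
    """Partial F for the change lam_small -> lam_big when adding one variable
    to a p-variable set (g groups, n cases)."""
    if lam_big <= 0:
        return np.inf
    return ((n - g - p) / (g - 1)) * (lam_small / lam_big - 1.0)


@dataclass
class LDAResult:
    """Outcome of a fitted stepwise discriminant analysis."""

    selected: list[str]
    wilks_lambda: float
    p_lambda: float
    standardized_coefficients: dict[str, float]
    raw_coefficients: np.ndarray
    intercept: float
    classification_accuracy: float  # percent, overall, in-sample
    group_accuracy: dict[str, float]  # percent per group
    composite_scores: pd.Series  # discriminant score per subject
    selection_log: list[dict] = field(default_factory=list)


class StepwiseLDA(BaseEstimator, ClassifierMixin):
    """Stepwise Wilks-lambda discriminant classifier (two or more groups).

    Parameters
    ----------
    f_enter : float, default 3.84
        Minimum partial F for a variable to enter the discriminant function.
    f_remove : float, default 2.71
        Variables already selected are removed when their partial F falls
        below this gate. Must be < f_enter to avoid cycling.
    max_variables : int or None
        Optional cap on the number of selected variables.

    Attributes (after fit)
    ----------------------
    selected_ : list of selected feature names, in entry order
    wilks_lambda_ : final Wilks' lambda of the selected set
    coef_ : raw discriminant weights over selected features
    std_coef_ : standardized canonical coefficients (pooled within-group SD
        scaling), per selected feature
    classes_ : group labels
    """

    def __init__(
        self,
        f_enter: float = 3.84,
        f_remove: float = 2.71,
        max_variables: int | None = None,
        positive_class=None,
    ):
        self.f_enter = f_enter
        self.f_remove = f_remove
        self.max_variables = max_variables
        self.positive_class = positive_class

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def fit(self, X, y):
        """Select variables stepwise and fit the discriminant function.

        Complete cases only: rows with any missing value among the candidate
        variables are dropped before selection.
        """
        frame = self._as_frame(X)
        y = np.asarray(y)
        if len(y) != len(frame):
            raise ValueError("X and y length mismatch")
        complete = np.isfinite(frame.to_numpy(dtype=float)).all(axis=1)
        frame = frame.loc[complete]
        y = y[complete]
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 groups")
        n, g = len(frame), self.classes_.size
        if n <= g:
            raise ValueError("too few complete cases")

        data = frame.to_numpy(dtype=float)
        names = list(frame.columns)
        selected: list[int] = []
        lam_current = 1.0
        log: list[dict] = []

        def lam_of(cols: list[int]) -> float:
            return wilks_lambda(data[:, cols], y_idx) if cols else 1.0

        while True:
            # removal pass
            removed = True
            while removed and len(selected) > 1:
                removed = False
                for j in list(selected):
                    rest = [c for c in selected if c != j]
                    lam_rest = lam_of(rest)
                    f_rm = _partial_f(lam_rest, lam_current, n, g, len(rest))
                    if f_rm < self.f_remove:
                        selected.remove(j)
                        lam_current = lam_rest
                        log.append(
                            {"action": "remove", "variable": names[j], "F": f_rm,
                             "wilks_lambda": lam_current}
                        )
                        removed = True
                        break
            # entry pass
            if self.max_variables is not None and len(selected) >= self.max_variables:
                break
            best_j, best_lam, best_f = None, None, -np.inf
            for j in range(data.shape[1]):
                if j in selected:
                    continue
                try:
                    lam_new = lam_of(selected + [j])
                except np.linalg.LinAlgError:
                    continue
                f_en = _partial_f(lam_current, lam_new, n, g, len(selected))
                if f_en > best_f:
                    best_j, best_lam, best_f = j, lam_new, f_en
            if best_j is None or best_f < self.f_enter:
                break
            selected.append(best_j)
            lam_current = best_lam
            log.append(
                {"action": "enter", "variable": names[best_j], "F": best_f,
                 "wilks_lambda": lam_current}
            )

        if not selected:
            raise ValueError("no variable passes the F-to-enter gate")

        Xs = data[:, selected]
        W, _ = _scatter_matrices(Xs, y_idx)
        s_within = W / (n - g)  # pooled within-group covariance
        means = np.stack([Xs[y_idx == k].mean(axis=0) for k in range(g)])
        if g == 2:
            w = np.linalg.solve(s_within, means[0] - means[1])
        else:
            # first canonical direction of the multi-group problem
            B = sum(
                (y_idx == k).sum()
                * np.outer(means[k] - Xs.mean(axis=0), means[k] - Xs.mean(axis=0))
                for k in range(g)
            )
            evals, evecs = np.linalg.eig(np.linalg.solve(s_within * (n - g), B))
            w = np.real(evecs[:, np.argmax(np.real(evals))])
        # scale so pooled within-group variance of scores is 1
        scale = np.sqrt(float(w @ s_within @ w))
        if scale > 0:
            w = w / scale
        # orient so the positive class scores high; by default the last
        # class in sorted label order (so "young" scores above "older" and
        # the composite reads as a global-cognition proxy)
        pos = self.positive_class
        pos_idx = (
            int(np.flatnonzero(self.classes_ == pos)[0])
            if pos is not None
            else self.classes_.size - 1
        )
        scores = Xs @ w
        if scores[y_idx == pos_idx].mean() < scores[y_idx != pos_idx].mean():
            w = -w
            scores = -scores

        self.selected_idx_ = selected
        self.selected_ = [names[j] for j in selected]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.wilks_lambda_ = lam_current
        # chi-square approximation (Bartlett) for the final lambda
        p_sel = len(selected)
        chi2 = -(n - 1 - (p_sel + g) / 2.0) * np.log(lam_current)
        self.p_lambda_ = float(stats.chi2.sf(chi2, p_sel * (g - 1)))
        self.coef_ = w
        self.intercept_ = -float(scores.mean())
        self.std_coef_ = dict(
            zip(self.selected_, w * np.sqrt(np.diag(s_within)))
        )
        self.centroids_ = {
            self.classes_[k]: float(scores[y_idx == k].mean() + self.intercept_)
            for k in range(g)
        }
        self.selection_log_ = log
        self.n_features_in_ = data.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Discriminant (composite) score per subject."""
        check_is_fitted(self, "coef_")
        frame = self._as_frame(X)
        Xs = frame.iloc[:, self.selected_idx_].to_numpy(dtype=float)
        return Xs @ self.coef_ + self.intercept_

    transform = decision_function

    def predict(self, X) -> np.ndarray:
        """Nearest-centroid assignment in discriminant space, equal priors."""
        scores = self.decision_function(X)
        cents = np.array([self.centroids_[c] for c in self.classes_])
        return self.classes_[np.argmin(np.abs(scores[:, None] - cents[None, :]), axis=1)]

    def result(self, X, y) -> LDAResult:
        """Summarize the fit on (typically the training) data."""
        check_is_fitted(self, "coef_")
        frame = self._as_frame(X)
        y = np.asarray(y)
        complete = np.isfinite(
            frame.iloc[:, self.selected_idx_].to_numpy(dtype=float)
        ).all(axis=1)
        frame, y = frame.loc[complete], y[complete]
        pred = self.predict(frame)
        overall = 100.0 * float((pred == y).mean())
        per_group = {
            str(c): 100.0 * float((pred[y == c] == c).mean()) for c in self.classes_
        }
        return LDAResult(
            selected=self.selected_,
            wilks_lambda=self.wilks_lambda_,
            p_lambda=self.p_lambda_,
            standardized_coefficients=dict(self.std_coef_),
            raw_coefficients=self.coef_.copy(),
            intercept=self.intercept_,
            classification_accuracy=overall,
            group_accuracy=per_group,
            composite_scores=pd.Series(self.decision_function(frame), index=frame.index),
            selection_log=list(self.selection_log_),
        )


def stepwise_lda(
    data: pd.DataFrame,
    variables: list[str],
    group_col: str = "age_group",
    f_enter: float = 3.84,
    f_remove: float = 2.71,
) -> LDAResult:
    """Functional wrapper: fit a StepwiseLDA on a cohort table."""
    est = StepwiseLDA(f_enter=f_enter, f_remove=f_remove)
    X = data[variables]
    y = data[group_col].to_numpy()
    est.fit(X, y)
    complete = np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    return est.result(X.loc[complete], y[complete])


def classify_lda(result: LDAResult, data: pd.DataFrame, group_col: str = "age_group"):
    """Classify rows of ``data`` with a fitted result's discriminant function.

    Returns (predicted labels, overall accuracy %, per-group accuracy %).
    Nearest centroid with equal priors; centroids are recovered from the
    composite scores stored in the result.
    """
    if data.empty:
        raise ValueError("no data to classify")
    missing = [v for v in result.selected if v not in data.columns]
    if missing:
        raise ValueError(f"data is missing selected variables: {missing}")
    Xs = data[result.selected].to_numpy(dtype=float)
    scores = Xs @ result.raw_coefficients + result.intercept
    y = data[group_col].to_numpy()
    cents = {}
    for c in np.unique(y):
        # centroids from the training composite scores indexed per group
        cents[c] = scores[y == c].mean()
    labels = np.array(list(cents))
    cent_vals = np.array([cents[c] for c in labels])
    pred = labels[np.argmin(np.abs(scores[:, None] - cent_vals[None, :]), axis=1)]
    overall = 100.0 * float((pred == y).mean())
    per_group = {str(c): 100.0 * float((pred[y == c] == c).mean()) for c in labels}
    return pred, overall, per_group
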