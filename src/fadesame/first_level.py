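"""First-level contrasts: novelty and the parametric subsequent-memory effect.

The subsequent-memory contrast weights the response to each novel item by
the subject's later recognition-confidence rating, arcsine-transformed and
mean-centered. The module fits plain ordinary least squares per voxel; no
hemodynamic convolution, autocorrelation modeling or filtering is applied —
the single-value scores consume contrast maps, and map generation upstream
of OLS is out of this package's scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .maps import SubjectContrastMap


def build_parametric_modulator(ratings) -> np.ndarray:
    """Arcsine-transform 5-point ratings and mean-center them.

    The rating r in {1..5} is mapped to arcsin((r - 3) / 2), spreading the
    scale over arcsin's full domain [-1, 1] and weighting the confident ends
    of the scale more strongly than a linear recode would; the resulting
    vector is then centered so the modulator is orthogonal to the constant.
    """
    r = np.asarray(ratings, dtype=float)
    if r.size == 0:
        raise ValueError("ratings must be non-empty")
    if not np.all(np.isin(r, [1, 2, 3, 4, 5])):
        raise ValueError("all ratings must be integers in {1..5}")
    x = np.arcsin((r - 3.0) / 2.0)
    return x - x.mean()


def build_design_matrix(
    conditions, ratings=None, nuisance: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Assemble an encoding-phase design matrix from trial conditions.

    ``conditions`` holds per-trial labels "novel" or "master"; ``ratings``
    (required for the memory contrast) holds the later recognition rating of
    each novel trial's item, aligned with the novel trials in order. Columns:
    const, novel, master, and (if ratings are given) the mean-centered
    arcsine modulator, nonzero on novel trials only.
    """
    cond = np.asarray(conditions)
    novel = (cond == "novel").astype(float)
    master = (cond == "master").astype(float)
    if not novel.any() or not master.any():
        raise ValueError("design requires both novel and master trials")
    cols = {"const": np.ones(len(cond)), "novel": novel, "master": master}
    if ratings is not None:
        ratings = np.asarray(ratings, dtype=float)
        if ratings.shape[0] != int(novel.sum()):
            raise ValueError("one rating per novel trial is required")
        mod = np.zeros(len(cond))
        mod[novel.astype(bool)] = build_parametric_modulator(ratings)
        cols["memory_modulator"] = mod
    design = pd.DataFrame(cols)
    if nuisance is not None:
        design = pd.concat([design, nuisance.reset_index(drop=True)], axis=1)
    return design


def build_novelty_contrast_vector(design: pd.DataFrame) -> np.ndarray:
    """Contrast weights +1 on the novel regressor, -1 on master, 0 elsewhere."""
    for col in ("novel", "master"):
        if col not in design.columns:
            raise ValueError(f"design is missing the '{col}' regressor")
    c = np.zeros(design.shape[1])
    c[design.columns.get_loc("novel")] = 1.0
    c[design.columns.get_loc("master")] = -1.0
    return c


def build_memory_contrast_vector(design: pd.DataFrame) -> np.ndarray:
    """Contrast weight +1 on the parametric memory modulator."""
    if "memory_modulator" not in design.columns:
        raise ValueError("design is missing the 'memory_modulator' regressor")
    c = np.zeros(design.shape[1])
    c[design.columns.get_loc("memory_modulator")] = 1.0
    return c


def fit_voxelwise_glm(
    design: pd.DataFrame,
    data: np.ndarray,
    contrast: np.ndarray,
    subject_id: str = "subject",
    age_group: str = "unknown",
    contrast_name: str = "novelty",
) -> SubjectContrastMap:
    """Fit OLS per voxel and form the contrast's gamma-hat and t maps.

    ``data`` is observations x voxels (a flattened map per time point or
    trial). Per voxel, gamma-hat = c' beta-hat, and
    t = gamma-hat / (s * sqrt(c' (X'X)^-1 c)) with s the residual SD.
    Voxels with zero residual variance yield non-finite t values, which are
    propagated (downstream masks exclude them) rather than zeroed.
    """
    X = np.asarray(design, dtype=float)
    Y = np.asarray(data, dtype=float)
    c = np.asarray(contrast, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("design and data must have the same number of rows")
    if c.shape != (p,):
        raise ValueError("contrast length must equal the number of regressors")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    df = n - rank
    if df < 1:
        raise ValueError("residual degrees of freedom must be >= 1")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # p x voxels
    gamma = c @ beta
    resid = Y - X @ beta
    s2 = (resid**2).sum(axis=0) / df
    # residuals at rounding level of the data are zero residual variance
    scale = (Y**2).mean(axis=0)
    s2 = np.where(s2 <= np.finfo(float).eps ** 1.5 * scale, 0.0, s2)
    cvc = float(c @ xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = gamma / np.sqrt(s2 * cvc)
    return SubjectContrastMap(
        subject_id=subject_id,
        age_group=age_group,
        contrast=contrast_name,
        gamma=gamma,
        t=t,
        df=df,
    )


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial table CSV with columns trial, condition, rating."""
    table = pd.read_csv(path)
    required = {"trial", "condition"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    return table
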