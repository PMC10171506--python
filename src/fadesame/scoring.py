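"""FADE and SAME single-value scores.

Given a young-reference set for a contrast, a subject's maps reduce to:

* FADE = mean t outside J+ minus mean t inside J+ (sums over the analysis
  mask); larger values mean stronger deviation from the prototypical
  young activation pattern.
* SAME = mean over J+ of (gamma - beta_hat) / sigma_hat plus mean over J-
  of (beta_hat - gamma) / sigma_hat; the two terms have opposite sign
  conventions so that reduced activations and reduced deactivations both
  lower the score. Higher values mean higher similarity to the young
  prototype, with each voxel's deviation standardized by the young
  between-subject SD.

The :class:`FadeSameScorer` estimator exposes the same computation in
scikit-learn fit/transform form on masked, flattened map stacks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .grid import BrainGrid
from .maps import SubjectContrastMap
from .reference import ReferenceSet, build_reference

SCORE_COLUMNS = [
    "subject_id",
    "age_group",
    "contrast",
    "fade",
    "same",
    "same_act",
    "same_deact",
    "deact_defined",
]


def fade_score(t_map: np.ndarray, ref: ReferenceSet) -> float:
    """FADE deviation score of one subject's t map against the reference."""
    if ref.v_plus == 0:
        raise ValueError("FADE is undefined with an empty J+")
    mask = ref.grid.analysis_mask
    t = ref.grid.check_map(t_map, "t map")
    if not np.all(np.isfinite(t[mask])):
        raise ValueError("t map contains non-finite values inside the analysis mask")
    outside = mask & ~ref.j_plus
    if not outside.any():
        raise ValueError("analysis mask has no voxels outside J+")
    return float(t[outside].mean() - t[ref.j_plus].mean())


def same_score(gamma_map: np.ndarray, ref: ReferenceSet) -> tuple[float, float, float]:
    """SAME similarity score: (same, activation term, deactivation term).

    When the reference has no significant deactivations (J- empty, flagged at
    build time), the deactivation term is 0 and ``same`` equals the
    activation term.
    """
    gamma = ref.grid.check_map(gamma_map, "gamma map")
    voxels = ref.j_plus | ref.j_minus
    if not np.all(ref.sigma_hat[voxels] > 0):
        raise ValueError("sigma_hat must be positive on all reference voxels")
    act = float(
        ((gamma[ref.j_plus] - ref.beta_hat[ref.j_plus]) / ref.sigma_hat[ref.j_plus]).mean()
    )
    if ref.v_minus > 0:
        deact = float(
            (
                (ref.beta_hat[ref.j_minus] - gamma[ref.j_minus])
                / ref.sigma_hat[ref.j_minus]
            ).mean()
        )
    else:
        deact = 0.0
    return act + deact, act, deact


def score_subject(cmap: SubjectContrastMap, ref: ReferenceSet) -> dict:
    """Score one subject map against a reference; returns a score record row."""
    if cmap.shape != ref.grid.shape:
        raise ValueError(
            f"{cmap.subject_id}: map shape {cmap.shape} does not match "
            f"reference grid {ref.grid.shape}"
        )
    same, act, deact = same_score(cmap.gamma, ref)
    return {
        "subject_id": cmap.subject_id,
        "age_group": cmap.age_group,
        "contrast": cmap.contrast,
        "fade": fade_score(cmap.t, ref),
        "same": same,
        "same_act": act,
        "same_deact": deact,
        "deact_defined": ref.deact_defined,
    }


def score_cohort(
    maps: dict[str, list[SubjectContrastMap]] | list[SubjectContrastMap],
    refs: dict[str, ReferenceSet] | ReferenceSet,
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Score every subject map against its contrast's reference.

    By default young subjects are scored against the full young reference,
    themselves included — the published usage of the scores. With
    ``leave_one_out``, each young subject is scored against a reference
    rebuilt from the remaining young subjects (same threshold parameters).
    """
    if isinstance(maps, list):
        maps = {maps[0].contrast: maps} if maps else {}
    if isinstance(refs, ReferenceSet):
        refs = {refs.contrast: refs}
    rows = []
    for contrast, cmaps in maps.items():
        if contrast not in refs:
            raise KeyError(f"no reference provided for contrast '{contrast}'")
        ref = refs[contrast]
        young = [m for m in cmaps if m.age_group == "young"]
        for cmap in cmaps:
            if leave_one_out and cmap.age_group == "young":
                others = [m for m in young if m.subject_id != cmap.subject_id]
                sub_ref = build_reference(
                    others,
                    ref.grid,
                    alpha=ref.alpha_fwe,
                    k=ref.k_extent,
                    connectivity=ref.connectivity,
                    contrast=contrast,
                )
                rows.append(score_subject(cmap, sub_ref))
            else:
                rows.append(score_subject(cmap, ref))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


class FadeSameScorer(BaseEstimator, TransformerMixin):
    """Scikit-learn estimator computing FADE/SAME scores from map stacks.

    ``fit`` takes the young reference stack; ``transform`` turns any stack
    of subject maps into the four score columns. Maps are passed flattened
    to the analysis mask of ``grid``: ``fit`` accepts an array of shape
    (n_subjects, m) of gamma-hat values (or (n_subjects, 2m), in which case
    the first half is used), and ``transform`` requires shape
    (n_subjects, 2m) with gamma-hat values in the first m columns and
    t values in the second — the FADE score needs t maps, the SAME score
    needs contrast estimates.

    Parameters
    ----------
    grid : BrainGrid
        Common voxel lattice and analysis mask.
    alpha_fwe : float, default 0.05
        Family-wise (Bonferroni) significance level of the reference masks.
    k_extent : int, default 10
        Minimum cluster extent (voxels) of reference-mask components.
    connectivity : int, default 26
        Neighborhood (6, 18 or 26) used for the extent filter.

    Attributes
    ----------
    reference_ : ReferenceSet
        Fitted young-reference masks and summary maps.
    n_features_in_ : int
        Number of masked voxels m.
    """

    def __init__(
        self,
        grid: BrainGrid | None = None,
        alpha_fwe: float = 0.05,
        k_extent: int = 10,
        connectivity: int = 26,
        contrast: str = "novelty",
    ):
        self.grid = grid
        self.alpha_fwe = alpha_fwe
        self.k_extent = k_extent
        self.connectivity = connectivity
        self.contrast = contrast

    def _check_grid(self) -> BrainGrid:
        if self.grid is None:
            raise ValueError("FadeSameScorer requires a BrainGrid")
        return self.grid

    def _split(self, X: np.ndarray, require_t: bool) -> tuple[np.ndarray, np.ndarray | None]:
        grid = self._check_grid()
        m = grid.n_voxels
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_subjects, n_masked_voxels[*2])")
        if X.shape[1] == 2 * m:
            return X[:, :m], X[:, m:]
        if X.shape[1] == m:
            if require_t:
                raise ValueError(
                    "transform requires (n_subjects, 2m) with gamma and t halves"
                )
            return X, None
        raise ValueError(
            f"X has {X.shape[1]} columns; expected {m} (gamma) or {2 * m} (gamma|t)"
        )

    def fit(self, X, y=None):
        """Build the young reference from a stack of young gamma-hat rows."""
        grid = self._check_grid()
        gamma, _ = self._split(X, require_t=False)
        young_maps = [
            SubjectContrastMap(
                subject_id=f"ref-{i:03d}",
                age_group="young",
                contrast=self.contrast,
                gamma=grid.unmask(row),
                t=grid.unmask(row),
            )
            for i, row in enumerate(gamma)
        ]
        self.reference_ = build_reference(
            young_maps,
            grid,
            alpha=self.alpha_fwe,
            k=self.k_extent,
            connectivity=self.connectivity,
            contrast=self.contrast,
        )
        self.n_features_in_ = grid.n_voxels
        return self

    def transform(self, X) -> np.ndarray:
        """Score subject rows; returns (n_subjects, 4): fade, same, same_act, same_deact."""
        check_is_fitted(self, "reference_")
        grid = self._check_grid()
        gamma, t = self._split(X, require_t=True)
        out = np.empty((gamma.shape[0], 4))
        for i in range(gamma.shape[0]):
            same, act, deact = same_score(grid.unmask(gamma[i]), self.reference_)
            out[i] = [
                fade_score(grid.unmask(t[i]), self.reference_),
                same,
                act,
                deact,
            ]
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["fade", "same", "same_act", "same_deact"], dtype=object)

    @staticmethod
    def stack_maps(maps: list[SubjectContrastMap], grid: BrainGrid) -> np.ndarray:
        """Flatten subject maps into the (n_subjects, 2m) gamma|t layout."""
        gamma = np.stack([grid.mask_values(m.gamma) for m in maps])
        t = np.stack([grid.mask_values(m.t) for m in maps])
        return np.hstack([gamma, t])
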