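"""Young-reference construction and voxel-wise group inference.

The reference for the single-value scores is built from the young group's
stack of contrast-estimate maps: a one-sample t map yields the sets J+ and
J- of voxels with significant positive/negative young-group effects
(family-wise error controlled by Bonferroni over analysis-mask voxels, with
a minimum cluster-extent filter), together with the young mean map
(beta-hat) and between-subject SD map (sigma-hat) at every voxel.

Voxel-wise correction is Bonferroni rather than random-field theory: it is
conservative, assumption-free at the smoothness levels simulated here, and
its error control is exactly testable. Cluster-level inference for
score-map regressions uses a permutation null of the maximum cluster size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage, stats

from .grid import BrainGrid
from .maps import SubjectContrastMap


@dataclass
class StatMap:
    """A statistic map (t or z) with its degrees of freedom and grid."""

    values: np.ndarray
    stat: str  # "t" | "z"
    df: float | None
    grid: BrainGrid

    def __post_init__(self) -> None:
        self.values = self.grid.check_map(self.values, "statistic map")

    def one_tailed_p(self, tail: str) -> np.ndarray:
        """Per-voxel one-tailed p values in the requested tail."""
        if tail not in ("positive", "negative"):
            raise ValueError("tail must be 'positive' or 'negative'")
        v = self.values if tail == "positive" else -self.values
        if self.stat == "t":
            return stats.t.sf(v, self.df)
        return stats.norm.sf(v)


@dataclass
class ReferenceSet:
    """Young-group reference masks and summary maps for one contrast."""

    contrast: str
    grid: BrainGrid
    j_plus: np.ndarray  # significant positive young effect
    j_minus: np.ndarray  # significant negative young effect
    beta_hat: np.ndarray  # young mean gamma-hat per voxel
    sigma_hat: np.ndarray  # young between-subject SD per voxel
    alpha_fwe: float = 0.05
    k_extent: int = 10
    connectivity: int = 26
    n_young: int = 0
    deact_defined: bool = True  # False when J- is empty

    def __post_init__(self) -> None:
        self.j_plus = np.asarray(self.j_plus, dtype=bool)
        self.j_minus = np.asarray(self.j_minus, dtype=bool)
        if (self.j_plus & self.j_minus).any():
            raise ValueError("J+ and J- must be disjoint")

    @property
    def v_plus(self) -> int:
        return int(self.j_plus.sum())

    @property
    def v_minus(self) -> int:
        return int(self.j_minus.sum())

    @property
    def v_out(self) -> int:
        """Analysis-mask voxels outside J+ (the v of the FADE deviation term)."""
        return int((self.grid.analysis_mask & ~self.j_plus).sum())

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vols = {
            "j_plus": self.j_plus.astype(np.uint8),
            "j_minus": self.j_minus.astype(np.uint8),
            "beta_hat": self.beta_hat,
            "sigma_hat": self.sigma_hat,
            "analysis_mask": self.grid.analysis_mask.astype(np.uint8),
        }
        for name, vol in vols.items():
            img = nib.Nifti1Image(np.asarray(vol, dtype=np.float64), self.grid.affine)
            nib.save(img, out_dir / f"{name}.nii")
        meta = {
            "contrast": self.contrast,
            "alpha_fwe": float(self.alpha_fwe),
            "k_extent": int(self.k_extent),
            "connectivity": int(self.connectivity),
            "n_young": int(self.n_young),
            "deact_defined": bool(self.deact_defined),
            "v_plus": self.v_plus,
            "v_minus": self.v_minus,
            "v_out": self.v_out,
            "shape": list(self.grid.shape),
            "voxel_size": [float(v) for v in self.grid.voxel_size],
        }
        with open(out_dir / "reference.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, ref_dir: str | Path) -> "ReferenceSet":
        ref_dir = Path(ref_dir)
        with open(ref_dir / "reference.yaml") as fh:
            meta = yaml.safe_load(fh)

        def _vol(name):
            return np.asarray(nib.load(str(ref_dir / f"{name}.nii")).get_fdata())

        mask = _vol("analysis_mask") > 0.5
        affine = nib.load(str(ref_dir / "j_plus.nii")).affine
        grid = BrainGrid(
            tuple(meta["shape"]),
            voxel_size=tuple(meta["voxel_size"]),
            analysis_mask=mask,
            affine=affine,
        )
        return cls(
            contrast=meta["contrast"],
            grid=grid,
            j_plus=_vol("j_plus") > 0.5,
            j_minus=_vol("j_minus") > 0.5,
            beta_hat=_vol("beta_hat"),
            sigma_hat=_vol("sigma_hat"),
            alpha_fwe=meta["alpha_fwe"],
            k_extent=meta["k_extent"],
            connectivity=meta["connectivity"],
            n_young=meta["n_young"],
            deact_defined=meta["deact_defined"],
        )


def one_sample_t_map(
    maps: list[SubjectContrastMap], grid: BrainGrid
) -> tuple[StatMap, np.ndarray, np.ndarray]:
    """One-sample t map of a gamma-hat stack, with mean and SD maps.

    Per voxel, t = mean / (SD / sqrt(n)) with df = n - 1. Voxels with zero
    between-subject variance yield non-finite t values, which are propagated
    for downstream masks to exclude.
    """
    if len(maps) < 2:
        raise ValueError("one-sample t map requires at least 2 subjects")
    stack = np.stack([grid.check_map(m.gamma, m.subject_id) for m in maps])
    n = stack.shape[0]
    beta = stack.mean(axis=0)
    sigma = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / (sigma / np.sqrt(n))
    return StatMap(t, "t", n - 1, grid), beta, sigma


def fwe_voxel_threshold(
    stat: StatMap, alpha: float, n_tests: int, tail: str
) -> np.ndarray:
    """Bonferroni-corrected voxel threshold: keep p <= alpha / n_tests.

    ``n_tests`` is normally the number of analysis-mask voxels. NaN
    statistic values (undefined, e.g. 0/0) never pass; infinite values count
    as maximally significant in their tail (a zero-variance voxel with a
    nonzero mean). The boundary is inclusive (p equal to the corrected level
    is kept).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p = stat.one_tailed_p(tail)
    keep = np.zeros(stat.grid.shape, dtype=bool)
    inside = stat.grid.analysis_mask & ~np.isnan(stat.values)
    keep[inside] = p[inside] <= alpha / n_tests
    return keep


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def extent_filter(mask: np.ndarray, k: int, connectivity: int = 26) -> np.ndarray:
    """Drop connected components smaller than ``k`` voxels."""
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if k == 1 or not mask.any():
        return mask.copy()
    labels, n_comp = ndimage.label(mask, structure=_connectivity_structure(connectivity))
    if n_comp == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep_labels = np.flatnonzero(sizes >= k)
    keep_labels = keep_labels[keep_labels > 0]
    return np.isin(labels, keep_labels)


def build_reference(
    young_maps: list[SubjectContrastMap],
    grid: BrainGrid,
    alpha: float = 0.05,
    k: int = 10,
    connectivity: int = 26,
    contrast: str | None = None,
) -> ReferenceSet:
    """Build J+/J- masks and young summary maps from the young gamma stack.

    J+ (J-) collects voxels with a significant positive (negative) one-sample
    effect at the Bonferroni-corrected level ``alpha``, filtered to connected
    components of at least ``k`` voxels. An empty J+ is an error (the FADE
    deviation score is undefined without a reference activation set); an
    empty J- only raises a warning and flags the deactivation term as
    undefined, since the activation-based information remains valid.
    """
    contrast = contrast or (young_maps[0].contrast if young_maps else "unknown")
    stat, beta, sigma = one_sample_t_map(young_maps, grid)
    n_tests = grid.n_voxels
    j_plus = extent_filter(
        fwe_voxel_threshold(stat, alpha, n_tests, "positive"), k, connectivity
    )
    j_minus = extent_filter(
        fwe_voxel_threshold(stat, alpha, n_tests, "negative"), k, connectivity
    )
    if not j_plus.any():
        raise ValueError(
            "no significant positive young-group voxels survive thresholding; "
            "the FADE score is undefined without J+"
        )
    deact_defined = bool(j_minus.any())
    if not deact_defined:
        warnings.warn(
            "no significant negative young-group voxels; SAME deactivation "
            "term will be 0 and flagged undefined",
            stacklevel=2,
        )
    return ReferenceSet(
        contrast=contrast,
        grid=grid,
        j_plus=j_plus,
        j_minus=j_minus,
        beta_hat=beta,
        sigma_hat=sigma,
        alpha_fwe=alpha,
        k_extent=k,
        connectivity=connectivity,
        n_young=len(young_maps),
        deact_defined=deact_defined,
    )


@dataclass
class ClusterResult:
    """One significant cluster from permutation-based cluster inference."""

    size: int
    peak_t: float
    peak_voxel: tuple[int, int, int]
    p_cluster: float


def _regression_t_map(maps_2d: np.ndarray, score_z: np.ndarray) -> np.ndarray:
    """Simple-regression t per voxel of maps on a standardized score."""
    n = maps_2d.shape[0]
    M = maps_2d - maps_2d.mean(axis=0)
    norms = np.sqrt((M**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (score_z @ M) / (norms * np.sqrt((score_z**2).sum()))
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return t


def voxelwise_score_regression(
    maps: list[SubjectContrastMap],
    score: np.ndarray,
    grid: BrainGrid,
    cluster_forming_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_permutations: int = 1000,
    tail: str = "positive",
    connectivity: int = 26,
    seed: int | np.random.Generator | None = 0,
) -> tuple[StatMap, list[ClusterResult]]:
    """Voxel-wise regression of gamma maps on a per-subject score.

    Per voxel, a simple-regression t of gamma-hat on the score. Clusters are
    formed among analysis-mask voxels exceeding the uncorrected
    cluster-forming threshold in the requested tail; family-wise cluster
    significance comes from the permutation null of the maximum cluster
    size, obtained by permuting the score labels across subjects.
    """
    if len(maps) < 3:
        raise ValueError("score regression requires at least 3 subjects")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    score = np.asarray(score, dtype=float)
    if score.shape != (len(maps),):
        raise ValueError("one score per subject is required")
    if np.ptp(score) == 0:
        raise ValueError("score vector is constant; regression is degenerate")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    n = len(maps)
    df = n - 2
    mask = grid.analysis_mask
    maps_2d = np.stack([grid.check_map(m.gamma)[mask] for m in maps])
    sc = score - score.mean()

    t_masked = _regression_t_map(maps_2d, sc)
    t_vol = grid.unmask(t_masked, fill=np.nan)
    stat = StatMap(np.nan_to_num(t_vol, nan=0.0), "t", df, grid)

    t_thresh = stats.t.isf(cluster_forming_p, df)
    signed = t_masked if tail == "positive" else -t_masked

    structure = _connectivity_structure(connectivity)

    def _cluster_sizes(sig_masked: np.ndarray) -> np.ndarray:
        vol = np.zeros(grid.shape, dtype=bool)
        vol[mask] = sig_masked
        labels, n_comp = ndimage.label(vol, structure=structure)
        if n_comp == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(labels.ravel())[1:]

    # permutation null of the maximum cluster size
    perm_idx = np.stack([rng.permutation(n) for _ in range(n_permutations)])
    perm_t = np.empty((n_permutations, maps_2d.shape[1]))
    M = maps_2d - maps_2d.mean(axis=0)
    norms = np.sqrt((M**2).sum(axis=0))
    sc_norm = np.sqrt((sc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (sc[perm_idx] @ M) / (norms * sc_norm)
        r = np.clip(r, -1.0, 1.0)
        perm_t = r * np.sqrt(df / (1.0 - r**2))
    if tail == "negative":
        perm_t = -perm_t
    max_null = np.zeros(n_permutations, dtype=int)
    for b in range(n_permutations):
        sizes = _cluster_sizes(perm_t[b] > t_thresh)
        max_null[b] = sizes.max() if sizes.size else 0

    # observed clusters with permutation p values
    obs_vol = np.zeros(grid.shape, dtype=bool)
    obs_vol[mask] = signed > t_thresh
    labels, n_comp = ndimage.label(obs_vol, structure=structure)
    clusters: list[ClusterResult] = []
    peak_map = stat.values if tail == "positive" else -stat.values
    for lab in range(1, n_comp + 1):
        comp = labels == lab
        size = int(comp.sum())
        p_cl = (1 + int((max_null >= size).sum())) / (1 + n_permutations)
        if p_cl <= cluster_alpha:
            peak_flat = np.argmax(np.where(comp, peak_map, -np.inf))
            peak = np.unravel_index(peak_flat, grid.shape)
            clusters.append(
                ClusterResult(
                    size=size,
                    peak_t=float(stat.values[peak]),
                    peak_voxel=tuple(int(v) for v in peak),
                    p_cluster=p_cl,
                )
            )
    clusters.sort(key=lambda c: -c.size)
    return stat, clusters
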