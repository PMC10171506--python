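"""Synthetic study generator: maps and behavior with known ground truth.

The generator emulates the data structure the scoring pipeline consumes,
at "effective regressor" level (no time series): each subject contributes,
per contrast, a 3D contrast-estimate map built from spatially clustered
activations and deactivations plus Gaussian between-subject noise, and a
t map proportional to it within subject. Older subjects attenuate the
planted activations by a per-subject factor ``alpha`` and reduce the
planted deactivations by ``delta``; a latent memory ability coupled to the
preserved signal (a weighted mean of ``1 - alpha`` and ``1 - delta``)
drives the behavioral tables, so that recovery of the map-behavior
association can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import BrainGrid
from .maps import CONTRASTS, SubjectContrastMap


@dataclass(frozen=True)
class Cluster:
    """Spherical signal cluster on the lattice: center voxel, radius, amplitude."""

    center: tuple[int, int, int]
    radius: float
    amplitude: float


# Group anchors (mean, SD) per age group and the "good performance" direction
# for the 19-variable neuropsychological battery: verbal list learning (VLMT),
# logical-memory story recall (WMS), tonic/phasic alertness RTs, attentional
# flexibility, flanker interference, and n-back working memory. RT and error
# variables point downward (-1): lower is better.
BATTERY_ANCHORS: dict[str, tuple[float, float, float, float, int]] = {
    # name: (young_mean, young_sd, older_mean, older_sd, direction)
    "vlmt_learning_sum": (67.02, 6.09, 53.42, 9.38, +1),
    "vlmt_distractor": (10.14, 2.68, 6.36, 2.02, +1),
    "vlmt_recall_a": (14.47, 1.02, 11.32, 2.84, +1),
    "vlmt_recall_30min": (14.44, 1.09, 11.43, 2.88, +1),
    "vlmt_recall_1day": (13.94, 1.49, 9.26, 3.43, +1),
    "wms_immediate": (31.35, 7.32, 25.45, 6.27, +1),
    "wms_recall_30min": (29.85, 7.99, 22.99, 6.58, +1),
    "wms_recall_1day": (29.21, 7.77, 21.93, 6.83, +1),
    "alertness_tone_rt": (249.91, 29.71, 295.54, 54.87, -1),
    "alertness_no_tone_rt": (276.28, 30.40, 329.74, 58.40, -1),
    "flexibility_error_rate": (4.42, 4.62, 11.25, 13.19, -1),
    "flexibility_rt": (1146.73, 264.59, 2006.76, 575.52, -1),
    "flanker_rt_diff": (111.26, 52.52, 213.37, 133.95, -1),
    "nback1_corrected_hit_rate": (97.45, 4.63, 89.65, 18.16, +1),
    "nback1_rt": (433.17, 54.23, 490.50, 86.10, -1),
    "nback2_corrected_hit_rate": (65.29, 28.39, 20.35, 37.47, +1),
    "nback2_rt": (588.91, 100.65, 663.39, 108.36, -1),
    "nback3_corrected_hit_rate": (23.67, 34.40, -11.77, 31.03, +1),
    "nback3_rt": (630.91, 118.27, 708.45, 150.52, -1),
}

#: memory-related variables, loaded more strongly on the latent ability
MEMORY_VARIABLES = (
    "vlmt_learning_sum",
    "vlmt_distractor",
    "vlmt_recall_a",
    "vlmt_recall_30min",
    "vlmt_recall_1day",
    "wms_immediate",
    "wms_recall_30min",
    "wms_recall_1day",
)


def _default_activation_clusters() -> list[Cluster]:
    # two "temporo-occipital" activation spheres
    return [
        Cluster((6, 6, 8), 3.0, 1.0),
        Cluster((14, 13, 7), 2.5, 0.8),
    ]


def _default_deactivation_clusters() -> list[Cluster]:
    # one "midline" deactivation sphere (DMN-like), as strong as the
    # activations: encoding-related DMN deactivations are prominent effects
    return [Cluster((10, 10, 13), 3.0, -1.0)]


@dataclass
class CohortSpec:
    """Parameters of one synthetic study.

    Defaults mirror the cross-sectional study design the pipeline targets:
    a young reference group and a combined middle-aged/older target group
    (106 and 153 subjects), with cluster amplitudes about one between-subject
    noise SD and moderate, variable attenuation in the older group.
    """

    n_young: int = 106
    n_older: int = 153
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    activation_clusters: list[Cluster] = field(
        default_factory=_default_activation_clusters
    )
    deactivation_clusters: list[Cluster] = field(
        default_factory=_default_deactivation_clusters
    )
    noise_sd: float = 1.0
    t_dof: int = 100  # residual df used to synthesize per-subject t scale
    attenuation_mean: float = 0.35
    attenuation_sd: float = 0.20
    deactivation_reduction_mean: float = 0.45
    deactivation_reduction_sd: float = 0.20
    behavior_coupling: float = 1.0
    deactivation_coupling: float = 1.0
    ability_noise_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_young < 1 or self.n_older < 0:
            raise ValueError("cohort sizes must be positive")
        if not self.activation_clusters:
            raise ValueError("at least one activation cluster is required")
        for c in self.activation_clusters:
            if c.amplitude <= 0:
                raise ValueError("activation cluster amplitudes must be > 0")
        for c in self.deactivation_clusters:
            if c.amplitude >= 0:
                raise ValueError("deactivation cluster amplitudes must be < 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.t_dof < 1:
            raise ValueError("t_dof must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["activation_clusters"] = [asdict(c) for c in self.activation_clusters]
        d["deactivation_clusters"] = [asdict(c) for c in self.deactivation_clusters]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for key in ("activation_clusters", "deactivation_clusters"):
            if key in d and d[key] is not None:
                d[key] = [
                    Cluster(tuple(c["center"]), float(c["radius"]), float(c["amplitude"]))
                    if isinstance(c, dict)
                    else Cluster(tuple(c[0]), float(c[1]), float(c[2]))
                    for c in d[key]
                ]
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class SubjectRecord:
    """Ground truth for one simulated subject."""

    subject_id: str
    age_group: str  # "young" | "older"
    latent_ability: float
    alpha: float = 0.0  # activation attenuation (older only)
    delta: float = 0.0  # deactivation reduction (older only)


def cluster_template(grid: BrainGrid, clusters: Sequence[Cluster]) -> np.ndarray:
    """Sum of spherical clusters rendered on the lattice (amplitudes add)."""
    vol = np.zeros(grid.shape)
    idx = np.indices(grid.shape)
    for c in clusters:
        dist2 = sum((idx[a] - c.center[a]) ** 2 for a in range(3))
        vol[dist2 <= c.radius**2] += c.amplitude
    return vol


def _truncated_normal(rng, mean, sd, size, low=0.0, high=1.0):
    if sd <= 0:
        return np.full(size, np.clip(mean, low, high))
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _jitter_clusters(clusters, grid_shape, rng, max_shift=2):
    """Independently drawn geometry for the second contrast: shift centers."""
    out = []
    for c in clusters:
        shift = rng.integers(-max_shift, max_shift + 1, size=3)
        center = tuple(
            int(np.clip(c.center[a] + shift[a], 0, grid_shape[a] - 1)) for a in range(3)
        )
        out.append(Cluster(center, c.radius, c.amplitude))
    return out


def generate_cohort(
    spec: CohortSpec,
) -> tuple[BrainGrid, dict[str, list[SubjectContrastMap]], list[SubjectRecord]]:
    """Simulate the full imaging cohort for both contrasts.

    Returns the grid, a dict mapping contrast name ("novelty", "memory") to
    the list of per-subject maps (young first, then older), and the ground
    truth records. Young maps are template + noise; an older subject's map is
    ``(1 - alpha_i) * activations + (1 - delta_i) * deactivations + noise``.
    Each subject's t map is the gamma map divided by a per-subject residual
    noise-scale estimate (chi-distributed around ``noise_sd`` with ``t_dof``
    degrees of freedom), so t and gamma are proportional within subject.
    """
    spec.validate()
    grid = BrainGrid(spec.grid_shape)

    ss = np.random.SeedSequence(spec.seed)
    rng_geom, rng_truth, rng_maps = [np.random.default_rng(s) for s in ss.spawn(3)]

    # ground truth: attenuation parameters and latent ability
    alphas = _truncated_normal(
        rng_truth, spec.attenuation_mean, spec.attenuation_sd, spec.n_older
    )
    deltas = _truncated_normal(
        rng_truth,
        spec.deactivation_reduction_mean,
        spec.deactivation_reduction_sd,
        spec.n_older,
    )
    records: list[SubjectRecord] = []
    n_total = spec.n_young + spec.n_older
    width = max(3, len(str(n_total)))
    ability_noise = rng_truth.normal(0.0, spec.ability_noise_sd, size=n_total)
    # latent ability tracks preserved activation (1 - alpha) and, weighted by
    # deactivation_coupling, preserved deactivation (1 - delta): reduced DMN
    # suppression carries behavioral information of its own
    w_d = spec.deactivation_coupling
    for i in range(spec.n_young):
        records.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:0{width}d}",
                age_group="young",
                latent_ability=spec.behavior_coupling * 1.0 + ability_noise[i],
            )
        )
    for i in range(spec.n_older):
        preserved = ((1.0 - alphas[i]) + w_d * (1.0 - deltas[i])) / (1.0 + w_d)
        records.append(
            SubjectRecord(
                subject_id=f"sub-{spec.n_young + i + 1:0{width}d}",
                age_group="older",
                latent_ability=spec.behavior_coupling * preserved
                + ability_noise[spec.n_young + i],
                alpha=float(alphas[i]),
                delta=float(deltas[i]),
            )
        )

    # per-contrast cluster geometry: the memory contrast gets independently
    # (but reproducibly) jittered copies of the novelty geometry
    geometry = {
        "novelty": (spec.activation_clusters, spec.deactivation_clusters),
        "memory": (
            _jitter_clusters(spec.activation_clusters, grid.shape, rng_geom),
            _jitter_clusters(spec.deactivation_clusters, grid.shape, rng_geom),
        ),
    }

    maps: dict[str, list[SubjectContrastMap]] = {}
    for contrast in CONTRASTS:
        act_clusters, deact_clusters = geometry[contrast]
        act = cluster_template(grid, act_clusters)
        deact = cluster_template(grid, deact_clusters)
        contrast_maps = []
        for rec in records:
            signal = (1.0 - rec.alpha) * act + (1.0 - rec.delta) * deact
            noise = rng_maps.standard_normal(grid.shape) * spec.noise_sd
            gamma = signal + noise
            if spec.noise_sd > 0:
                s_i = spec.noise_sd * np.sqrt(
                    rng_maps.chisquare(spec.t_dof) / spec.t_dof
                )
            else:
                s_i = 1.0
            contrast_maps.append(
                SubjectContrastMap(
                    subject_id=rec.subject_id,
                    age_group=rec.age_group,
                    contrast=contrast,
                    gamma=gamma,
                    t=gamma / s_i,
                    df=spec.t_dof,
                )
            )
        maps[contrast] = contrast_maps
    return grid, maps, records


#: fixed rating criteria of the equal-variance latent-Gaussian rating model
RATING_CRITERIA = (-1.5, -0.5, 0.5, 1.5)


def generate_recognition_ratings(
    record: SubjectRecord,
    n_old: int = 88,
    n_new: int = 44,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a 5-point recognition test (1 = definitely new ... 5 = definitely old).

    Discretized equal-variance latent-Gaussian model with four fixed
    criteria: new items draw memory strength from N(0, 1), old items from
    N(d, 1) with d = max(latent_ability, 0), so zero ability yields identical
    rating distributions for old and new items (A' of 0.5 in expectation).
    """
    if n_old < 1 or n_new < 1:
        raise ValueError("n_old and n_new must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    d = max(float(record.latent_ability), 0.0)
    strength = np.concatenate(
        [rng.normal(d, 1.0, size=n_old), rng.normal(0.0, 1.0, size=n_new)]
    )
    ratings = np.digitize(strength, RATING_CRITERIA) + 1
    return pd.DataFrame(
        {
            "trial": np.arange(n_old + n_new),
            "status": ["old"] * n_old + ["new"] * n_new,
            "rating": ratings.astype(int),
        }
    )


def generate_neuropsych(
    records: Sequence[SubjectRecord],
    spec: CohortSpec | None = None,
    seed: int | np.random.Generator = 0,
    anchors: dict[str, tuple[float, float, float, float, int]] | None = None,
    loadings: dict[str, float] | None = None,
    missing_rate: float = 0.03,
) -> pd.DataFrame:
    """Simulate the neuropsychological battery for a cohort.

    Each variable v is generated per subject i as

        value = mu_gv + sd_gv * (dir_v * rho_v * z_i + sqrt(1 - rho_v^2) * eps)

    where (mu_gv, sd_gv) are the subject's age-group anchors, z_i is the
    subject's latent ability standardized within group, dir_v is +1 for
    accuracy-type and -1 for speed/error-type variables, and rho_v is the
    within-group loading on ability. Group mean offsets therefore come from
    the anchors (young outperform older under the defaults), while
    within-group individual differences track the latent ability that also
    drives map attenuation. Cells go missing independently at
    ``missing_rate``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    anchors = anchors if anchors is not None else BATTERY_ANCHORS
    if loadings is None:
        loadings = {
            name: (0.6 if name in MEMORY_VARIABLES else 0.35) for name in anchors
        }

    groups = np.array([r.age_group for r in records])
    ability = np.array([r.latent_ability for r in records], dtype=float)
    z = np.zeros_like(ability)
    for g in np.unique(groups):
        sel = groups == g
        sd = ability[sel].std(ddof=1) if sel.sum() > 1 else 0.0
        if sd > 0:
            z[sel] = (ability[sel] - ability[sel].mean()) / sd

    data: dict[str, np.ndarray] = {
        "subject_id": np.array([r.subject_id for r in records]),
        "age_group": groups,
    }
    n = len(records)
    for name, (m_y, s_y, m_o, s_o, direction) in anchors.items():
        rho = float(np.clip(loadings.get(name, 0.0), 0.0, 1.0))
        eps = rng.standard_normal(n)
        mu = np.where(groups == "young", m_y, m_o)
        sd = np.where(groups == "young", s_y, s_o)
        values = mu + sd * (direction * rho * z + np.sqrt(1.0 - rho**2) * eps)
        if missing_rate > 0:
            values = values.copy()
            values[rng.random(n) < missing_rate] = np.nan
        data[name] = values
    return pd.DataFrame(data)


def plant_outlier(
    table: pd.DataFrame, variable: str, subject_id: str, factor: float = 4.0
) -> pd.DataFrame:
    """Replace one cell with an extreme high value, Q3 + factor * IQR.

    Used to construct ground-truth extreme outliers for testing the
    downstream interquartile-range exclusion rule (which triggers strictly
    above Q3 + 3 * IQR, so ``factor`` must exceed 3 for the plant to be
    flagged).
    """
    col = table[variable].dropna()
    q1, q3 = np.percentile(col, [25, 75])
    iqr = q3 - q1
    out = table.copy()
    out.loc[out["subject_id"] == subject_id, variable] = q3 + factor * max(iqr, 1.0)
    return out
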