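"""End-to-end pipeline: simulate -> reference -> score -> analyze.

Stages mirror the analysis order of the score-validation study design:
build young-reference masks per contrast, reduce every subject's maps to
FADE/SAME scores, then run the behavioral association battery separately
per age group (group comparisons with Levene-gated t tests, score
intercorrelations with dependent-correlation tests, FADE+SAME multiple
regressions with Holm-Bonferroni correction per family, and the stepwise
LDA yielding a global-cognition composite).

All randomness flows from one root seed with named substreams per stage.
Stage outputs are cached: a completed stage whose configuration has not
changed is skipped on re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import a_prime, apply_outlier_filter_by_group
from .discriminant import stepwise_lda
from .grid import BrainGrid
from .maps import CONTRASTS, read_maps_from_dir, write_map
from .reference import ReferenceSet, build_reference
from .scoring import score_cohort
from .stats import (
    dependent_r_compare,
    fade_same_regression,
    holm_correct_models,
    levene_test,
    pearson_r,
    two_sample_t,
)
from .synthetic import (
    BATTERY_ANCHORS,
    CohortSpec,
    generate_cohort,
    generate_neuropsych,
    generate_recognition_ratings,
)

#: episodic-memory dependent variables of the per-contrast regression family
MEMORY_DEPENDENTS = [
    "a_prime",
    "vlmt_recall_30min",
    "vlmt_recall_1day",
    "wms_recall_30min",
    "wms_recall_1day",
]


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    alpha_fwe: float = 0.05
    k_extent: int = 10
    connectivity: int = 26
    leave_one_out: bool = False
    analysis_alpha: float = 0.05
    f_enter: float = 3.84
    f_remove: float = 2.71
    out_dir: str = "fadesame_run"
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        if self.cohort.n_young < 2:
            raise ValueError("n_young must be >= 2 to build a reference")
        if not 0 < self.alpha_fwe < 1:
            raise ValueError("alpha_fwe must be in (0, 1)")
        if self.k_extent < 1:
            raise ValueError("k_extent must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["version"] = __version__
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d.pop("version", None)
        if "cohort" in d:
            d["cohort"] = CohortSpec.from_dict(d["cohort"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    seed: int
    version: str
    config_digest: str
    stages: dict[str, dict] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)

    def record_stage(self, name: str, started: float, outputs: list[Path]) -> None:
        self.stages[name] = {
            "started": started,
            "finished": time.time(),
            "outputs": [str(p) for p in outputs],
        }
        for p in outputs:
            if Path(p).is_file():
                self.files[str(p)] = _sha256(Path(p))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _stage_done(out_dir: Path, stage: str, digest: str) -> bool:
    marker = out_dir / f".{stage}.done"
    return marker.exists() and marker.read_text().strip() == digest


def _mark_stage(out_dir: Path, stage: str, digest: str) -> None:
    (out_dir / f".{stage}.done").write_text(digest)


def simulate_stage(config: PipelineConfig, out_dir: Path) -> list[Path]:
    """Generate maps and behavioral tables; write NIfTI volumes and CSVs."""
    spec = dataclasses.replace(config.cohort, seed=config.seed)
    grid, maps, records = generate_cohort(spec)

    map_dir = out_dir / "maps"
    outputs: list[Path] = []
    for contrast in CONTRASTS:
        for cmap in maps[contrast]:
            outputs.extend(write_map(cmap, grid, map_dir))

    ss = np.random.SeedSequence([config.seed, 1])
    rng_ratings, rng_psych = [np.random.default_rng(s) for s in ss.spawn(2)]
    behavior = generate_neuropsych(records, spec, seed=rng_psych)
    behavior["a_prime"] = [
        a_prime(generate_recognition_ratings(rec, seed=rng_ratings))
        for rec in records
    ]
    behavior_path = out_dir / "behavior.csv"
    behavior.to_csv(behavior_path, index=False)

    truth = pd.DataFrame(
        [dataclasses.asdict(rec) for rec in records]
    )
    truth_path = out_dir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    outputs.extend([behavior_path, truth_path])
    return outputs


def reference_stage(config: PipelineConfig, out_dir: Path) -> list[Path]:
    """Build and serialize the young reference per contrast."""
    grid, groups = _load_grid_and_groups(config, out_dir)
    outputs = []
    for contrast in CONTRASTS:
        maps = read_maps_from_dir(out_dir / "maps", contrast, grid, groups)
        young = [m for m in maps if m.age_group == "young"]
        ref = build_reference(
            young,
            grid,
            alpha=config.alpha_fwe,
            k=config.k_extent,
            connectivity=config.connectivity,
            contrast=contrast,
        )
        ref_dir = out_dir / f"reference_{contrast}"
        ref.save(ref_dir)
        outputs.extend(sorted(ref_dir.iterdir()))
    return outputs


def score_stage(config: PipelineConfig, out_dir: Path) -> list[Path]:
    """Score every subject against the per-contrast references."""
    grid, groups = _load_grid_and_groups(config, out_dir)
    all_maps = {}
    refs = {}
    for contrast in CONTRASTS:
        all_maps[contrast] = read_maps_from_dir(out_dir / "maps", contrast, grid, groups)
        refs[contrast] = ReferenceSet.load(out_dir / f"reference_{contrast}")
    scores = score_cohort(all_maps, refs, leave_one_out=config.leave_one_out)
    path = out_dir / "scores.csv"
    scores.to_csv(path, index=False)
    return [path]


def _load_grid_and_groups(config: PipelineConfig, out_dir: Path):
    truth = pd.read_csv(out_dir / "ground_truth.csv")
    groups = dict(zip(truth["subject_id"], truth["age_group"]))
    grid = BrainGrid(config.cohort.grid_shape)
    return grid, groups


def scores_wide(scores: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long score table to one row per subject with
    fade_<contrast>, same_<contrast>, same_act_<contrast>, same_deact_<contrast>."""
    wide = scores.pivot(
        index=["subject_id", "age_group"],
        columns="contrast",
        values=["fade", "same", "same_act", "same_deact"],
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    return wide.reset_index()


def _group_comparisons(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    rows = []
    for var in variables:
        young = table.loc[table["age_group"] == "young", var].dropna()
        older = table.loc[table["age_group"] == "older", var].dropna()
        if len(young) < 2 or len(older) < 2:
            continue
        _, p_lev = levene_test(young, older)
        form = "welch" if p_lev < 0.05 else "student"
        t, df, p = two_sample_t(young, older, form=form)
        rows.append(
            {
                "variable": var,
                "young_mean": young.mean(),
                "young_sd": young.std(ddof=1),
                "young_n": len(young),
                "older_mean": older.mean(),
                "older_sd": older.std(ddof=1),
                "older_n": len(older),
                "levene_p": p_lev,
                "form": form,
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _score_correlations(wide: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of the four scores and the
    activation/deactivation component analysis, per age group."""
    score_cols = [f"{s}_{c}" for s in ("fade", "same") for c in CONTRASTS]
    rows = []
    for g, sub in wide.groupby("age_group"):
        for i, a in enumerate(score_cols):
            for b in score_cols[i + 1 :]:
                r, p = pearson_r(sub[a], sub[b])
                rows.append(
                    {"age_group": g, "x": a, "y": b, "r": r, "p": p, "kind": "score"}
                )
        # components: FADE vs SAME activation/deactivation parts, with a
        # dependent-correlation comparison of the two component correlations
        for contrast in CONTRASTS:
            fade = sub[f"fade_{contrast}"]
            act = sub[f"same_act_{contrast}"]
            deact = sub[f"same_deact_{contrast}"]
            if np.ptp(deact.to_numpy()) == 0:
                # deactivation term undefined (empty J-); no component split
                continue
            r_act, p_act = pearson_r(fade, act)
            r_deact, p_deact = pearson_r(fade, deact)
            r_comp, _ = pearson_r(act, deact)
            z, p_z = dependent_r_compare(r_act, r_deact, r_comp, len(sub))
            rows.append(
                {"age_group": g, "x": f"fade_{contrast}", "y": f"same_act_{contrast}",
                 "r": r_act, "p": p_act, "kind": "component"}
            )
            rows.append(
                {"age_group": g, "x": f"fade_{contrast}", "y": f"same_deact_{contrast}",
                 "r": r_deact, "p": p_deact, "kind": "component"}
            )
            rows.append(
                {"age_group": g, "x": f"meng_z_{contrast}", "y": "act_vs_deact",
                 "r": z, "p": p_z, "kind": "meng"}
            )
    return pd.DataFrame(rows)


def _regression_family(
    merged: pd.DataFrame, dependents: list[str], contrast: str, alpha: float
) -> pd.DataFrame:
    results = []
    for dep in dependents:
        if dep not in merged.columns:
            continue
        try:
            res = fade_same_regression(
                merged[dep], merged[f"fade_{contrast}"], merged[f"same_{contrast}"],
                dependent=dep,
            )
        except ValueError:
            continue
        results.append(res)
    holm_correct_models(results, alpha=alpha)
    rows = []
    for res in results:
        row = {
            "dependent": res.dependent,
            "contrast": contrast,
            "n": res.n,
            "r_squared": res.r_squared,
            "f": res.f_value,
            "df1": res.df1,
            "df2": res.df2,
            "p_model": res.p_model,
            "holm_significant": res.holm_significant,
            "n_models_corrected": res.n_models_corrected,
        }
        for name, c in res.coef.items():
            row[f"beta_{name}"] = c["beta"]
            row[f"t_{name}"] = c["t"]
            row[f"p_{name}"] = c["p"]
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_stage(config: PipelineConfig, out_dir: Path) -> list[Path]:
    """Behavioral association battery on scores + behavior tables."""
    scores = pd.read_csv(out_dir / "scores.csv")
    behavior = pd.read_csv(out_dir / "behavior.csv")
    wide = scores_wide(scores)

    battery = [v for v in BATTERY_ANCHORS if v in behavior.columns]
    filtered, exclusions = apply_outlier_filter_by_group(behavior, battery)
    merged = wide.merge(filtered, on=["subject_id", "age_group"], how="inner")

    outputs = []
    comparisons = _group_comparisons(filtered, battery + ["a_prime"])
    path = out_dir / "group_comparisons.csv"
    comparisons.to_csv(path, index=False)
    outputs.append(path)

    path = out_dir / "outlier_exclusions.csv"
    exclusions.to_csv(path, index=False)
    outputs.append(path)

    correlations = _score_correlations(wide)
    path = out_dir / "score_correlations.csv"
    correlations.to_csv(path, index=False)
    outputs.append(path)

    # stepwise LDA on the full cohort -> global-cognition composite
    lda_report: dict = {}
    try:
        lda = stepwise_lda(
            filtered, battery, f_enter=config.f_enter, f_remove=config.f_remove
        )
        lda_report = {
            "selected": lda.selected,
            "wilks_lambda": lda.wilks_lambda,
            "p_lambda": lda.p_lambda,
            "standardized_coefficients": lda.standardized_coefficients,
            "classification_accuracy": lda.classification_accuracy,
            "group_accuracy": lda.group_accuracy,
        }
        composite = pd.Series(np.nan, index=filtered.index)
        composite.loc[lda.composite_scores.index] = lda.composite_scores.to_numpy()
        merged = merged.merge(
            pd.DataFrame(
                {"subject_id": filtered["subject_id"], "global_cognition": composite}
            ),
            on="subject_id",
            how="left",
        )
    except ValueError as err:
        lda_report = {"error": str(err)}
    path = out_dir / "lda_report.json"
    path.write_text(json.dumps(lda_report, indent=2))
    outputs.append(path)

    # regression families, separately per age group and contrast
    cognition_deps = ["global_cognition"] + [
        v for v in lda_report.get("selected", []) if v not in MEMORY_DEPENDENTS
    ][:4]
    mem_rows, cog_rows = [], []
    for g, sub in merged.groupby("age_group"):
        for contrast in CONTRASTS:
            fam = _regression_family(
                sub, MEMORY_DEPENDENTS, contrast, config.analysis_alpha
            )
            fam["age_group"] = g
            mem_rows.append(fam)
            fam = _regression_family(
                sub, cognition_deps, contrast, config.analysis_alpha
            )
            fam["age_group"] = g
            cog_rows.append(fam)
    for name, rows in (("regressions_memory", mem_rows), ("regressions_cognition", cog_rows)):
        path = out_dir / f"{name}.csv"
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
        outputs.append(path)
    return outputs


STAGES = {
    "simulate": simulate_stage,
    "reference": reference_stage,
    "score": score_stage,
    "analyze": analyze_stage,
}


def run_pipeline(config: PipelineConfig, resume: bool = True) -> RunManifest:
    """Run all stages in order; cached stages are skipped when resuming."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.save_yaml(out_dir / "config.yaml")
    digest = config.digest()
    manifest = RunManifest(seed=config.seed, version=__version__, config_digest=digest)
    for name, stage in STAGES.items():
        if resume and _stage_done(out_dir, name, digest):
            manifest.stages[name] = {"cached": True}
            continue
        started = time.time()
        try:
            outputs = stage(config, out_dir)
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
        manifest.record_stage(name, started, outputs)
        _mark_stage(out_dir, name, digest)
    manifest.save(out_dir / "manifest.json")
    return manifest
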