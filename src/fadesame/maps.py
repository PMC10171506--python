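"""Per-subject contrast maps and their NIfTI serialization.

A :class:`SubjectContrastMap` bundles one subject's voxel-wise contrast
estimates (gamma-hat) and t-values for a single first-level contrast
(novelty or subsequent memory), on a shared :class:`~fadesame.grid.BrainGrid`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import BrainGrid

CONTRASTS = ("novelty", "memory")


@dataclass
class SubjectContrastMap:
    """One subject's gamma-hat and t maps for one contrast."""

    subject_id: str
    age_group: str  # "young" | "older"
    contrast: str  # "novelty" | "memory"
    gamma: np.ndarray  # 3D contrast-estimate map
    t: np.ndarray  # 3D t-value map
    df: float | None = None  # residual degrees of freedom of the t map

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.gamma.shape != self.t.shape:
            raise ValueError("gamma and t maps must share one shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gamma.shape


def write_map(cmap: SubjectContrastMap, grid: BrainGrid, out_dir: str | Path) -> list[Path]:
    """Write a subject's gamma/t volumes as ``<id>_<contrast>_{con,t}.nii``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for suffix, vol in (("con", cmap.gamma), ("t", cmap.t)):
        grid.check_map(vol, suffix)
        path = out_dir / f"{cmap.subject_id}_{cmap.contrast}_{suffix}.nii"
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float64), grid.affine)
        img.header.set_data_dtype(np.float64)
        nib.save(img, path)
        written.append(path)
    return written


def _load_volume(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def read_map(
    con_path: str | os.PathLike,
    t_path: str | os.PathLike,
    subject_id: str,
    age_group: str,
    contrast: str,
    grid: BrainGrid | None = None,
) -> SubjectContrastMap:
    """Read a paired con/t NIfTI volume; validate against ``grid`` if given."""
    gamma, _ = _load_volume(con_path)
    t, _ = _load_volume(t_path)
    if grid is not None:
        for vol, path in ((gamma, con_path), (t, t_path)):
            if vol.shape != grid.shape:
                raise ValueError(
                    f"{path}: volume shape {vol.shape} does not match "
                    f"grid shape {grid.shape}"
                )
    return SubjectContrastMap(subject_id, age_group, contrast, gamma, t)


def read_maps_from_dir(
    map_dir: str | Path,
    contrast: str,
    grid: BrainGrid | None = None,
    age_groups: dict[str, str] | None = None,
) -> list[SubjectContrastMap]:
    """Read all ``*_<contrast>_con.nii`` / ``*_t.nii`` pairs in a directory.

    ``age_groups`` optionally maps subject id to group label; otherwise the
    label is ``"unknown"``.
    """
    map_dir = Path(map_dir)
    con_files = sorted(map_dir.glob(f"*_{contrast}_con.nii"))
    if not con_files:
        raise FileNotFoundError(
            f"no *_{contrast}_con.nii volumes found in {map_dir}"
        )
    out = []
    for con_path in con_files:
        sid = con_path.name[: -len(f"_{contrast}_con.nii")]
        t_path = map_dir / f"{sid}_{contrast}_t.nii"
        if not t_path.exists():
            raise FileNotFoundError(f"missing t map for {sid}: {t_path}")
        group = (age_groups or {}).get(sid, "unknown")
        out.append(read_map(con_path, t_path, sid, group, contrast, grid=grid))
    return out
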