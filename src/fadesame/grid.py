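"""Voxel lattice shared by all maps in an analysis.

A :class:`BrainGrid` plays the role the normalized-template voxel grid plays
in a standard fMRI group analysis: every subject map must live on the same
lattice, and all score sums run over the voxels of one common analysis mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class BrainGrid:
    """Common 3D voxel lattice and analysis mask.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis (three positive integers).
    voxel_size : tuple of float, default (3.5, 3.5, 3.5)
        Edge length of a voxel in mm per axis.
    analysis_mask : ndarray of bool, optional
        Voxels included in the analysis. Defaults to the full box.
    affine : (4, 4) ndarray, optional
        Voxel-to-world transform; a scaled identity by default.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (3.5, 3.5, 3.5)
    analysis_mask: np.ndarray | None = None
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if self.analysis_mask is None:
            self.analysis_mask = np.ones(self.shape, dtype=bool)
        else:
            self.analysis_mask = np.asarray(self.analysis_mask, dtype=bool)
            if self.analysis_mask.shape != self.shape:
                raise ValueError(
                    f"analysis_mask shape {self.analysis_mask.shape} "
                    f"does not match grid shape {self.shape}"
                )
        if not self.analysis_mask.any():
            raise ValueError("analysis_mask must contain at least one voxel")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def n_voxels(self) -> int:
        """Number of voxels inside the analysis mask."""
        return int(self.analysis_mask.sum())

    def check_map(self, volume: np.ndarray, name: str = "map") -> np.ndarray:
        """Validate that ``volume`` lives on this grid and return it as float."""
        vol = np.asarray(volume, dtype=float)
        if vol.shape != self.shape:
            raise ValueError(
                f"{name} shape {vol.shape} does not match grid shape {self.shape}"
            )
        return vol

    def mask_values(self, volume: np.ndarray) -> np.ndarray:
        """Flatten a 3D map to the 1D vector of analysis-mask voxels."""
        return self.check_map(volume)[self.analysis_mask]

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a 1D masked vector back into a full 3D volume."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValueError(
                f"expected {self.n_voxels} masked values, got {values.shape}"
            )
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.analysis_mask] = values
        return vol

    def ellipsoid_mask(self, margin: float = 0.08) -> np.ndarray:
        """Inscribed-ellipsoid mask, a crude brain-like analysis region."""
        center = (np.array(self.shape) - 1) / 2.0
        semi = (np.array(self.shape) / 2.0) * (1.0 - margin)
        idx = np.indices(self.shape)
        dist = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
        return dist <= 1.0

    def same_geometry(self, other: "BrainGrid") -> bool:
        return (
            self.shape == other.shape
            and np.array_equal(self.analysis_mask, other.analysis_mask)
        )
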