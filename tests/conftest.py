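import numpy as np
import pytest

from fadesame.grid import BrainGrid
from fadesame.reference import ReferenceSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid_1d6():
    """A 6-voxel grid (6x1x1) for hand-solvable score fixtures."""
    return BrainGrid((6, 1, 1), voxel_size=(1, 1, 1))


def make_reference(
    grid: BrainGrid,
    j_plus=None,
    j_minus=None,
    beta=None,
    sigma=None,
    contrast="novelty",
) -> ReferenceSet:
    """Assemble a ReferenceSet directly from given masks and maps."""
    shape = grid.shape
    j_plus = np.zeros(shape, bool) if j_plus is None else np.asarray(j_plus, bool)
    j_minus = np.zeros(shape, bool) if j_minus is None else np.asarray(j_minus, bool)
    beta = np.zeros(shape) if beta is None else np.asarray(beta, float)
    sigma = np.ones(shape) if sigma is None else np.asarray(sigma, float)
    return ReferenceSet(
        contrast=contrast,
        grid=grid,
        j_plus=j_plus,
        j_minus=j_minus,
        beta_hat=beta,
        sigma_hat=sigma,
        deact_defined=bool(j_minus.any()),
    )


def naive_fade(t_map, ref):
    """Per-voxel double-loop oracle for the FADE score."""
    out_sum = out_n = in_sum = in_n = 0.0
    shape = ref.grid.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not ref.grid.analysis_mask[i, j, k]:
                    continue
                if ref.j_plus[i, j, k]:
                    in_sum += t_map[i, j, k]
                    in_n += 1
                else:
                    out_sum += t_map[i, j, k]
                    out_n += 1
    return out_sum / out_n - in_sum / in_n


def naive_same(gamma_map, ref):
    """Per-voxel double-loop oracle for the SAME score and its components."""
    act_sum = act_n = deact_sum = deact_n = 0.0
    shape = ref.grid.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if ref.j_plus[i, j, k]:
                    act_sum += (
                        gamma_map[i, j, k] - ref.beta_hat[i, j, k]
                    ) / ref.sigma_hat[i, j, k]
                    act_n += 1
                if ref.j_minus[i, j, k]:
                    deact_sum += (
                        ref.beta_hat[i, j, k] - gamma_map[i, j, k]
                    ) / ref.sigma_hat[i, j, k]
                    deact_n += 1
    act = act_sum / act_n if act_n else 0.0
    deact = deact_sum / deact_n if deact_n else 0.0
    return act + deact, act, deact
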