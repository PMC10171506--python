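"""Reference construction: one-sample t, Bonferroni FWE, extent filter,
cluster inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fadesame.grid import BrainGrid
from fadesame.maps import SubjectContrastMap
from fadesame.reference import (
    ReferenceSet,
    StatMap,
    build_reference,
    extent_filter,
    fwe_voxel_threshold,
    one_sample_t_map,
    voxelwise_score_regression,
)
from fadesame.synthetic import CohortSpec, Cluster, cluster_template, generate_cohort


def _maps_from_stack(stack, grid, group="young"):
    return [
        SubjectContrastMap(f"s{i:02d}", group, "novelty", m, m)
        for i, m in enumerate(stack)
    ]


class TestOneSampleT:
    def test_degenerate_variance_flagged(self):
        grid = BrainGrid((3, 3, 3), voxel_size=(1, 1, 1))
        stack = np.full((5, 3, 3, 3), 2.5)
        stat, beta, sigma = one_sample_t_map(_maps_from_stack(stack, grid), grid)
        assert np.all(beta == 2.5)
        assert np.all(sigma == 0.0)
        assert not np.isfinite(stat.values).any()

    def test_antisymmetric_pair_gives_zero_t(self):
        grid = BrainGrid((2, 2, 2), voxel_size=(1, 1, 1))
        a = np.arange(8, dtype=float).reshape(2, 2, 2) + 1
        stat, _, _ = one_sample_t_map(_maps_from_stack(np.stack([a, -a]), grid), grid)
        assert np.allclose(stat.values, 0.0)

    def test_matches_textbook_formula(self, rng):
        grid = BrainGrid((1, 1, 1), voxel_size=(1, 1, 1))
        x = rng.normal(1.0, 2.0, size=20)
        stack = x.reshape(-1, 1, 1, 1)
        stat, _, _ = one_sample_t_map(_maps_from_stack(stack, grid), grid)
        expected = x.mean() / (x.std(ddof=1) / np.sqrt(20))
        assert stat.values[0, 0, 0] == pytest.approx(expected, abs=1e-10)
        assert stat.df == 19
        # cross-check against scipy's one-sample test
        assert stat.values[0, 0, 0] == pytest.approx(
            stats.ttest_1samp(x, 0.0).statistic, abs=1e-10
        )

    def test_requires_two_subjects(self):
        grid = BrainGrid((2, 2, 2), voxel_size=(1, 1, 1))
        with pytest.raises(ValueError, match="at least 2"):
            one_sample_t_map(_maps_from_stack(np.zeros((1, 2, 2, 2)), grid), grid)


class TestFweThreshold:
    def test_all_zero_map_is_empty(self):
        grid = BrainGrid((5, 5, 5), voxel_size=(1, 1, 1))
        stat = StatMap(np.zeros(grid.shape), "z", None, grid)
        assert not fwe_voxel_threshold(stat, 0.05, grid.n_voxels, "positive").any()

    def test_exact_boundary_is_kept(self):
        # the rule is p <= alpha/n: a voxel sitting exactly on the corrected
        # level survives
        grid = BrainGrid((10, 10, 10), voxel_size=(1, 1, 1))
        target = 0.05 / grid.n_voxels
        v = stats.norm.isf(target)
        # nudge within a few ulps to land exactly on the target p if the
        # quantile round-trip is off by one floating-point step
        for _ in range(5):
            p = stats.norm.sf(v)
            if p <= target:
                break
            v = np.nextafter(v, np.inf)
        vol = np.zeros(grid.shape)
        vol[0, 0, 0] = v
        keep = fwe_voxel_threshold(StatMap(vol, "z", None, grid), 0.05, grid.n_voxels, "positive")
        assert keep[0, 0, 0]
        assert keep.sum() == 1

    def test_tails_and_alpha_validation(self):
        grid = BrainGrid((2, 2, 2), voxel_size=(1, 1, 1))
        vol = np.zeros(grid.shape)
        vol[0, 0, 0] = -10.0
        stat = StatMap(vol, "z", None, grid)
        assert not fwe_voxel_threshold(stat, 0.05, 8, "positive").any()
        assert fwe_voxel_threshold(stat, 0.05, 8, "negative")[0, 0, 0]
        with pytest.raises(ValueError, match="alpha"):
            fwe_voxel_threshold(stat, 1.5, 8, "positive")

    def test_infinite_t_counts_nan_does_not(self):
        grid = BrainGrid((2, 2, 2), voxel_size=(1, 1, 1))
        vol = np.zeros(grid.shape)
        vol[0, 0, 0] = np.inf
        vol[1, 0, 0] = np.nan
        keep = fwe_voxel_threshold(StatMap(vol, "t", 10, grid), 0.05, 8, "positive")
        assert keep[0, 0, 0] and not keep[1, 0, 0]


class TestExtentFilter:
    def test_component_size_boundary(self):
        # a single 9-voxel component vanishes at k=10 ...
        line9 = np.zeros((12, 3, 3), bool)
        line9[:9, 1, 1] = True
        assert not extent_filter(line9, 10).any()
        # ... while a 10-voxel component survives unchanged (>= rule)
        line10 = np.zeros((12, 3, 3), bool)
        line10[:10, 1, 1] = True
        assert np.array_equal(extent_filter(line10, 10), line10)
        # small components are removed independently of surviving ones
        both = line10.copy()
        both[11, 0, 0] = True
        assert np.array_equal(extent_filter(both, 10), line10)

    def test_connectivity_semantics_for_diagonal_touch(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True  # full-corner neighbors
        # one component under 26-connectivity: both survive k=2
        assert extent_filter(mask, 2, connectivity=26).sum() == 2
        # two singletons under 6- (and 18-) connectivity: both removed
        assert extent_filter(mask, 2, connectivity=6).sum() == 0
        assert extent_filter(mask, 2, connectivity=18).sum() == 0
        # an edge-touching pair is one component already at 18
        mask2 = np.zeros((4, 4, 4), bool)
        mask2[0, 0, 0] = True
        mask2[1, 1, 0] = True
        assert extent_filter(mask2, 2, connectivity=18).sum() == 2
        assert extent_filter(mask2, 2, connectivity=6).sum() == 0

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**16), k=st.integers(1, 12))
    def test_idempotent(self, seed, k):
        rng = np.random.default_rng(seed)
        mask = rng.random((8, 8, 8)) < 0.2
        once = extent_filter(mask, k)
        assert np.array_equal(extent_filter(once, k), once)


class TestBuildReference:
    def test_noise_free_sphere_recovered_exactly(self):
        grid = BrainGrid((12, 12, 12), voxel_size=(1, 1, 1))
        sphere = cluster_template(grid, [Cluster((6, 6, 6), 2.0, 1.0)]) > 0
        assert sphere.sum() == 33
        stack = np.repeat(sphere[None].astype(float), 5, axis=0)
        ref = build_reference(_maps_from_stack(stack, grid), grid, k=10)
        assert np.array_equal(ref.j_plus, sphere)
        assert ref.v_plus == 33
        assert ref.v_out == grid.n_voxels - 33

    def test_pure_noise_cohort_raises_empty_j_plus(self, rng):
        grid = BrainGrid((10, 10, 10), voxel_size=(1, 1, 1))
        stack = rng.normal(size=(8,) + grid.shape)
        with pytest.raises(ValueError, match="undefined without J\\+"):
            build_reference(_maps_from_stack(stack, grid), grid)

    def test_masks_disjoint_and_counts_consistent(self):
        spec = CohortSpec(n_young=60, n_older=0, grid_shape=(14, 14, 14), seed=5)
        grid, maps, _ = generate_cohort(spec)
        ref = build_reference(maps["novelty"], grid)
        assert not (ref.j_plus & ref.j_minus).any()
        assert ref.v_plus == ref.j_plus.sum()
        assert ref.v_minus == ref.j_minus.sum()
        assert ref.v_out + ref.v_plus == grid.n_voxels

    def test_cluster_support_recovery_jaccard(self):
        # planted supports recovered at n_young=80, small noise
        spec = CohortSpec(
            n_young=80, n_older=0, grid_shape=(16, 16, 16), noise_sd=0.5, seed=9
        )
        grid, maps, _ = generate_cohort(spec)
        act = cluster_template(grid, spec.activation_clusters) > 0
        deact = cluster_template(grid, spec.deactivation_clusters) < 0
        ref = build_reference(maps["novelty"], grid)
        for est, true in ((ref.j_plus, act), (ref.j_minus, deact)):
            jaccard = (est & true).sum() / (est | true).sum()
            assert jaccard >= 0.9

    def test_save_load_roundtrip(self, tmp_path):
        spec = CohortSpec(n_young=50, n_older=0, grid_shape=(12, 12, 12), seed=2)
        grid, maps, _ = generate_cohort(spec)
        ref = build_reference(maps["novelty"], grid)
        ref.save(tmp_path / "ref")
        loaded = ReferenceSet.load(tmp_path / "ref")
        assert np.array_equal(loaded.j_plus, ref.j_plus)
        assert np.array_equal(loaded.j_minus, ref.j_minus)
        np.testing.assert_allclose(loaded.beta_hat, ref.beta_hat)
        np.testing.assert_allclose(loaded.sigma_hat, ref.sigma_hat)
        assert loaded.contrast == ref.contrast
        assert loaded.k_extent == ref.k_extent
        assert loaded.deact_defined == ref.deact_defined


class TestScoreRegression:
    def test_constant_score_rejected(self, rng):
        grid = BrainGrid((6, 6, 6), voxel_size=(1, 1, 1))
        maps = _maps_from_stack(rng.normal(size=(10,) + grid.shape), grid, "older")
        with pytest.raises(ValueError, match="constant"):
            voxelwise_score_regression(maps, np.ones(10), grid, n_permutations=100)

    def test_noise_free_template_support_recovered(self, rng):
        grid = BrainGrid((10, 10, 10), voxel_size=(1, 1, 1))
        template = cluster_template(grid, [Cluster((5, 5, 5), 2.5, 1.0)]) > 0
        score = rng.normal(size=14)
        stack = score[:, None, None, None] * template[None].astype(float)
        maps = _maps_from_stack(stack, grid, "older")
        _, clusters = voxelwise_score_regression(
            maps, score, grid, n_permutations=200, seed=0
        )
        assert clusters, "expected the template to surface as a cluster"
        assert clusters[0].size == template.sum()
        assert template[clusters[0].peak_voxel]
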