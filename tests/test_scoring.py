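"""FADE/SAME score math: worked fixtures, identities, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fadesame.grid import BrainGrid
from fadesame.scoring import FadeSameScorer, fade_score, same_score, score_cohort
from fadesame.synthetic import CohortSpec, generate_cohort
from fadesame.reference import build_reference

from conftest import make_reference, naive_fade, naive_same


def _vol(grid, values):
    return np.asarray(values, float).reshape(grid.shape)


class TestFade:
    def test_zero_t_map_gives_zero(self, grid_1d6):
        ref = make_reference(grid_1d6, j_plus=_vol(grid_1d6, [1, 1, 0, 0, 0, 0]))
        assert fade_score(np.zeros(grid_1d6.shape), ref) == 0.0

    def test_worked_six_voxel_fixtures(self, grid_1d6):
        # J+ = first two voxels; deviation = mean outside - mean inside
        ref = make_reference(grid_1d6, j_plus=_vol(grid_1d6, [1, 1, 0, 0, 0, 0]))
        t1 = _vol(grid_1d6, [3, 3, 0, 0, 0, 0])
        assert fade_score(t1, ref) == pytest.approx(-3.0, abs=1e-12)
        t2 = _vol(grid_1d6, [1, 1, 2, 2, 2, 2])
        assert fade_score(t2, ref) == pytest.approx(1.0, abs=1e-12)

    def test_empty_j_plus_rejected(self, grid_1d6):
        ref = make_reference(grid_1d6)
        with pytest.raises(ValueError, match="empty J\\+"):
            fade_score(np.zeros(grid_1d6.shape), ref)

    def test_nonfinite_t_inside_mask_rejected(self, grid_1d6):
        ref = make_reference(grid_1d6, j_plus=_vol(grid_1d6, [1, 0, 0, 0, 0, 0]))
        t = np.zeros(grid_1d6.shape)
        t[3, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fade_score(t, ref)


class TestSame:
    def test_perfect_match_is_zero(self, grid_1d6):
        beta = _vol(grid_1d6, [2, 2, -1, -1, 0, 0])
        ref = make_reference(
            grid_1d6,
            j_plus=_vol(grid_1d6, [1, 1, 0, 0, 0, 0]),
            j_minus=_vol(grid_1d6, [0, 0, 1, 1, 0, 0]),
            beta=beta,
        )
        assert same_score(beta, ref) == (0.0, 0.0, 0.0)

    def test_worked_two_voxel_fixture(self):
        grid = BrainGrid((2, 1, 1), voxel_size=(1, 1, 1))
        ref = make_reference(
            grid,
            j_plus=_vol(grid, [1, 0]),
            j_minus=_vol(grid, [0, 1]),
            beta=_vol(grid, [2, -2]),
        )
        # gamma halfway back toward zero in both masks: each term -1
        same, act, deact = same_score(_vol(grid, [1, -1]), ref)
        assert (same, act, deact) == pytest.approx((-2.0, -1.0, -1.0), abs=1e-12)
        # one young-SD better than the young mean in both masks: each term +1
        same, act, deact = same_score(_vol(grid, [3, -3]), ref)
        assert (same, act, deact) == pytest.approx((2.0, 1.0, 1.0), abs=1e-12)

    def test_component_sum_identity(self, rng, grid_1d6):
        ref = make_reference(
            grid_1d6,
            j_plus=_vol(grid_1d6, [1, 1, 0, 0, 0, 0]),
            j_minus=_vol(grid_1d6, [0, 0, 1, 0, 0, 0]),
            beta=rng.normal(size=grid_1d6.shape),
            sigma=rng.uniform(0.5, 2, grid_1d6.shape),
        )
        gamma = rng.normal(size=grid_1d6.shape)
        same, act, deact = same_score(gamma, ref)
        assert same == pytest.approx(act + deact, abs=1e-12)

    def test_zero_sigma_on_reference_voxel_rejected(self, grid_1d6):
        sigma = np.ones(grid_1d6.shape)
        sigma[0, 0, 0] = 0.0
        ref = make_reference(
            grid_1d6, j_plus=_vol(grid_1d6, [1, 0, 0, 0, 0, 0]), sigma=sigma
        )
        with pytest.raises(ValueError, match="sigma"):
            same_score(np.ones(grid_1d6.shape), ref)

    def test_empty_j_minus_flagged_not_fatal(self, grid_1d6):
        ref = make_reference(grid_1d6, j_plus=_vol(grid_1d6, [1, 1, 0, 0, 0, 0]))
        same, act, deact = same_score(np.ones(grid_1d6.shape), ref)
        assert deact == 0.0 and same == act
        assert not ref.deact_defined

    @settings(deadline=None, max_examples=25)
    @given(a=st.floats(0.0, 1.0), seed=st.integers(0, 2**16))
    def test_linearity_in_interpolation_toward_young_mean(self, a, seed):
        # same(a*gamma + (1-a)*beta) = a * same(gamma), exactly by linearity
        rng = np.random.default_rng(seed)
        grid = BrainGrid((4, 4, 4), voxel_size=(1, 1, 1))
        j_plus = np.zeros(grid.shape, bool)
        j_plus[:2, 0, 0] = True
        j_minus = np.zeros(grid.shape, bool)
        j_minus[2:, 1, 1] = True
        ref = make_reference(
            grid,
            j_plus=j_plus,
            j_minus=j_minus,
            beta=rng.normal(size=grid.shape),
            sigma=rng.uniform(0.5, 2.0, grid.shape),
        )
        gamma = rng.normal(size=grid.shape)
        full, _, _ = same_score(gamma, ref)
        mixed, _, _ = same_score(a * gamma + (1 - a) * ref.beta_hat, ref)
        assert mixed == pytest.approx(a * full, abs=1e-9)


class TestOracleEquivalence:
    def test_vectorized_matches_double_loop(self, rng):
        grid = BrainGrid((10, 10, 10), voxel_size=(1, 1, 1))
        for _ in range(5):
            j_plus = rng.random(grid.shape) < 0.1
            j_plus[0, 0, 0] = True  # never empty
            j_minus = (rng.random(grid.shape) < 0.1) & ~j_plus
            ref = make_reference(
                grid,
                j_plus=j_plus,
                j_minus=j_minus,
                beta=rng.normal(size=grid.shape),
                sigma=rng.uniform(0.5, 2.0, grid.shape),
            )
            t_map = rng.normal(size=grid.shape)
            gamma = rng.normal(size=grid.shape)
            assert fade_score(t_map, ref) == pytest.approx(
                naive_fade(t_map, ref), abs=1e-12
            )
            assert same_score(gamma, ref) == pytest.approx(
                naive_same(gamma, ref), abs=1e-12
            )


@pytest.fixture(scope="module")
def noiseless_cohort():
    spec = CohortSpec(
        n_young=12,
        n_older=8,
        grid_shape=(12, 12, 12),
        noise_sd=0.0,
        attenuation_mean=0.0,
        attenuation_sd=0.0,
        deactivation_reduction_mean=0.0,
        deactivation_reduction_sd=0.0,
        seed=7,
    )
    return generate_cohort(spec)


class TestScoreCohort:
    def test_zero_attenuation_zero_noise_same_is_zero(self, noiseless_cohort):
        grid, maps, _ = noiseless_cohort
        # noise-free young stack: sigma-hat is 0, so score against an
        # explicitly constructed reference with unit sigma
        template = maps["novelty"][0].gamma
        ref = make_reference(
            grid, j_plus=template > 0, j_minus=template < 0, beta=template
        )
        table = score_cohort({"novelty": maps["novelty"]}, {"novelty": ref})
        assert np.allclose(table["same"], 0.0, atol=1e-10)
        assert np.allclose(table["same_act"] + table["same_deact"], table["same"])

    def test_same_strictly_decreasing_in_attenuation(self):
        spec = CohortSpec(
            n_young=6,
            n_older=10,
            grid_shape=(12, 12, 12),
            noise_sd=0.0,
            deactivation_reduction_mean=0.0,
            deactivation_reduction_sd=0.0,
            attenuation_mean=0.5,
            attenuation_sd=0.3,
            seed=11,
        )
        grid, maps, records = generate_cohort(spec)
        template = maps["novelty"][0].gamma
        ref = make_reference(
            grid, j_plus=template > 0, j_minus=template < 0, beta=template
        )
        table = score_cohort({"novelty": maps["novelty"]}, {"novelty": ref})
        older = table[table["age_group"] == "older"].set_index("subject_id")
        alphas = {r.subject_id: r.alpha for r in records if r.age_group == "older"}
        ordered = older.loc[sorted(alphas, key=alphas.get), "same"].to_numpy()
        assert np.all(np.diff(ordered) < 0)

    def test_scoring_is_deterministic(self, noiseless_cohort):
        grid, maps, _ = noiseless_cohort
        template = maps["novelty"][0].gamma
        ref = make_reference(
            grid, j_plus=template > 0, j_minus=template < 0, beta=template
        )
        t1 = score_cohort({"novelty": maps["novelty"]}, {"novelty": ref})
        t2 = score_cohort({"novelty": maps["novelty"]}, {"novelty": ref})
        assert t1.equals(t2)

    def test_grid_mismatch_rejected(self, noiseless_cohort, grid_1d6):
        _, maps, _ = noiseless_cohort
        ref = make_reference(grid_1d6, j_plus=_vol(grid_1d6, [1, 0, 0, 0, 0, 0]))
        with pytest.raises(ValueError, match="does not match"):
            score_cohort({"novelty": maps["novelty"]}, {"novelty": ref})


class TestFadeSameScorerEstimator:
    def test_sklearn_protocol_and_agreement_with_functions(self, rng):
        from sklearn.base import clone

        spec = CohortSpec(n_young=30, n_older=10, grid_shape=(12, 12, 12), seed=3)
        grid, maps, _ = generate_cohort(spec)
        young = [m for m in maps["novelty"] if m.age_group == "young"]
        est = FadeSameScorer(grid=grid)
        est_clone = clone(est)  # params survive cloning
        assert est_clone.get_params()["alpha_fwe"] == 0.05

        X_young = np.stack([grid.mask_values(m.gamma) for m in young])
        est.fit(X_young)
        X_all = FadeSameScorer.stack_maps(maps["novelty"], grid)
        scores = est.transform(X_all)

        ref = build_reference(young, grid)
        table = score_cohort({"novelty": maps["novelty"]}, {"novelty": ref})
        np.testing.assert_allclose(scores[:, 0], table["fade"], atol=1e-12)
        np.testing.assert_allclose(scores[:, 1], table["same"], atol=1e-12)
        assert list(est.get_feature_names_out()) == [
            "fade",
            "same",
            "same_act",
            "same_deact",
        ]

    def test_transform_requires_t_half(self):
        grid = BrainGrid((6, 6, 6), voxel_size=(1, 1, 1))
        est = FadeSameScorer(grid=grid)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, grid.n_voxels)) + 2.0
        est.fit(X)
        with pytest.raises(ValueError, match="2m"):
            est.transform(X)
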