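import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_index_totals, brute_quintile, ecdf_quantile_lower
from plantdex.diet_indices import (
    INDICES,
    SampleSizeError,
    assign_unit_score,
    compute_cutpoints,
    default_scoring_matrix,
    extreme_cohort_score,
    quintile_of,
    score_cohort,
    score_participant,
    theoretical_range,
    unit_weight_total,
    weighted_quantile_lower,
)
from plantdex.food_composition import (
    Category,
    Context,
    FoodGroupIntakeMatrix,
    N_GROUPS,
)

PROBS = (0.2, 0.4, 0.6, 0.8)


class TestScoringMatrix:
    def test_unit_weight_totals(self):
        sm = default_scoring_matrix()
        assert unit_weight_total(sm, "pdi") == 46
        assert unit_weight_total(sm, "hpdi") == 53
        assert unit_weight_total(sm, "updi") == 51

    def test_theoretical_ranges(self):
        sm = default_scoring_matrix()
        assert theoretical_range(sm, "pdi") == (46, 230)
        assert theoretical_range(sm, "hpdi") == (53, 265)
        assert theoretical_range(sm, "updi") == (51, 255)

    def test_context_weighting(self):
        """The double weight sits on healthy-plant core units for hPDI and on
        unhealthy-plant discretionary units for uPDI."""
        sm = default_scoring_matrix()
        assert sm[("hpdi", Category.HEALTHY_PLANT, Context.CORE)].weight == 2
        assert sm[("hpdi", Category.HEALTHY_PLANT, Context.DISCRETIONARY)].weight == 1
        assert sm[("updi", Category.UNHEALTHY_PLANT, Context.DISCRETIONARY)].weight == 2
        assert sm[("updi", Category.UNHEALTHY_PLANT, Context.CORE)].weight == 1
        assert all(
            sm[("pdi", cat, ctx)].weight == 1
            for cat in Category for ctx in (Context.CORE, Context.DISCRETIONARY)
        )


class TestWeightedQuantiles:
    def test_matches_brute_force_ecdf(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.choice([0.0, 1.0, 2.5, 7.0, 11.0], size=17)
            w = rng.uniform(0.1, 3.0, 17)
            got = weighted_quantile_lower(vals, w, np.array(PROBS))
            want = [ecdf_quantile_lower(vals, w, p) for p in PROBS]
            np.testing.assert_array_equal(got, want)

    def test_equal_weights_match_unweighted_percentiles(self):
        """Intakes 1..100 with equal weights: cuts at 20/40/60/80 and the
        participant at 50 g falls in Q3."""
        vals = np.arange(1.0, 101.0)
        w = np.ones(100)
        cuts = weighted_quantile_lower(vals, w, np.array(PROBS))
        np.testing.assert_array_equal(cuts, [20, 40, 60, 80])
        assert quintile_of(50.0, cuts) == 3

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(5)
        cube = rng.uniform(0, 10, (12, N_GROUPS, 2))
        w = rng.uniform(0.5, 2.0, 12)
        np.testing.assert_array_equal(
            compute_cutpoints(cube, w), compute_cutpoints(cube, 10 * w)
        )

    def test_all_zero_unit_degenerates_to_q1(self):
        cube = np.zeros((8, N_GROUPS, 2))
        cuts = compute_cutpoints(cube, np.ones(8))
        assert np.all(cuts == 0)
        assert quintile_of(0.0, cuts[0, 0]) == 1

    def test_sample_size_guard(self):
        with pytest.raises(SampleSizeError):
            compute_cutpoints(np.zeros((4, N_GROUPS, 2)), np.ones(4))


class TestUnitScore:
    CUTS = np.array([1.0, 2.0, 3.0, 4.0])

    @pytest.mark.parametrize(
        "intake,orientation,weight,expected",
        [
            (5.0, "positive", 1, 5),   # top quintile scores five
            (5.0, "positive", 2, 10),  # doubled for weighted core units
            (5.0, "reverse", 1, 1),    # animal groups reverse
            (0.5, "positive", 1, 1),   # below the lowest cut scores one
            (0.5, "reverse", 2, 10),
            (2.0, "positive", 1, 2),   # tie goes to the lower quintile
        ],
    )
    def test_examples(self, intake, orientation, weight, expected):
        assert assign_unit_score(intake, self.CUTS, orientation, weight) == expected

    def test_reversal_symmetry(self):
        for intake in (0.0, 1.0, 1.5, 2.5, 3.5, 9.0):
            pos = assign_unit_score(intake, self.CUTS, "positive", 1)
            rev = assign_unit_score(intake, self.CUTS, "reverse", 1)
            assert pos + rev == 6


def random_cohort(n, seed, zero_heavy=False):
    rng = np.random.default_rng(seed)
    cube = rng.lognormal(2.0, 1.0, (n, N_GROUPS, 2))
    if zero_heavy:
        cube *= rng.random((n, N_GROUPS, 2)) > 0.5
    w = rng.uniform(0.2, 3.0, n)
    return cube, w


@pytest.mark.parametrize("seed,zero_heavy", [(0, False), (1, True), (2, True)])
def test_cohort_scores_match_brute_force(seed, zero_heavy):
    """Vectorised engine vs an independent per-unit ECDF enumeration on small
    cohorts, including zero-heavy intakes that stress the tie rule."""
    cube, w = random_cohort(18, seed, zero_heavy)
    sm = default_scoring_matrix()
    got = score_cohort(cube, w, sm)
    want = brute_index_totals(cube, w, sm)
    for name in INDICES:
        np.testing.assert_array_equal(got[name].to_numpy(), want[name])


def test_score_participant_matches_cohort_path():
    cube, w = random_cohort(10, 4)
    cuts = compute_cutpoints(cube, w)
    df = score_cohort(cube, w, cuts=cuts)
    for i in range(10):
        s = score_participant(FoodGroupIntakeMatrix(i, cube[i]), cuts)
        assert (s.pdi, s.hpdi, s.updi) == (
            df.loc[i, "pdi"], df.loc[i, "hpdi"], df.loc[i, "updi"]
        )


@settings(derandomize=True, max_examples=20)
@given(st.integers(0, 10_000))
def test_scores_within_theoretical_ranges(seed):
    cube, w = random_cohort(25, seed, zero_heavy=seed % 2 == 0)
    df = score_cohort(cube, w)
    sm = default_scoring_matrix()
    for name in INDICES:
        lo, hi = theoretical_range(sm, name)
        assert df[name].between(lo, hi).all()


def test_monotonicity_in_healthy_core_intake():
    """Raising one healthy-plant core intake with cutpoints held fixed never
    decreases hPDI and never increases uPDI."""
    cube, w = random_cohort(15, 6)
    cuts = compute_cutpoints(cube, w)
    base = score_cohort(cube, w, cuts=cuts)
    bumped = cube.copy()
    bumped[:, 1, 0] += 50.0  # fruits, core
    after = score_cohort(bumped, w, cuts=cuts)
    assert (after["hpdi"] >= base["hpdi"]).all()
    assert (after["updi"] <= base["updi"]).all()
    assert (after["pdi"] >= base["pdi"]).all()


def test_quintile_invariant_under_increasing_transform():
    rng = np.random.default_rng(8)
    vals = rng.lognormal(1.0, 1.0, 30)
    w = rng.uniform(0.5, 2.0, 30)
    before = [brute_quintile(v, vals, w) for v in vals]
    tv = np.exp(0.5 * vals) + 3.0  # strictly increasing
    after = [brute_quintile(v, tv, w) for v in tv]
    assert before == after


@pytest.mark.parametrize(
    "index,extreme,expected",
    [
        ("pdi", "min", 46), ("pdi", "max", 230),
        ("hpdi", "min", 53), ("hpdi", "max", 265),
        ("updi", "min", 51), ("updi", "max", 255),
    ],
)
def test_engine_attains_theoretical_bounds(index, extreme, expected):
    for seed in (0, 99):
        assert extreme_cohort_score(index, extreme, seed=seed) == expected
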