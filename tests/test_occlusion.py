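"""Transport encodings and the exact 1-D quadratic Wasserstein distance."""

import math

import numpy as np
import pytest
from scipy.optimize import linprog

from occlumorph import (
    Asperity,
    AsperityKind,
    DegenerateMassError,
    Digit,
    WeightedPointSet,
    build_weighted_pointset,
    cross_digit_distance_matrix,
    occlusive_distance,
    wasserstein1d_p2,
)
from occlumorph.synthetic_data import perfect_complement_pair

from conftest import make_specimen


def asp(x, y, kind=AsperityKind.PEAK):
    return Asperity(x=float(x), y=float(y), kind=kind)


def pointset(locs, weights):
    return WeightedPointSet.from_raw(np.asarray(locs, float), np.asarray(weights, float))


def w2_lp(a: WeightedPointSet, b: WeightedPointSet) -> float:
    """Independent oracle: discrete optimal-transport linear program."""
    xa, wa = a.locations, a.weights
    xb, wb = b.locations, b.weights
    n, m = xa.size, xb.size
    C = (xa[:, None] - xb[None, :]) ** 2
    A_eq = []
    for i in range(n):
        row = np.zeros((n, m))
        row[i, :] = 1.0
        A_eq.append(row.ravel())
    for j in range(m):
        row = np.zeros((n, m))
        row[:, j] = 1.0
        A_eq.append(row.ravel())
    b_eq = np.concatenate([wa, wb])
    res = linprog(C.ravel(), A_eq=np.array(A_eq)[:-1], b_eq=b_eq[:-1],
                  bounds=(0, None), method="highs")
    assert res.status == 0
    return math.sqrt(max(res.fun, 0.0))


def random_pointset(rng, max_support=6):
    k = int(rng.integers(1, max_support + 1))
    return pointset(rng.uniform(-5, 5, k), rng.uniform(0.05, 1.0, k))


class TestEncoding:
    def test_moveable_peak_run_uses_heights_directly(self):
        ps = build_weighted_pointset([asp(3, 2), asp(6, 2)], Digit.MOVEABLE, "peak")
        np.testing.assert_allclose(ps.weights, [0.5, 0.5])

    def test_fixed_peak_run_flips_heights(self):
        ps = build_weighted_pointset([asp(3, 1), asp(6, 3)], Digit.FIXED, "peak")
        np.testing.assert_allclose(ps.weights, [1.0, 0.0])

    def test_moveable_gullet_run_reflects_heights(self):
        ps = build_weighted_pointset(
            [asp(3, 1), asp(6, 3)], Digit.MOVEABLE, "gullet_reflected"
        )
        np.testing.assert_allclose(ps.weights, [1.0, 0.0])

    def test_degenerate_fixed_digit_errors_without_fallback(self):
        flat = [asp(3, 2), asp(6, 2)]
        with pytest.raises(DegenerateMassError):
            build_weighted_pointset(flat, Digit.FIXED, "peak")
        ps = build_weighted_pointset(flat, Digit.FIXED, "peak", uniform_fallback=True)
        np.testing.assert_allclose(ps.weights, [0.5, 0.5])

    def test_location_normalization(self):
        ps = build_weighted_pointset([asp(5, 1)], Digit.MOVEABLE, "peak", x_scale=10.0)
        assert ps.locations[0] == pytest.approx(0.5)

    def test_double_reflection_recovers_peak_run_when_floor_is_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.uniform(0, 4, 5)
            y[rng.integers(0, 5)] = 0.0  # gullet floor on the axis
            asps = [asp(i + 1, v) for i, v in enumerate(y)]
            peak = build_weighted_pointset(asps, Digit.MOVEABLE, "peak")
            reflected_twice = [
                asp(a.x, max(x.y for x in asps) - a.y) for a in asps
            ]
            back = build_weighted_pointset(reflected_twice, Digit.MOVEABLE, "gullet_reflected")
            np.testing.assert_allclose(back.weights, peak.weights, atol=1e-12)


class TestWasserstein1D:
    def test_identical_sets_zero(self):
        ps = pointset([1.0, 2.0, 5.0], [0.2, 0.3, 0.5])
        assert wasserstein1d_p2(ps, ps) == 0.0

    def test_point_mass_translation(self):
        assert wasserstein1d_p2(pointset([0], [1]), pointset([3], [1])) == pytest.approx(3.0)

    def test_equal_weight_quantile_integral(self):
        a = pointset([0, 1], [0.5, 0.5])
        b = pointset([0, 2], [0.5, 0.5])
        assert wasserstein1d_p2(a, b) == pytest.approx(math.sqrt(0.5))

    def test_reweighted_same_support(self):
        a = pointset([0, 1], [0.75, 0.25])
        b = pointset([0, 1], [0.25, 0.75])
        assert wasserstein1d_p2(a, b) == pytest.approx(math.sqrt(0.5))

    def test_matches_lp_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(200):
            a, b = random_pointset(rng), random_pointset(rng)
            worst = max(worst, abs(wasserstein1d_p2(a, b) - w2_lp(a, b)))
        assert worst < 1e-9

    def test_metric_axioms_on_sampled_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            a, b, c = (random_pointset(rng) for _ in range(3))
            dab = wasserstein1d_p2(a, b)
            assert dab == wasserstein1d_p2(b, a)
            assert dab >= 0
            assert dab <= wasserstein1d_p2(a, c) + wasserstein1d_p2(c, b) + 1e-9

    def test_translation_equivariance(self):
        rng = np.random.default_rng(9)
        a, b = random_pointset(rng), random_pointset(rng)
        shift = 2.7
        a2 = pointset(a.locations + shift, a.weights)
        b2 = pointset(b.locations + shift, b.weights)
        assert wasserstein1d_p2(a2, b2) == pytest.approx(wasserstein1d_p2(a, b), abs=1e-12)
        same_shape = pointset(a.locations + shift, a.weights)
        assert wasserstein1d_p2(a, same_shape) == pytest.approx(shift, abs=1e-12)


class TestOcclusiveDistance:
    def test_perfect_complement_is_exactly_zero(self, geometry):
        s = perfect_complement_pair([3, 6, 9, 12], [2, 1, 2, 1], geometry)
        d = occlusive_distance(s)
        assert (d.d_peak, d.d_gullet, d.d_mean) == (0.0, 0.0, 0.0)

    def test_single_shared_asperity_is_zero(self):
        s = make_specimen(
            md_asperities=[asp(5, 2)], fd_asperities=[asp(5, 2)]
        )
        d = occlusive_distance(s, uniform_fallback=True)
        assert d.d_mean == 0.0

    def test_rigid_shift_of_uniform_masses(self):
        s = make_specimen(
            md_asperities=[asp(3, 2), asp(6, 2)],
            fd_asperities=[asp(4, 2), asp(7, 2)],
        )
        d = occlusive_distance(s, uniform_fallback=True)
        assert d.d_peak == pytest.approx(1.0)
        assert d.d_gullet == pytest.approx(1.0)
        assert d.d_mean == pytest.approx(1.0)

    def test_degenerate_error_names_specimen(self):
        s = make_specimen(
            specimen_id="BAD-1",
            md_asperities=[asp(3, 2)],
            fd_asperities=[asp(4, 2), asp(7, 2)],  # constant fixed heights
        )
        with pytest.raises(DegenerateMassError, match="BAD-1"):
            occlusive_distance(s)


class TestCrossDigitMatrix:
    def test_symmetry_and_zero_diagonal(self, small_cohorts):
        dm, skips = cross_digit_distance_matrix(small_cohorts)
        assert skips == []
        v = dm.values
        assert np.abs(v - v.T).max() <= 1e-12
        assert np.abs(np.diag(v)).max() == 0.0

    def test_matches_pairwise_oracle_on_hand_built_digits(self):
        specs = [
            make_specimen("H-1", md_asperities=[asp(2, 1), asp(6, 3)],
                          fd_asperities=[asp(3, 1), asp(5, 2)]),
            make_specimen("H-2", md_asperities=[asp(4, 2)],
                          fd_asperities=[asp(2, 2), asp(8, 1)]),
        ]
        from occlumorph import Cohort

        cohort = Cohort(species_code="SP", specimens=specs)
        dm, _ = cross_digit_distance_matrix(
            [cohort], digit_selector="moveable", run="peak", normalize_locations=False
        )
        sets = [
            build_weighted_pointset(s.md_asperities, Digit.MOVEABLE, "peak")
            for s in specs
        ]
        expected = w2_lp(sets[0], sets[1])
        assert dm.values[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_degenerate_digits_are_skipped_with_report(self):
        from occlumorph import Cohort

        specs = [
            make_specimen("OK-1", md_asperities=[asp(2, 1), asp(6, 3)],
                          fd_asperities=[asp(3, 1), asp(5, 2)]),
            make_specimen("FLAT-1", md_asperities=[asp(2, 1), asp(6, 3)],
                          fd_asperities=[asp(3, 2), asp(5, 2)]),
        ]
        cohort = Cohort(species_code="SP", specimens=specs)
        dm, skips = cross_digit_distance_matrix([cohort], digit_selector="both")
        assert len(skips) == 1
        assert skips[0]["specimen_id"] == "FLAT-1"
        assert "FLAT-1:fd" not in dm.labels
        assert "FLAT-1:md" in dm.labels
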