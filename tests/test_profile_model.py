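"""Domain invariants, occlusal-frame handling, asperity extraction, and I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occlumorph import (
    Asperity,
    AsperityKind,
    Digit,
    GridProfile,
    LeverGeometry,
    SchemaError,
    ValidationError,
    extract_asperities,
    flip_to_occlusal_frame,
    generate_cohorts,
    load_specimens,
    write_specimens,
)
from occlumorph.profile_model import N_STATIONS


class TestDomainInvariants:
    def test_lever_geometry_rejects_inverted_arms(self):
        with pytest.raises(ValidationError):
            LeverGeometry(L1U=20, L2M=18, L2F=19, x_ie_md=10, x_ie_fd=10, alpha_deg=50)

    def test_mastication_end_must_lie_on_axis(self):
        with pytest.raises(ValidationError):
            LeverGeometry(L1U=10, L2M=18, L2F=19, x_ie_md=20, x_ie_fd=10, alpha_deg=50)

    def test_profile_tip_must_be_zero_height(self):
        x = np.linspace(0, 17, N_STATIONS)
        y = np.ones(N_STATIONS)
        with pytest.raises(ValidationError, match="tip"):
            GridProfile(digit_kind=Digit.MOVEABLE, x=x, y=y)

    def test_profile_requires_equispaced_stations(self):
        x = np.linspace(0, 17, N_STATIONS)
        x[5] += 0.5
        y = np.zeros(N_STATIONS)
        with pytest.raises(ValidationError, match="equispaced"):
            GridProfile(digit_kind=Digit.MOVEABLE, x=x, y=y)

    def test_asperity_rejects_tip_and_negative_height(self):
        with pytest.raises(ValidationError):
            Asperity(x=0.0, y=1.0, kind=AsperityKind.PEAK)
        with pytest.raises(ValidationError):
            Asperity(x=1.0, y=-0.1, kind=AsperityKind.PEAK)


class TestOcclusalFlip:
    def test_negates_native_heights(self):
        np.testing.assert_array_equal(
            flip_to_occlusal_frame([0.0, -2.0, -1.0]), [0.0, 2.0, 1.0]
        )

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1, max_size=30,
        )
    )
    @settings(deadline=None)
    def test_involution(self, heights):
        once = flip_to_occlusal_frame(heights)
        twice = flip_to_occlusal_frame(once)
        np.testing.assert_array_equal(twice, np.asarray(heights, float))

    def test_zero_profile_fixed_point(self):
        np.testing.assert_array_equal(flip_to_occlusal_frame(np.zeros(5)), np.zeros(5))

    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            flip_to_occlusal_frame([0.0, np.nan])

    def test_builds_fixed_profile_with_grid(self):
        x = np.linspace(0, 17, N_STATIONS)
        raw = np.zeros(N_STATIONS)
        raw[3] = -2.0
        prof = flip_to_occlusal_frame(raw, x=x)
        assert prof.digit_kind is Digit.FIXED
        assert prof.y[3] == 2.0


def brute_force_extrema(y):
    """Oracle: exhaustive scan of interior stations with plateau grouping."""
    out = []
    i = 1
    n = len(y)
    while i < n - 1:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        if j < n - 1:
            left, right = y[i - 1], y[j + 1]
            if y[i] > left and y[i] > right:
                out.append(("peak", (i + j) / 2))
            elif y[i] < left and y[i] < right:
                out.append(("gullet", (i + j) / 2))
        i = j + 1
    return out


class TestExtractAsperities:
    @staticmethod
    def profile(y):
        x = np.linspace(0, 17, len(y))
        return GridProfile(digit_kind=Digit.MOVEABLE, x=x, y=np.asarray(y, float))

    def test_monotone_profile_has_no_asperities(self):
        y = np.concatenate([[0.0], np.linspace(0.1, 5, N_STATIONS - 1)])
        assert extract_asperities(self.profile(y)) == []

    def test_single_bump_is_one_peak_at_its_station(self):
        y = np.zeros(N_STATIONS)
        y[4] = 3.0  # station 5
        asps = extract_asperities(self.profile(y), min_prominence=0.5)
        peaks = [a for a in asps if a.kind is AsperityKind.PEAK]
        assert len(peaks) == 1
        assert peaks[0].x == pytest.approx(self.profile(y).x[4])

    def test_sawtooth_matches_brute_force_scan(self):
        y = np.zeros(N_STATIONS)
        period = np.array([0.0, 1.0, 2.0, 1.0, 0.5, 1.5, 2.5, 1.5, 0.5])
        y[: period.size] = period
        y[period.size : 2 * period.size] = period
        prof = self.profile(y)
        got = [(a.kind.value, a.x) for a in extract_asperities(prof)]
        expected = [
            (kind, prof.x[0] + idx * (prof.x[1] - prof.x[0]))
            for kind, idx in brute_force_extrema(y)
        ]
        expected.sort(key=lambda t: t[1])
        assert [k for k, _ in got] == [k for k, _ in expected]
        np.testing.assert_allclose([x for _, x in got], [x for _, x in expected])

    def test_plateau_contributes_midpoint(self):
        y = np.zeros(N_STATIONS)
        y[5:8] = 2.0
        asps = extract_asperities(self.profile(y))
        peaks = [a for a in asps if a.kind is AsperityKind.PEAK]
        assert len(peaks) == 1
        prof = self.profile(y)
        assert peaks[0].x == pytest.approx(0.5 * (prof.x[5] + prof.x[7]))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_invariant_to_constant_height_shift(self, seed):
        rng = np.random.default_rng(seed)
        y = np.concatenate([[0.0], rng.uniform(1.0, 5.0, N_STATIONS - 1)])
        base = extract_asperities(self.profile(y), min_prominence=0.2)
        shifted_y = y + 3.0
        shifted_y[0] = 0.0  # keep the tip invariant valid
        x = np.linspace(0, 17, N_STATIONS)
        shifted = extract_asperities(
            GridProfile(digit_kind=Digit.MOVEABLE, x=x, y=shifted_y), min_prominence=0.2
        )
        # interior extrema are unaffected by a constant offset
        interior = [a for a in base if a.x > x[1]]
        interior_shifted = [a for a in shifted if a.x > x[1]]
        assert [(a.kind, a.x) for a in interior] == [(a.kind, a.x) for a in interior_shifted]


class TestTabularIO:
    def test_round_trip_preserves_content(self, tmp_path, small_cohorts):
        paths = [tmp_path / f for f in ("profiles.csv", "specimens.csv", "asperities.csv")]
        write_specimens(small_cohorts, *paths)
        loaded = load_specimens(*paths)
        assert {c.species_code for c in loaded} == {c.species_code for c in small_cohorts}
        by_code = {c.species_code: c for c in loaded}
        for cohort in small_cohorts:
            other = by_code[cohort.species_code]
            assert len(other) == len(cohort)
            for a, b in zip(cohort.specimens, other.specimens):
                assert a.specimen_id == b.specimen_id
                assert a.geometry == b.geometry
                assert a.tip_offset_um == b.tip_offset_um
                np.testing.assert_array_equal(a.md_profile.y, b.md_profile.y)
                np.testing.assert_array_equal(a.fd_profile.x, b.fd_profile.x)
                assert a.md_asperities == b.md_asperities
                assert a.fd_asperities == b.fd_asperities
                assert a.socket_present == b.socket_present
                assert a.MvG_um3 == b.MvG_um3

    def test_counts_preserved_for_two_species_fixture(self, tmp_path):
        cohorts = generate_cohorts(n_per_species=3, seed=2)[:2]
        paths = [tmp_path / f for f in ("p.csv", "s.csv", "a.csv")]
        write_specimens(cohorts, *paths)
        loaded = load_specimens(*paths)
        assert len(loaded) == 2
        assert all(len(c) == 3 for c in loaded)

    def test_tip_height_violation_is_reported(self, tmp_path, small_cohorts):
        import pandas as pd

        paths = [tmp_path / f for f in ("p.csv", "s.csv", "a.csv")]
        write_specimens(small_cohorts[:1], *paths)
        df = pd.read_csv(paths[0])
        df.loc[(df.station == 1) & (df.digit == "md"), "y_um"] = 1.0
        df.to_csv(paths[0], index=False)
        with pytest.raises(ValidationError, match="tip"):
            load_specimens(*paths)

    def test_missing_column_names_the_column(self, tmp_path, small_cohorts):
        import pandas as pd

        paths = [tmp_path / f for f in ("p.csv", "s.csv", "a.csv")]
        write_specimens(small_cohorts[:1], *paths)
        pd.read_csv(paths[1]).drop(columns=["alpha_deg"]).to_csv(paths[1], index=False)
        with pytest.raises(SchemaError, match="alpha_deg"):
            load_specimens(*paths)
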