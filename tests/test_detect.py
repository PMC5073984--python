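"""Lane/band detection contracts: projections, smoothing, peak calling,
sub-pixel refinement and manual edits, checked against brute-force
oracles and the stated deterministic tie rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gelquant import (
    Band,
    Edit,
    EditSet,
    IntensityProfile,
    apply_edits,
    detect_bands,
    detect_lanes,
    lane_profile,
    lateral_profile,
    refine_subpixel,
    smooth_profile,
)
from gelquant.gelio import Lane
from gelquant.errors import DetectionError, EditError, ProfileError
from conftest import random_profiles
from oracles import brute_peak_calls, brute_truncated_mean


def migration(values):
    return IntensityProfile(values=np.asarray(values, float), axis="migration")


def lateral(values):
    return IntensityProfile(values=np.asarray(values, float), axis="lateral")


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

class TestProfiles:
    def test_lateral_all_ones(self):
        prof = lateral_profile(np.ones((4, 4)))
        np.testing.assert_array_equal(prof.values, [4, 4, 4, 4])
        assert prof.axis == "lateral"

    def test_lateral_single_bright_column(self):
        px = np.zeros((5, 6))
        px[:, 2] = 10.0
        np.testing.assert_array_equal(lateral_profile(px).values,
                                      [0, 0, 50, 0, 0, 0])

    def test_lateral_matches_double_loop(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(0, 5, (20, 30))
        prof = lateral_profile(px, row_range=(3, 17))
        expected = [sum(px[r, c] for r in range(3, 17)) for c in range(30)]
        np.testing.assert_allclose(prof.values, expected)

    def test_lateral_empty_row_range(self):
        with pytest.raises(ProfileError):
            lateral_profile(np.ones((6, 6)), row_range=(4, 4))

    def test_lane_profile_all_ones(self):
        prof = lane_profile(np.ones((6, 10)),
                            Lane(lane_id=0, center_col=5, half_width=2))
        np.testing.assert_array_equal(prof.values, [4] * 6)
        assert prof.axis == "migration"

    def test_lane_profile_single_bright_row(self):
        px = np.zeros((8, 10))
        px[3, :] = 2.0
        prof = lane_profile(px, Lane(lane_id=0, center_col=5, half_width=2))
        expected = np.zeros(8)
        expected[3] = 8.0
        np.testing.assert_array_equal(prof.values, expected)

    def test_lane_profile_matches_double_loop(self):
        rng = np.random.default_rng(1)
        px = rng.uniform(0, 5, (25, 30))
        lane = Lane(lane_id=0, center_col=12.0, half_width=3.5)
        prof = lane_profile(px, lane)
        lo, hi = 9, 16  # ceil(12-3.5), ceil(12+3.5)
        expected = [sum(px[r, c] for c in range(lo, hi)) for r in range(25)]
        np.testing.assert_allclose(prof.values, expected)

    def test_lane_window_outside_image(self):
        with pytest.raises(ProfileError):
            lane_profile(np.ones((6, 10)),
                         Lane(lane_id=0, center_col=50.0, half_width=2))


class TestSmoothProfile:
    def test_window_one_is_identity(self):
        prof = migration([1, 5, 2, 8, 3])
        out = smooth_profile(prof, window=1)
        np.testing.assert_array_equal(out.values, prof.values)

    def test_small_example(self):
        out = smooth_profile(migration([0, 0, 9, 0, 0]), window=3)
        np.testing.assert_allclose(out.values, [0, 3, 3, 3, 0])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1e4, allow_nan=False), min_size=8,
                    max_size=64),
           st.sampled_from([3, 5, 7]))
    def test_matches_truncated_mean_oracle(self, values, window):
        out = smooth_profile(migration(values), window=window)
        np.testing.assert_allclose(out.values,
                                   brute_truncated_mean(values, window),
                                   rtol=1e-12, atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ProfileError):
            smooth_profile(migration([1, 2, 3, 4]), window=2)


# ---------------------------------------------------------------------------
# sub-pixel refinement
# ---------------------------------------------------------------------------

class TestRefineSubpixel:
    @pytest.mark.parametrize("triple,offset", [
        ((2, 10, 2), 0.0),
        ((0, 10, 10), +0.5),   # vertex formula clamps at the half-sample edge
        ((4, 10, 6), +0.1),    # (4-6)/(2*(4-20+6)) = 0.1
    ])
    def test_closed_form_vertex(self, triple, offset):
        values = np.array([0.0, *triple, 0.0])
        assert refine_subpixel(values, 2) == pytest.approx(2 + offset)

    def test_boundary_index_unchanged(self):
        assert refine_subpixel(np.array([5.0, 1.0, 0.0]), 0) == 0.0


# ---------------------------------------------------------------------------
# band calling
# ---------------------------------------------------------------------------

def gaussian_bumps(length, bumps):
    rows = np.arange(length, dtype=float)
    v = np.zeros(length)
    for pos, height, sigma in bumps:
        v += height * np.exp(-((rows - pos) ** 2) / (2 * sigma**2))
    return v


class TestDetectBands:
    def test_flat_profile_returns_empty(self):
        assert detect_bands(migration(np.full(32, 7.0)), 1.0) == []

    def test_two_gaussian_bumps(self):
        v = gaussian_bumps(200, [(40, 100, 2), (120, 60, 2)])
        calls = detect_bands(migration(v), min_prominence=10.0,
                             min_distance_rows=4)
        assert len(calls) == 2
        assert calls[0].position == pytest.approx(40.0, abs=0.25)
        assert calls[1].position == pytest.approx(120.0, abs=0.25)
        assert calls[0].prominence == pytest.approx(100.0, rel=1e-6)
        assert calls[1].prominence == pytest.approx(60.0, rel=1e-6)

    def test_threshold_drops_smaller_bump(self):
        v = gaussian_bumps(200, [(40, 100, 2), (120, 60, 2)])
        calls = detect_bands(migration(v), min_prominence=80.0)
        assert len(calls) == 1
        assert calls[0].position == pytest.approx(40.0, abs=0.25)

    def test_matches_brute_oracle_on_random_profiles(self):
        rng = np.random.default_rng(2)
        for v in random_profiles(rng, 60, max_len=256):
            threshold = float(rng.uniform(1, 30))
            dist = int(rng.integers(1, 8))
            calls = detect_bands(migration(v), min_prominence=threshold,
                                 min_distance_rows=dist)
            expected = brute_peak_calls(v, threshold, dist)
            assert len(calls) == len(expected)
            for call, (idx, prom) in zip(calls, expected):
                assert abs(call.position - idx) <= 0.5
                assert call.prominence == pytest.approx(prom, rel=1e-9)

    def test_equal_peaks_tie_breaks_to_smaller_row(self):
        v = np.zeros(40)
        v[[10, 12, 30]] = 5.0
        calls = detect_bands(migration(v), min_prominence=1.0,
                             min_distance_rows=5)
        assert [round(c.position) for c in calls] == [10, 30]

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotonicity_raising_threshold_never_adds_bands(self, seed):
        rng = np.random.default_rng(seed)
        v = next(iter(random_profiles(rng, 1, 128)))
        lo = detect_bands(migration(v), min_prominence=5.0)
        hi = detect_bands(migration(v), min_prominence=25.0)
        lo_pos = {round(c.position, 6) for c in lo}
        assert {round(c.position, 6) for c in hi} <= lo_pos

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 40))
    def test_shift_equivariance(self, seed, t):
        rng = np.random.default_rng(seed)
        core = gaussian_bumps(100, [(30, rng.uniform(50, 100), 2),
                                    (70, rng.uniform(50, 100), 2)])
        base = np.concatenate([np.zeros(50), core, np.zeros(50)])
        shifted = np.concatenate([np.zeros(50 + t), core, np.zeros(50 - t + 40)])
        a = detect_bands(migration(base), min_prominence=10.0)
        b = detect_bands(migration(shifted), min_prominence=10.0)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert cb.position - ca.position == pytest.approx(t, abs=1e-9)

    def test_noise_free_recovery_recall_and_precision_one(self):
        """Every well-separated Gaussian band is called, nothing else."""
        truth = [(40, 120, 2), (90, 80, 2), (160, 200, 3), (240, 60, 2)]
        v = gaussian_bumps(300, truth)
        calls = detect_bands(migration(v), min_prominence="auto")
        assert len(calls) == len(truth)
        for call, (pos, _, _) in zip(calls, truth):
            assert call.position == pytest.approx(pos, abs=0.5)


# ---------------------------------------------------------------------------
# lane detection
# ---------------------------------------------------------------------------

class TestDetectLanes:
    def test_two_rectangular_plateaus(self):
        v = np.zeros(45)
        v[8:13] = 100.0   # plateau centered at 10
        v[28:33] = 100.0  # plateau centered at 30
        lanes = detect_lanes(lateral(v), expected_n=2, min_separation_cols=5)
        assert len(lanes) == 2
        assert lanes[0].center_col == pytest.approx(10, abs=0.5)
        assert lanes[1].center_col == pytest.approx(30, abs=0.5)
        assert lanes[0].lane_id == 0 and lanes[1].lane_id == 1

    def test_flat_profile_errors(self):
        with pytest.raises(DetectionError, match="no lanes"):
            detect_lanes(lateral(np.full(40, 3.0)))

    def test_equal_peaks_separation_tie_to_leftmost(self):
        v = np.zeros(40)
        v[[10, 12, 30]] = 5.0
        lanes = detect_lanes(lateral(v), min_separation_cols=5,
                             prominence_frac=0.2)
        assert [round(l.center_col) for l in lanes] == [10, 30]

    def test_fewer_than_expected_errors(self):
        v = np.zeros(40)
        v[20] = 10.0
        with pytest.raises(DetectionError, match="expected"):
            detect_lanes(lateral(v), expected_n=3)

    def test_expected_n_keeps_most_prominent(self):
        v = np.zeros(80)
        v[[10, 40, 70]] = [100.0, 20.0, 90.0]
        lanes = detect_lanes(lateral(v), expected_n=2,
                             min_separation_cols=5, prominence_frac=0.05)
        assert [round(l.center_col) for l in lanes] == [10, 70]

    def test_lane_windows_do_not_overlap(self):
        v = np.zeros(120)
        v[[10, 35, 80]] = 100.0  # uneven gaps: 25 and 45
        lanes = detect_lanes(lateral(v), min_separation_cols=5)
        for a, b in zip(lanes[:-1], lanes[1:]):
            assert a.center_col + a.half_width <= b.center_col - b.half_width + 1e-9


# ---------------------------------------------------------------------------
# manual edits
# ---------------------------------------------------------------------------

def _band(lane_id, row):
    return Band(lane_id=lane_id, position_row=row, peak_intensity=50.0,
                prominence=40.0, area=200.0)


class TestApplyEdits:
    @pytest.fixture
    def profile(self):
        return migration(gaussian_bumps(300, [(40, 100, 2), (120, 60, 2)]))

    def test_remove_within_tolerance(self, profile):
        bands = [_band(0, 40.0), _band(0, 120.0)]
        edits = EditSet(edits=(Edit("remove", 0, 118.0, 5.0),))
        out = apply_edits(bands, edits, profile)
        assert [b.position_row for b in out] == [40.0]

    def test_add_flags_manual_origin(self, profile):
        bands = [_band(0, 40.0)]
        out = apply_edits(bands, EditSet(edits=(Edit("add", 0, 200.0),)),
                          profile)
        assert [b.position_row for b in out] == [40.0, 200.0]
        assert out[1].origin == "manual"
        assert out[0].origin == "auto"

    def test_remove_matching_nothing_errors(self, profile):
        bands = [_band(0, 40.0)]
        with pytest.raises(EditError, match="matches no band"):
            apply_edits(bands, EditSet(edits=(Edit("remove", 0, 90.0, 5.0),)),
                        profile)

    def test_add_collision_errors(self, profile):
        bands = [_band(0, 40.0)]
        with pytest.raises(EditError, match="collides"):
            apply_edits(bands, EditSet(edits=(Edit("add", 0, 42.0),)),
                        profile, min_distance_rows=4)

    def test_reapplying_remove_errors(self, profile):
        bands = [_band(0, 40.0), _band(0, 120.0)]
        edits = EditSet(edits=(Edit("remove", 0, 120.0, 3.0),))
        once = apply_edits(bands, edits, profile)
        with pytest.raises(EditError):
            apply_edits(once, edits, profile)
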