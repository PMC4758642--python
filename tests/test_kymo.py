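"""Kymograph construction, linking, classification and transport metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cordflux.core import TimeLapse
from cordflux.kymo import (
    Kymograph,
    Track,
    build_kymograph,
    classify_track,
    detect_and_link,
    segment_runs,
    track_velocity,
    transport_summary,
)
from cordflux.simdata import SimMovieSpec, VesicleSpec, make_movie

PX = 0.16
DT = 1 / 3.1


def track_from_positions(x, move=None):
    t = Track(track_id=0, frames=np.arange(len(x)), x_px=np.array(x, float),
              pixel_size_um=PX, frame_interval_s=DT)
    return t


class TestBuildKymograph:
    def test_static_spot_gives_vertical_line(self, single_vesicle_spec):
        movie, _ = make_movie(single_vesicle_spec(0.0, frames=30))
        kymo = build_kymograph(movie)
        cols = kymo.data.argmax(axis=1)
        assert np.all(cols == cols[0])

    def test_moving_spot_slope_matches_velocity(self):
        # render a spot moving exactly +2 px/frame on a blank movie
        frames = np.zeros((20, 9, 100))
        for t in range(20):
            frames[t, 4, 10 + 2 * t] = 100.0
        kymo = build_kymograph(TimeLapse(frames, 3.1, PX))
        cols = kymo.data.argmax(axis=1)
        np.testing.assert_array_equal(np.diff(cols), 2)

    def test_width_one_reduces_to_line_sampling(self, single_vesicle_spec):
        movie, _ = make_movie(single_vesicle_spec(1.0, frames=10))
        row = movie.data.shape[1] // 2
        kymo = build_kymograph(movie, row=row, width_px=1)
        np.testing.assert_array_equal(kymo.data, movie.data[:, row, :])

    def test_roi_outside_frame_rejected(self, single_vesicle_spec):
        movie, _ = make_movie(single_vesicle_spec(1.0, frames=5))
        with pytest.raises(IndexError):
            build_kymograph(movie, row=999)

    def test_mirroring_swaps_orientation(self, single_vesicle_spec):
        movie, _ = make_movie(single_vesicle_spec(1.0, frames=10))
        kymo = build_kymograph(movie)
        assert kymo.mirrored().anterior_left != kymo.anterior_left


class TestDetectAndLink:
    def test_recovers_ground_truth_positions(self, single_vesicle_spec):
        spec = single_vesicle_spec(1.5, frames=60, start=20.0)
        movie, truth = make_movie(spec)
        tracks = detect_and_link(build_kymograph(movie), 30.0)
        assert len(tracks) == 1
        true_px = truth.tracks["x_um"].to_numpy() / PX
        assert len(tracks[0]) == len(true_px)
        np.testing.assert_allclose(tracks[0].x_px, true_px, atol=1.0)

    def test_empty_movie_gives_no_tracks(self):
        movie = TimeLapse(np.zeros((10, 8, 50)), 3.1, PX)
        assert detect_and_link(build_kymograph(movie), 10.0) == []

    def test_max_link_floor_enforced(self):
        kymo = Kymograph(np.zeros((5, 50)), PX, DT)
        with pytest.raises(ValueError):
            detect_and_link(kymo, 10.0, max_link_px=2)

    def test_crossing_tracks_both_retained(self):
        # two vesicles crossing: greedy linking keeps two tracks covering
        # all detections (identities may swap at the crossing)
        frames = np.zeros((30, 9, 120))
        yy, xx = np.mgrid[0:9, 0:120]
        for t in range(30):
            for x0 in (20 + 2.5 * t, 95 - 2.5 * t):
                frames[t] += 100 * np.exp(
                    -((xx - x0) ** 2 + (yy - 4) ** 2) / (2 * 1.5**2))
        tracks = detect_and_link(build_kymograph(TimeLapse(frames, 3.1, PX)), 30.0)
        long_tracks = [t for t in tracks if len(t) >= 10]
        assert len(long_tracks) >= 2
        n_points = sum(len(t) for t in tracks)
        assert n_points >= 2 * 30 - 6  # nearly all detections linked


class TestClassifyTrack:
    def test_immobile_positions_are_stationary(self):
        t = classify_track(track_from_positions([10, 10, 10, 10, 10]))
        assert t.track_class == "stationary"
        assert t.direction == "none"

    def test_three_px_steps_are_mobile_anterograde(self):
        # +3 px per frame, x increasing = rightward = posterior
        t = classify_track(track_from_positions([10, 13, 16, 19]))
        assert t.track_class == "mobile"
        assert t.direction == "anterograde"

    def test_short_slow_drift_is_excluded(self):
        t = classify_track(track_from_positions([10, 11, 12]))
        assert t.track_class == "excluded"

    def test_leftward_track_is_retrograde(self):
        t = classify_track(track_from_positions([50, 46, 42, 38]))
        assert t.direction == "retrograde"

    def test_single_point_track_excluded_with_reason(self):
        t = classify_track(track_from_positions([10.0]))
        assert t.track_class == "excluded"
        assert t.exclusion_reason

    def test_every_track_gets_exactly_one_class(self, rng):
        classes = set()
        for _ in range(50):
            x = np.cumsum(rng.integers(-4, 5, size=rng.integers(1, 20)))
            t = classify_track(track_from_positions(x))
            assert t.track_class in {"mobile", "stationary", "excluded"}
            classes.add(t.track_class)
        assert classes == {"mobile", "stationary", "excluded"}

    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=25))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_mirror_symmetry_swaps_direction_only(self, steps):
        x = np.cumsum(np.array([0] + steps)).astype(float)
        t = classify_track(track_from_positions(x))
        m = classify_track(track_from_positions(-x))
        assert t.track_class == m.track_class
        swap = {"anterograde": "retrograde",
                "retrograde": "anterograde", "none": "none"}
        assert m.direction == swap[t.direction]


class TestSegmentRuns:
    def test_hand_worked_pause_and_reversal(self):
        # +6 px, pause, -6 px: two events of 0.96 µm each
        t = track_from_positions([0, 3, 6, 6, 6, 6, 3, 0])
        events = segment_runs(t, move_px=3)
        assert len(events) == 2
        assert events[0].direction == "anterograde"
        assert events[1].direction == "retrograde"
        for ev in events:
            assert ev.run_length_um == pytest.approx(6 * PX)  # 0.96 µm
        assert events[0].run_length_um == pytest.approx(0.96)

    def test_monotone_track_single_event(self):
        t = track_from_positions(np.arange(0, 60, 4))
        events = segment_runs(t, move_px=3)
        assert len(events) == 1
        assert events[0].start_frame == 0
        assert events[0].end_frame == len(t) - 1

    def test_stationary_track_has_no_events(self):
        assert segment_runs(track_from_positions([5, 5, 5, 5])) == []

    def test_event_displacement_bounded_by_path_length(self, rng):
        for _ in range(30):
            x = np.cumsum(rng.integers(-5, 6, size=25)).astype(float)
            t = track_from_positions(x)
            events = segment_runs(t, move_px=3)
            total = sum(abs(ev.displacement_px) for ev in events)
            assert total <= np.abs(np.diff(x)).sum() + 1e-9


class TestTrackVelocity:
    def test_constant_speed_arithmetic(self):
        # 2 px/frame at 0.16 µm/px and 3.1 fps -> 0.992 µm/s
        t = track_from_positions(np.arange(0, 40, 2))
        t.runs = segment_runs(t, move_px=2)
        assert track_velocity(t, move_px=2) == pytest.approx(0.992)

    def test_pausing_vesicle_recovered_within_five_percent(self):
        spec = SimMovieSpec(
            frames=150,
            vesicles=(VesicleSpec(10.0, 1.2, pause_prob_per_frame=0.03,
                                  pause_len_frames=5),),
            noise_sd=0.5, seed=4)
        movie, _ = make_movie(spec)
        tracks = [classify_track(t)
                  for t in detect_and_link(build_kymograph(movie), 30.0)]
        mobile = [t for t in tracks if t.track_class == "mobile"]
        assert mobile
        v = max(t.mean_velocity_um_per_s for t in mobile)
        assert v == pytest.approx(1.2, rel=0.05)

    def test_stationary_track_velocity_undefined(self):
        t = classify_track(track_from_positions([5, 5, 5, 5, 5]))
        with pytest.raises(ValueError, match="undefined"):
            track_velocity(t)


class TestTransportSummary:
    def _mobile(self, n, direction=+1):
        out = []
        for i in range(n):
            x = np.arange(0, 40, 4.0) * direction + 50
            t = classify_track(track_from_positions(x))
            t.track_id = i
            out.append(t)
        return out

    def test_flux_arithmetic(self):
        # 6 mobile tracks over 18 µm for 100 s -> 0.2 per µm per minute
        tracks = self._mobile(6)
        s = transport_summary(tracks, region_length_um=18.0, duration_s=100.0)
        assert s.flux_per_um_per_min == pytest.approx(0.2)

    def test_no_mobile_tracks(self):
        t = classify_track(track_from_positions([5, 5, 5, 5, 5]))
        s = transport_summary([t], region_length_um=18.0, duration_s=100.0)
        assert s.flux_per_um_per_min == 0.0
        assert np.isnan(s.frac_anterograde)

    def test_zero_duration_rejected(self):
        with pytest.raises(ZeroDivisionError):
            transport_summary([], region_length_um=18.0, duration_s=0.0)

    def test_direction_fractions_from_simulated_population(self):
        # 7 anterograde + 3 retrograde -> fractions 0.7 / 0.3
        tracks = self._mobile(7, +1) + self._mobile(3, -1)
        s = transport_summary(tracks, 18.0, 100.0)
        assert s.frac_anterograde == pytest.approx(0.7)
        assert s.frac_retrograde == pytest.approx(0.3)

    def test_flux_scales_linearly_with_mobile_count(self):
        f = [transport_summary(self._mobile(n), 18.0, 100.0).flux_per_um_per_min
             for n in (2, 4, 8)]
        assert f[1] == pytest.approx(2 * f[0])
        assert f[2] == pytest.approx(4 * f[0])
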