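"""Detection and LAP linking: localization accuracy, gap closing,
duration filtering and TrackMate-export parsing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snowmotility.io import SpotTableError, make_spot_table
from snowmotility.simulate import SimConfig, render_frames, simulate_tracks
from snowmotility.tracking import (
    LinkConfig,
    Track,
    detect_spots_dog,
    filter_spot_columns,
    filter_tracks,
    link_tracks,
    read_trackmate_export,
    tracks_from_spot_table,
)


def _straight_spot_table(tracks_xy0, n_frames=100, step=(2.0, 0.0), fps=30.0,
                         drop_frames=None):
    """Parallel straight tracks; optionally drop given frames of track 0."""
    rows = {"tid": [], "f": [], "x": [], "y": []}
    for tid, (x0, y0) in enumerate(tracks_xy0):
        for f in range(n_frames):
            if tid == 0 and drop_frames and f in drop_frames:
                continue
            rows["tid"].append(tid)
            rows["f"].append(f)
            rows["x"].append(x0 + f * step[0])
            rows["y"].append(y0 + f * step[1])
    frame = np.array(rows["f"])
    spots = make_spot_table(None, frame, frame / fps, rows["x"], rows["y"])
    return spots


class TestDetection:
    def test_single_blob_subpixel_localization(self):
        spots_in = make_spot_table([0], [0], [0.0], [30.3, ], [21.7])
        stack = render_frames(spots_in, psf_sigma_px=2.5, background_level=50.0,
                              noise_sd=0.5, seed=1, shape_px=(48, 64))
        det = detect_spots_dog(stack, diameter_px=10.0, quality_threshold=1.0)
        assert len(det) == 1
        assert abs(det["POSITION_X"].iloc[0] - 30.3) < 0.5
        assert abs(det["POSITION_Y"].iloc[0] - 21.7) < 0.5
        assert det["QUALITY"].iloc[0] > 1.0

    def test_blank_frames_yield_no_spots(self):
        rng = np.random.default_rng(0)
        stack = rng.normal(50, 0.5, size=(3, 40, 40))
        det = detect_spots_dog(stack, diameter_px=10.0, quality_threshold=1.0)
        assert len(det) == 0

    def test_two_separated_blobs(self):
        spots_in = make_spot_table([0, 1], [0, 0], [0.0, 0.0], [20.0, 60.0], [25.0, 25.0])
        stack = render_frames(spots_in, psf_sigma_px=2.5, background_level=50.0,
                              noise_sd=0.5, seed=2, shape_px=(50, 90))
        det = detect_spots_dog(stack, diameter_px=10.0, quality_threshold=1.0)
        assert len(det) == 2

    def test_empty_stack_and_bad_diameter(self):
        with pytest.raises(ValueError):
            detect_spots_dog(np.empty((0, 4, 4)), 10.0, 1.0)
        with pytest.raises(ValueError):
            detect_spots_dog(np.zeros((1, 4, 4)), -1.0, 1.0)


class TestLinking:
    def test_two_parallel_tracks_no_switches(self):
        spots = _straight_spot_table([(0.0, 0.0), (0.0, 500.0)])
        tracks = link_tracks(spots, LinkConfig())
        assert len(tracks) == 2
        for t in tracks:
            assert np.ptp(t.y_um) == 0.0  # never jumps between the two lines
            assert t.n_spots == 100

    def test_gap_within_limits_is_closed(self):
        spots = _straight_spot_table([(0.0, 0.0)], drop_frames={50, 51, 52, 53, 54})
        # 5 missing frames -> 20 px jump at step 2 px/frame and a 6-frame link
        tracks = link_tracks(spots, LinkConfig())
        assert len(tracks) == 1
        assert tracks[0].n_spots == 95
        assert tracks[0].span_frames == 100

    def test_gap_beyond_frame_limit_splits(self):
        spots = _straight_spot_table([(0.0, 0.0)], n_frames=200,
                                     drop_frames=set(range(80, 120)), step=(1.0, 0.0))
        tracks = link_tracks(spots, LinkConfig())
        assert len(tracks) == 2  # 40-frame gap exceeds the 30-frame limit

    def test_each_spot_used_once_one_per_frame(self):
        cfg = SimConfig(n_motile=10, n_drifting=4, n_stationary=4, seed=21,
                        arena_width_um=3000.0, arena_height_um=3000.0,
                        detection_dropout_p=0.05)
        spots, _ = simulate_tracks(cfg)
        raw = spots.copy()
        raw["TRACK_ID"] = np.nan
        tracks = link_tracks(raw, LinkConfig())
        used = sum(t.n_spots for t in tracks)
        assert used == len(raw)
        for t in tracks:
            assert len(np.unique(t.frames)) == t.n_spots

    def test_linking_deterministic(self):
        spots = _straight_spot_table([(0.0, 0.0), (0.0, 300.0), (100.0, 150.0)])
        a = link_tracks(spots, LinkConfig())
        b = link_tracks(spots, LinkConfig())
        assert [list(t.frames) for t in a] == [list(t.frames) for t in b]
        assert [list(t.x_um) for t in a] == [list(t.x_um) for t in b]


class TestFilters:
    def test_duration_threshold_boundary(self):
        def mk(n):
            f = np.arange(n)
            return Track(0, f, f / 30.0, f * 1.0, f * 0.0)

        assert filter_tracks([mk(74)], 75) == []
        assert len(filter_tracks([mk(75)], 75)) == 1
        assert filter_tracks([], 75) == []

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.integers(min_value=2, max_value=150), min_size=0, max_size=100))
    def test_filter_matches_brute_force(self, lengths):
        tracks = []
        for i, n in enumerate(lengths):
            f = np.arange(n)
            tracks.append(Track(i, f, f / 30.0, f * 1.0, f * 0.0))
        kept = filter_tracks(tracks, 75)
        expected = [t for t in tracks if t.frames[-1] - t.frames[0] + 1 >= 75]
        assert [t.track_id for t in kept] == [t.track_id for t in expected]

    def test_column_threshold_filter(self):
        spots = make_spot_table([0, 0], [0, 1], [0.0, 1 / 30], [1.0, 2.0], [0.0, 0.0],
                                quality=[0.5, 2.0])
        out = filter_spot_columns(spots, {"QUALITY": 1.0})
        assert len(out) == 1
        assert filter_spot_columns(spots, None) is spots


class TestTrackmateExport:
    def test_parses_extra_header_rows(self, tmp_path):
        path = tmp_path / "spots.csv"
        path.write_text(
            "TRACK_ID,FRAME,POSITION_T,POSITION_X,POSITION_Y,QUALITY\n"
            "Track ID,Frame,T,X,Y,Quality\n"
            "Track ID,Frame,(sec),(micron),(micron),(quality)\n"
            ",,,,,\n"
            "0,0,0.0,1.5,2.5,1.0\n"
            "0,1,0.033,2.5,2.5,1.0\n"
            "1,0,0.0,50.0,60.0,1.0\n"
            "1,1,0.033,51.0,60.0,1.0\n"
        )
        tracks = read_trackmate_export(path)
        assert len(tracks) == 2
        assert tracks[0].x_um[0] == pytest.approx(1.5)

    def test_unit_override_scales_positions(self, tmp_path):
        path = tmp_path / "spots.csv"
        path.write_text(
            "TRACK_ID,FRAME,POSITION_T,POSITION_X,POSITION_Y\n0,0,0.0,10,0\n0,1,0.033,20,0\n"
        )
        tracks = read_trackmate_export(path, position_unit_um=0.5)
        assert tracks[0].x_um.tolist() == [5.0, 10.0]

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("TRACK_ID,FRAME,POSITION_T,POSITION_X\n0,0,0.0,1.0\n")
        with pytest.raises(SpotTableError, match="POSITION_Y"):
            read_trackmate_export(path)


def test_track_requires_increasing_frames():
    with pytest.raises(ValueError):
        Track(0, [0, 0, 1], [0.0, 0.0, 0.1], [0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
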