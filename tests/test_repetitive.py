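"""Swim segmentation and the three repetitive-behaviour classifiers."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from zebraswim import (
    detect_back_and_forth,
    detect_large_circle,
    detect_stereotypic,
    positional_span,
    segment_swimming,
    summarize_repetitive,
)
from zebraswim.repetitive import SwimBout

from conftest import circle_path, make_traj


def span_oracle(points):
    """O(n^2) all-pairs spatial span."""
    return float(pdist(points).max()) if len(points) > 1 else 0.0


def winding_oracle(x, y, center):
    """Total signed angle swept about a centre, by atan2 increments."""
    th = np.arctan2(np.asarray(y) - center[1], np.asarray(x) - center[0])
    d = np.diff(th)
    d = (d + np.pi) % (2 * np.pi) - np.pi
    return float(d.sum())


class TestPositionalSpan:
    @pytest.mark.parametrize("n", [2, 10, 59, 200, 500])
    def test_matches_all_pairs_oracle(self, n):
        rng = np.random.default_rng(n)
        pts = np.cumsum(rng.normal(0, 1.5, (n, 2)), axis=0)
        assert positional_span(pts) == pytest.approx(span_oracle(pts), rel=1e-12)

    def test_collinear_points(self):
        pts = np.column_stack([np.linspace(0, 9, 100), np.linspace(0, 9, 100)])
        assert positional_span(pts) == pytest.approx(np.hypot(9, 9))


class TestSegmentSwimming:
    def test_always_moving_single_interval(self):
        traj = make_traj(np.arange(250) * 1.0, np.zeros(250))  # 25 mm/s
        segs = segment_swimming(traj)
        assert len(segs) == 1
        assert segs[0] == (0.0, pytest.approx(249 / 25))

    def test_always_stationary_empty(self):
        traj = make_traj(np.full(250, 1.0), np.full(250, 1.0))
        assert segment_swimming(traj) == []

    def test_swim_stop_swim_two_intervals(self):
        # 10 s swim, 1 s stop, 10 s swim at 25 fps
        seg = np.concatenate([np.ones(250), np.zeros(25), np.ones(250)])
        x = np.concatenate([[0.0], np.cumsum(seg)])
        traj = make_traj(x, np.zeros_like(x))
        segs = segment_swimming(traj)
        assert len(segs) == 2


class TestDetectStereotypic:
    def test_confined_jitter_yields_one_bout(self):
        rng = np.random.default_rng(1)
        th = rng.uniform(0, 2 * np.pi, 251)
        r = rng.uniform(0, 2.5, 251)  # 10 s inside a 5 mm disk, always moving
        traj = make_traj(100 + r * np.cos(th), 100 + r * np.sin(th))
        bouts = detect_stereotypic(traj)
        assert len(bouts) == 1
        assert bouts[0].metrics["max_span_mm"] < 30.0
        assert bouts[0].duration_s > 5.0

    def test_too_short_confinement_no_bout(self):
        rng = np.random.default_rng(2)
        th = rng.uniform(0, 2 * np.pi, 101)  # 4 s only
        traj = make_traj(100 + 2 * np.cos(th), 100 + 2 * np.sin(th))
        assert detect_stereotypic(traj) == []

    def test_bout_truncated_before_span_violation(self):
        # 7 s confined, then a straight dash that breaks the 30 mm span;
        # the expected truncation frame comes from the all-pairs oracle
        rng = np.random.default_rng(3)
        th = rng.uniform(0, 2 * np.pi, 176)
        x = np.concatenate([100 + 3 * np.cos(th), 100 + np.arange(1, 101) * 2.0])
        y = np.concatenate([100 + 3 * np.sin(th), np.full(100, 100.0)])
        pts = np.column_stack([x, y])
        j_end = max(j for j in range(1, len(pts)) if span_oracle(pts[: j + 1]) < 30.0)
        bouts = detect_stereotypic(make_traj(x, y))
        assert len(bouts) == 1
        assert bouts[0].end_s == pytest.approx(j_end / 25.0)
        assert bouts[0].metrics["max_span_mm"] < 30.0

    @pytest.mark.parametrize("seed", range(8))
    def test_emitted_windows_agree_with_span_oracle(self, seed):
        """Every emitted bout's span < 30 per the all-pairs oracle, and the
        frame right after a truncated bout would violate it."""
        rng = np.random.default_rng(seed)
        n = 500
        x = 150 + np.cumsum(rng.normal(0.0, 1.2, n))
        y = 150 + np.cumsum(rng.normal(0.0, 1.2, n))
        traj = make_traj(x, y)
        for b in detect_stereotypic(traj):
            i0 = int(round(b.start_s * 25))
            i1 = int(round(b.end_s * 25))
            window = np.column_stack([x[i0 : i1 + 1], y[i0 : i1 + 1]])
            assert span_oracle(window) < 30.0
            if i1 + 1 < n:
                extended = np.column_stack([x[i0 : i1 + 2], y[i0 : i1 + 2]])
                assert span_oracle(extended) >= 30.0


class TestDetectLargeCircle:
    def test_three_ccw_revolutions(self, dish):
        traj = circle_path(16.0, 2 * np.pi / 10, 30.4)  # just over 3 revolutions
        loops = detect_large_circle(traj, dish)
        assert len(loops) == 3
        assert all(b.label == "large_circle_ccw" for b in loops)

    def test_half_revolution_no_loop(self, dish):
        traj = circle_path(16.0, 2 * np.pi / 10, 5.0)
        assert detect_large_circle(traj, dish) == []

    def test_cw_labelled(self, dish):
        traj = circle_path(16.0, -2 * np.pi / 10, 10.5)
        loops = detect_large_circle(traj, dish)
        assert len(loops) == 1 and loops[0].label == "large_circle_cw"

    def test_off_band_circle_ignored(self, dish):
        traj = circle_path(5.0, 2 * np.pi / 10, 30.0)  # well inside, off the band
        assert detect_large_circle(traj, dish) == []
        assert len(detect_large_circle(traj, dish, edge_band_only=False)) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_noisy_wall_following_matches_winding_oracle(self, dish, seed):
        rng = np.random.default_rng(seed)
        n_rev = rng.integers(2, 6)
        n = int(n_rev * 250)
        ang = np.cumsum(rng.normal(2 * np.pi * n_rev / n, np.deg2rad(1.0), n))
        r = 16.0 + rng.normal(0, 0.3, n)
        x, y = r * np.cos(ang), r * np.sin(ang)
        traj = make_traj(x, y)
        loops = detect_large_circle(traj, dish)
        expected = int(abs(winding_oracle(x, y, (0, 0))) // (2 * np.pi))
        assert len(loops) == expected

    def test_time_reversal_swaps_cw_ccw(self, dish):
        traj = circle_path(16.0, 2 * np.pi / 10, 25.0)
        fwd = detect_large_circle(traj, dish)
        rev = detect_large_circle(
            make_traj(traj.x_mm[::-1], traj.y_mm[::-1]), dish
        )
        assert len(fwd) == len(rev)
        assert {b.label for b in fwd} == {"large_circle_ccw"}
        assert {b.label for b in rev} == {"large_circle_cw"}


class TestDetectBackAndForth:
    def test_out_and_back_along_one_wall(self, tank):
        t = np.arange(0, 20.04, 0.04)
        x = np.where(t <= 10, 50 + 15 * t, 50 + 15 * (20 - t))
        traj = make_traj(x, np.full_like(t, 10.0), t=t)
        bouts = detect_back_and_forth(traj, tank)
        assert len(bouts) == 1
        assert bouts[0].metrics["n_walls"] == 1.0

    def test_single_pass_no_return(self, tank):
        t = np.arange(0, 20.04, 0.04)
        traj = make_traj(50 + 10 * t, np.full_like(t, 10.0), t=t)
        assert detect_back_and_forth(traj, tank) == []

    def test_l_path_two_adjacent_edges(self, tank):
        t = np.arange(0, 40.04, 0.04)
        pts = []
        for tt in t:
            d = 15 * tt if tt <= 20 else 15 * (40 - tt)
            pts.append((50 + d, 10.0) if d <= 240 else (290.0, 10 + (d - 240)))
        xy = np.array(pts)
        bouts = detect_back_and_forth(make_traj(xy[:, 0], xy[:, 1], t=t), tank)
        assert len(bouts) == 1
        assert bouts[0].metrics["n_walls"] == 2.0

    def test_opposite_edge_traversal_excluded(self, tank):
        # bottom wall end to end (left wall to right wall) and back
        t = np.arange(0, 60.04, 0.04)
        pts = []
        for tt in t:
            d = 15 * tt if tt <= 30 else 15 * (60 - tt)
            pts.append((10 + min(d, 280), 10.0) if d <= 280 else (290.0, 10 + (d - 280)))
        xy = np.array(pts)
        assert detect_back_and_forth(make_traj(xy[:, 0], xy[:, 1], t=t), tank) == []

    def test_short_oscillation_below_min_leg_excluded(self, tank):
        t = np.arange(0, 20.04, 0.04)
        x = 150 + 20 * np.sin(2 * np.pi * t / 10)  # 40 mm swings < 50 mm floor
        traj = make_traj(x, np.full_like(t, 10.0), t=t)
        assert detect_back_and_forth(traj, tank) == []

    def test_circular_arena_rejected(self, dish):
        traj = circle_path(16.0, 1.0, 5.0)
        with pytest.raises(ValueError):
            detect_back_and_forth(traj, dish)


class TestSummary:
    def test_empty_is_all_zeros(self):
        s = summarize_repetitive([], (0.0, 100.0))
        assert all(v == 0 for v in s.counts.values())
        assert all(v == 0.0 for v in s.durations_s.values())

    def test_counts_and_durations(self):
        bouts = [
            SwimBout("f", "stereotypic", 10.0 * i, 10.0 * i + 6.0) for i in range(3)
        ]
        s = summarize_repetitive(bouts, (0.0, 60.0))
        assert s.counts["stereotypic"] == 3
        assert s.durations_s["stereotypic"] == pytest.approx(18.0)

    def test_mixed_labels_partition(self):
        bouts = [
            SwimBout("f", "stereotypic", 0.0, 6.0),
            SwimBout("f", "back_and_forth", 10.0, 15.0),
            SwimBout("f", "large_circle_cw", 20.0, 30.0),
        ]
        s = summarize_repetitive(bouts, (0.0, 40.0))
        assert s.counts == {
            "back_and_forth": 1,
            "stereotypic": 1,
            "large_circle_cw": 1,
            "large_circle_ccw": 0,
        }

    def test_bout_outside_window_rejected(self):
        with pytest.raises(ValueError):
            summarize_repetitive([SwimBout("f", "stereotypic", 0.0, 200.0)], (0.0, 100.0))
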