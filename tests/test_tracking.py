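"""Trajectory container, CSV round trips, gap filling, jitter suppression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zebraswim import Trajectory, read_tracking, suppress_jitter, write_tracking
from zebraswim.tracking import fill_gaps

from conftest import make_traj


def total_path(traj):
    ok = ~(traj.missing[:-1] | traj.missing[1:])
    return float(np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm))[ok].sum())


class TestTrajectory:
    def test_rejects_non_monotone_time(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_traj([0, 1, 2], [0, 0, 0], t=np.array([0.0, 0.5, 0.5]))

    def test_rejects_short(self):
        with pytest.raises(ValueError):
            make_traj([1.0], [1.0])

    def test_nan_positions_become_missing(self):
        traj = make_traj([0.0, np.nan, 2.0], [0.0, 1.0, 2.0])
        assert traj.missing.tolist() == [False, True, False]


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, well):
        rng = np.random.default_rng(1)
        trajs = []
        for fid in ("a", "b"):
            th = rng.uniform(0, 2 * np.pi, 100)
            r = 8.0 * np.sqrt(rng.uniform(size=100))
            trajs.append(
                make_traj(r * np.cos(th), r * np.sin(th), fish_id=fid, arena_id=well.arena_id)
            )
        path = tmp_path / "track.csv"
        write_tracking(trajs, path)
        back = read_tracking(path, well)
        assert [t.fish_id for t in back] == ["a", "b"]
        for orig, rt in zip(trajs, back):
            assert len(rt) == 100
            np.testing.assert_allclose(rt.x_mm, orig.x_mm, atol=1e-6)
            np.testing.assert_allclose(rt.y_mm, orig.y_mm, atol=1e-6)
            np.testing.assert_allclose(rt.t_s, orig.t_s, atol=1e-6)

    def test_empty_set_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_tracking([], path)
        assert path.read_text() == "fish_id,frame,t_s,x_mm,y_mm,arena_id\n"

    def test_mixed_frame_rates_rejected(self, tmp_path):
        a = make_traj([0, 1, 2], [0, 0, 0], fps=25.0)
        b = make_traj([0, 1, 2], [0, 0, 0], fps=30.0)
        with pytest.raises(ValueError, match="frame rates"):
            write_tracking([a, b], tmp_path / "x.csv")

    def test_malformed_header_lists_missing_columns(self, tmp_path, well):
        p = tmp_path / "bad.csv"
        p.write_text("fish_id,frame,t_s,x_mm\n1,0,0.0,1.0\n")
        with pytest.raises(ValueError, match="y_mm"):
            read_tracking(p, well)

    def test_duplicate_timestamps_name_the_fish(self, tmp_path, well):
        p = tmp_path / "dup.csv"
        p.write_text(
            "fish_id,frame,t_s,x_mm,y_mm,arena_id\n"
            "f9,0,0.0,1.0,1.0,w\nf9,1,0.0,1.5,1.0,w\n"
        )
        with pytest.raises(ValueError, match="f9"):
            read_tracking(p, well)

    def test_far_outside_point_flagged_missing(self, tmp_path, well):
        p = tmp_path / "out.csv"
        rows = ["fish_id,frame,t_s,x_mm,y_mm,arena_id"]
        for i in range(10):
            x = 14.0 if i == 5 else 1.0  # 5 mm outside the 9 mm well
            rows.append(f"f,{i},{i * 0.04:.2f},{x},0.0,w")
        p.write_text("\n".join(rows) + "\n")
        with pytest.warns(UserWarning, match="outside arena"):
            (traj,) = read_tracking(p, well, max_gap_frames=0)
        assert traj.missing[5]

    def test_slightly_outside_point_clamped(self, tmp_path, well):
        p = tmp_path / "clamp.csv"
        p.write_text(
            "fish_id,frame,t_s,x_mm,y_mm,arena_id\n"
            "f,0,0.00,9.3,0.0,w\nf,1,0.04,8.0,0.0,w\n"
        )
        (traj,) = read_tracking(p, well)
        assert traj.x_mm[0] == pytest.approx(9.0)
        assert not traj.missing[0]


class TestGapFilling:
    def test_short_gap_interpolated(self):
        x = np.array([0.0, np.nan, np.nan, 3.0])
        traj = fill_gaps(make_traj(x, np.zeros(4)))
        np.testing.assert_allclose(traj.x_mm, [0.0, 1.0, 2.0, 3.0])
        assert not traj.missing.any()

    def test_long_gap_left_missing(self):
        x = np.concatenate([[0.0], [np.nan] * 6, [7.0]])
        traj = fill_gaps(make_traj(x, np.zeros(8)), max_gap_frames=5)
        assert traj.missing.sum() == 6

    def test_leading_gap_not_extrapolated(self):
        x = np.array([np.nan, 1.0, 2.0])
        traj = fill_gaps(make_traj(x, np.zeros(3)))
        assert traj.missing[0]


class TestSuppressJitter:
    def test_zero_threshold_is_identity(self):
        traj = make_traj([0, 0.05, 0.1], [0, 0, 0])
        out = suppress_jitter(traj, 0.0)
        np.testing.assert_array_equal(out.x_mm, traj.x_mm)

    def test_gaussian_jitter_collapses_to_zero_distance(self):
        # sigma = 0.05 mm wobble around a fixed point: every deadband test
        # stays below 0.2 mm with high probability; asserted for a seed
        # verified against the threshold-then-sum oracle
        rng = np.random.default_rng(1)
        n = 300
        traj = make_traj(rng.normal(0, 0.05, n), rng.normal(0, 0.05, n))
        out = suppress_jitter(traj, 0.2)
        assert total_path(out) == 0.0

    def test_straight_run_unchanged(self):
        traj = make_traj(np.arange(50) * 2.0, np.zeros(50))
        out = suppress_jitter(traj, 0.2)
        assert total_path(out) == pytest.approx(total_path(traj))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            suppress_jitter(make_traj([0, 1], [0, 0]), -0.1)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_never_increases_path_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        traj = make_traj(
            np.cumsum(rng.normal(0, 0.3, n)), np.cumsum(rng.normal(0, 0.3, n))
        )
        once = suppress_jitter(traj, 0.25)
        assert total_path(once) <= total_path(traj) + 1e-9
        twice = suppress_jitter(once, 0.25)
        np.testing.assert_array_equal(once.x_mm, twice.x_mm)
        np.testing.assert_array_equal(once.y_mm, twice.y_mm)
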