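"""The synthetic swim simulator: determinism, distributions, ground truth."""

import dataclasses

import numpy as np
import pytest

from zebraswim import (
    AgentParams,
    interindividual_distance,
    make_cohort,
    simulate_fish,
    simulate_group,
    simulate_shoal,
)
from zebraswim.geometry import constant_light_schedule, make_pmr_schedule


class TestDeterminism:
    def test_same_seed_identical_fish(self, tank):
        p = AgentParams(mean_speed_mm_s=30.0, wall_bias=0.1)
        a, _ = simulate_fish(p, tank, None, 30.0, seed=5)
        b, _ = simulate_fish(p, tank, None, 30.0, seed=5)
        np.testing.assert_array_equal(a.x_mm, b.x_mm)
        np.testing.assert_array_equal(a.y_mm, b.y_mm)

    def test_different_seed_differs(self, tank):
        p = AgentParams(mean_speed_mm_s=30.0)
        a, _ = simulate_fish(p, tank, None, 10.0, seed=5)
        b, _ = simulate_fish(p, tank, None, 10.0, seed=6)
        assert not np.array_equal(a.x_mm, b.x_mm)

    def test_same_seed_identical_shoal(self, tank):
        p = AgentParams(mean_speed_mm_s=30.0, cohesion=0.5)
        sa, _ = simulate_shoal(4, p, tank, 10.0, seed=1)
        sb, _ = simulate_shoal(4, p, tank, 10.0, seed=1)
        for a, b in zip(sa, sb):
            np.testing.assert_array_equal(a.x_mm, b.x_mm)


class TestWalkStatistics:
    def test_positions_inside_arena(self, well, tank):
        for arena in (well, tank):
            p = AgentParams(mean_speed_mm_s=8.0 if arena is well else 40.0, wall_bias=0.3)
            traj, _ = simulate_fish(p, arena, None, 60.0, seed=2)
            assert np.all(arena.wall_distance(traj.x_mm, traj.y_mm) >= -1e-9)

    def test_mean_speed_matches_parameter(self, tank):
        p = AgentParams(mean_speed_mm_s=25.0, wall_bias=0.0, turn_sd_rad=0.1)
        traj, _ = simulate_fish(p, tank, None, 400.0, seed=3)  # 10^4 steps
        steps = np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm))
        speeds = steps * traj.frame_rate_hz
        n = len(speeds)
        # gamma(shape=3): sd = mean/sqrt(3); 3-sigma band on the sample mean,
        # with slack for wall-contact steps being shortened
        sem = 25.0 / np.sqrt(3) / np.sqrt(n)
        assert abs(speeds.mean() - 25.0) < 3 * sem + 0.3

    def test_dark_multiplier_scales_speed(self, well):
        sched = make_pmr_schedule("methods")
        p = AgentParams(mean_speed_mm_s=2.5, dark_multiplier=2.0, turn_sd_rad=0.5)
        traj, _ = simulate_fish(p, well, sched, sched.span_s, seed=4)
        dark = np.asarray(sched.condition_at(traj.t_s[:-1])) == "dark"
        steps = np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm))
        ratio = steps[dark].mean() / steps[~dark].mean()
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_invalid_params_rejected_before_simulation(self, tank):
        with pytest.raises(ValueError):
            simulate_fish(AgentParams(mean_speed_mm_s=-1.0), tank, None, 10.0, seed=0)
        with pytest.raises(ValueError):
            simulate_fish(AgentParams(wall_bias=1.5), tank, None, 10.0, seed=0)
        with pytest.raises(ValueError):
            simulate_fish(
                AgentParams(bout_rates={"nonsense": 0.1}), tank, None, 10.0, seed=0
            )


class TestGroundTruth:
    def test_bouts_disjoint_within_span(self, tank):
        p = AgentParams(
            mean_speed_mm_s=30.0,
            bout_rates={"stereotypic": 1 / 60, "large_circle": 1 / 60, "back_and_forth": 1 / 60},
        )
        _, log = simulate_fish(p, tank, None, 600.0, seed=8)
        assert log.bouts, "expected at least one injected bout"
        ivals = sorted((b["start_s"], b["end_s"]) for b in log.bouts)
        for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
            assert e0 <= s1 + 1e-9
        for s0, e0 in ivals:
            assert 0 <= s0 < e0 <= 600.0

    def test_truth_json_round_trip(self, tank, tmp_path):
        p = AgentParams(mean_speed_mm_s=30.0, bout_rates={"stereotypic": 1 / 50})
        _, log = simulate_fish(p, tank, None, 300.0, seed=9)
        path = tmp_path / "truth.json"
        log.to_json(path)
        from zebraswim import GroundTruthLog

        back = GroundTruthLog.from_json(path)
        assert back.bouts == log.bouts
        assert back.seed == log.seed


class TestShoal:
    def test_uncoupled_headings_uncorrelated(self, tank):
        p = AgentParams(mean_speed_mm_s=30.0, wall_bias=0.0, cohesion=0.0, turn_sd_rad=0.2)
        corrs = []
        for seed in range(12):
            trajs, _ = simulate_shoal(2, p, tank, 120.0, seed=seed)
            h = []
            for t in trajs:
                dx, dy = np.diff(t.x_mm), np.diff(t.y_mm)
                h.append(np.arctan2(dy, dx))
            corrs.append(np.corrcoef(np.cos(h[0]), np.cos(h[1]))[0, 1])
        # mean correlation within 3 sigma of zero
        corrs = np.asarray(corrs)
        assert abs(corrs.mean()) < 3 * corrs.std(ddof=1) / np.sqrt(len(corrs))

    def test_cohesion_tightens_shoal(self, tank):
        p_tight = AgentParams(mean_speed_mm_s=30.0, cohesion=0.9)
        p_loose = AgentParams(mean_speed_mm_s=30.0, cohesion=0.0)
        wins = 0
        n_pairs = 15
        for seed in range(n_pairs):
            st, _ = simulate_shoal(6, p_tight, tank, 60.0, seed=seed)
            sl, _ = simulate_shoal(6, p_loose, tank, 60.0, seed=seed)
            wins += (
                interindividual_distance(st).mean_iid_mm
                < interindividual_distance(sl).mean_iid_mm
            )
        assert wins >= n_pairs - 1

    def test_k_below_two_rejected(self, tank):
        with pytest.raises(ValueError):
            simulate_shoal(1, AgentParams(), tank, 10.0, seed=0)


class TestCohort:
    def test_file_count_and_determinism(self, tmp_path):
        out1 = tmp_path / "a"
        out2 = tmp_path / "b"
        m1 = make_cohort(2, None, None, "open_field", seed=3, out_dir=out1, duration_s=20.0)
        m2 = make_cohort(2, None, None, "open_field", seed=3, out_dir=out2, duration_s=20.0)
        files1 = sorted(p.name for p in out1.glob("*.csv"))
        assert len(files1) == 4
        for name in files1:
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
        assert (
            (out1 / "ground_truth.json").read_bytes()
            == (out2 / "ground_truth.json").read_bytes()
        )

    def test_unknown_assay_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="assay"):
            make_cohort(2, None, None, "nonsense", seed=0, out_dir=tmp_path)

    def test_shoaling_cohort_writes_shoal_files(self, tmp_path):
        m = make_cohort(
            1, None, None, "shoaling", seed=1, out_dir=tmp_path, duration_s=10.0, shoal_size=3
        )
        from zebraswim import read_tracking

        trajs = read_tracking(m.files["wt"][0], m.arena)
        assert len(trajs) == 3
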