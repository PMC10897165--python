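"""Distance, per-minute activity binning, and photomotor response ratios.

Distance is the sum of Euclidean chord lengths between consecutive
tracked frames.  Steps with a missing endpoint contribute no distance
(a long dropout splits the path rather than fabricating a jump).
Time bins are left-closed right-open; a step straddling a bin edge is
prorated linearly in time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import LightSchedule
from .tracking import Trajectory

__all__ = [
    "BinnedActivity",
    "CycleResponse",
    "path_distance",
    "bin_activity",
    "mean_distance_per_min",
    "light_dark_ratio",
]


def _step_arrays(traj: Trajectory):
    """Per-step (t0, t1, length) with zero length for steps touching a gap."""
    dx = np.diff(traj.x_mm)
    dy = np.diff(traj.y_mm)
    lengths = np.hypot(dx, dy)
    bad = traj.missing[:-1] | traj.missing[1:]
    lengths[bad] = 0.0
    return traj.t_s[:-1], traj.t_s[1:], lengths


def path_distance(traj: Trajectory, t0_s: float, t1_s: float) -> float:
    """Path length travelled in the window [t0_s, t1_s).

    Steps partially inside the window contribute in proportion to the
    time overlap, assuming constant speed within a frame interval.
    """
    if t1_s <= t0_s:
        raise ValueError("need t0_s < t1_s")
    lo, hi = traj.span_s
    if t0_s < lo - 1e-9 or t1_s > hi + 1e-9:
        raise ValueError(
            f"window [{t0_s}, {t1_s}) outside trajectory span [{lo}, {hi}]"
        )
    ta, tb, lengths = _step_arrays(traj)
    overlap = np.minimum(tb, t1_s) - np.maximum(ta, t0_s)
    frac = np.clip(overlap / (tb - ta), 0.0, 1.0)
    return float(np.sum(lengths * frac))


@dataclass
class BinnedActivity:
    """Distance travelled per fixed-duration time bin, labelled by epoch."""

    fish_id: str
    bin_duration_s: float
    bin_start_s: np.ndarray
    distance_mm: np.ndarray
    epoch: np.ndarray  # label strings, one per bin

    def __len__(self) -> int:
        return len(self.bin_start_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fish_id": self.fish_id,
                "bin_start_s": self.bin_start_s,
                "epoch": self.epoch,
                "distance_mm": self.distance_mm,
            }
        )


def bin_activity(
    traj: Trajectory,
    schedule: LightSchedule,
    bin_s: float = 60.0,
    t0_s: Optional[float] = None,
    t1_s: Optional[float] = None,
) -> BinnedActivity:
    """Pool a trajectory into fixed time bins labelled by light epoch.

    Bins tile [t0_s, t1_s) (default: the whole schedule span); each bin is
    labelled with the epoch covering its midpoint, the convention used for
    bins that straddle a light/dark transition.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    min_epoch = min(e.end_s - e.start_s for e in schedule.epochs)
    if bin_s > min_epoch:
        raise ValueError(
            f"bin of {bin_s} s exceeds the shortest epoch ({min_epoch} s); "
            "epoch labels would be ambiguous"
        )
    t0 = 0.0 if t0_s is None else float(t0_s)
    t1 = schedule.span_s if t1_s is None else float(t1_s)
    lo, hi = traj.span_s
    if t0 < lo - 1e-9 or t1 > hi + 1e-9:
        raise ValueError("binning window not covered by the trajectory")
    n_bins = int(np.floor((t1 - t0) / bin_s + 1e-9))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    starts = t0 + bin_s * np.arange(n_bins)
    ta, tb, lengths = _step_arrays(traj)
    dist = np.empty(n_bins)
    for i, s in enumerate(starts):
        overlap = np.minimum(tb, s + bin_s) - np.maximum(ta, s)
        frac = np.clip(overlap / (tb - ta), 0.0, 1.0)
        dist[i] = np.sum(lengths * frac)
    labels = schedule.label_at(starts + bin_s / 2.0)
    return BinnedActivity(
        fish_id=traj.fish_id,
        bin_duration_s=bin_s,
        bin_start_s=starts,
        distance_mm=dist,
        epoch=np.asarray(labels),
    )


def mean_distance_per_min(binned: BinnedActivity, epoch_label: str) -> float:
    """Mean distance per minute over the bins of one epoch."""
    sel = binned.epoch == epoch_label
    if not sel.any():
        raise ValueError(f"no bins labelled {epoch_label!r}")
    per_bin = binned.distance_mm[sel]
    return float(per_bin.mean() * (60.0 / binned.bin_duration_s))


@dataclass
class CycleResponse:
    """Dark/light activity ratio for one light-dark transition cycle."""

    cycle: int
    mean_dark_mm_per_min: float
    mean_light_mm_per_min: float
    ratio: float
    undefined: bool = False


def light_dark_ratio(binned: BinnedActivity, cycle: int) -> CycleResponse:
    """Ratio of mean dark-phase to mean light-phase distance for a cycle.

    The photomotor response of larvae is a burst of locomotion when the
    light goes out; a ratio above 1 quantifies it.  A zero light-phase
    mean makes the ratio undefined: it is returned as NaN with the
    ``undefined`` flag set rather than raising.
    """
    mean_light = mean_distance_per_min(binned, f"L{cycle}")
    mean_dark = mean_distance_per_min(binned, f"D{cycle}")
    if mean_light <= 0:
        return CycleResponse(cycle, mean_dark, mean_light, float("nan"), undefined=True)
    return CycleResponse(cycle, mean_dark, mean_light, mean_dark / mean_light)
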