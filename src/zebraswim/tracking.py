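"""Centroid tracking time series: the Trajectory container and CSV I/O.

The on-disk format is a plain CSV with the exact header
``fish_id,frame,t_s,x_mm,y_mm,arena_id``; missing positions are empty
fields.  Positions are millimetres in the arena frame defined by
:mod:`zebraswim.geometry`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .geometry import ArenaGeometry

__all__ = [
    "Trajectory",
    "TRACKING_COLUMNS",
    "read_tracking",
    "write_tracking",
    "suppress_jitter",
    "fill_gaps",
]

TRACKING_COLUMNS = ["fish_id", "frame", "t_s", "x_mm", "y_mm", "arena_id"]


@dataclass
class Trajectory:
    """Per-fish time-ordered centroid positions bound to an arena.

    ``missing`` marks frames with no valid position; the corresponding
    x/y entries are NaN.  Timestamps are carried explicitly rather than
    inferred from the frame index, so variable-rate input degrades
    gracefully.
    """

    fish_id: str
    arena_id: str
    frame_rate_hz: float
    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if self.missing is None:
            self.missing = np.isnan(self.x_mm) | np.isnan(self.y_mm)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = len(self.t_s)
        if n < 2:
            raise ValueError("a trajectory needs at least two frames")
        if not (len(self.x_mm) == len(self.y_mm) == len(self.missing) == n):
            raise ValueError("t_s, x_mm, y_mm and missing must have equal length")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError(f"timestamps for fish {self.fish_id!r} are not strictly increasing")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def span_s(self) -> tuple:
        return (float(self.t_s[0]), float(self.t_s[-1]))

    def positions(self) -> np.ndarray:
        """(n, 2) array of positions, NaN where missing."""
        return np.column_stack([self.x_mm, self.y_mm])


def fill_gaps(traj: Trajectory, max_gap_frames: int = 5) -> Trajectory:
    """Linearly interpolate runs of up to ``max_gap_frames`` missing frames.

    Longer dropouts stay missing: a tracker losing the fish for seconds
    must not fabricate motion, whereas one-or-few-frame dropouts are noise.
    Leading/trailing missing frames are never extrapolated.
    """
    miss = traj.missing.copy()
    if not miss.any():
        return traj
    x = traj.x_mm.copy()
    y = traj.y_mm.copy()
    idx = np.flatnonzero(miss)
    # group consecutive missing indices into runs
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0 or hi >= len(miss) or len(run) > max_gap_frames:
            continue
        t = traj.t_s
        frac = (t[run] - t[lo]) / (t[hi] - t[lo])
        x[run] = x[lo] + frac * (x[hi] - x[lo])
        y[run] = y[lo] + frac * (y[hi] - y[lo])
        miss[run] = False
    return replace(traj, x_mm=x, y_mm=y, missing=miss)


def _clamp_to_arena(arena: ArenaGeometry, x: np.ndarray, y: np.ndarray, tol_mm: float):
    """Clamp points within ``tol_mm`` outside the wall onto the boundary;
    return (x, y, out_mask) where out_mask marks points beyond tolerance."""
    depth = arena.wall_distance(x, y)
    with np.errstate(invalid="ignore"):
        slightly_out = (depth < 0) & (depth >= -tol_mm)
        far_out = depth < -tol_mm
    x = x.copy()
    y = y.copy()
    if arena.shape == "circle":
        r = np.hypot(x[slightly_out], y[slightly_out])
        scale = np.where(r > 0, arena.radius_mm / r, 0.0)
        x[slightly_out] *= scale
        y[slightly_out] *= scale
    else:
        x[slightly_out] = np.clip(x[slightly_out], 0.0, arena.width_mm)
        y[slightly_out] = np.clip(y[slightly_out], 0.0, arena.height_mm)
    return x, y, np.asarray(far_out)


def read_tracking(
    path,
    arena: ArenaGeometry,
    clamp_tol_mm: float = 0.5,
    max_gap_frames: int = 5,
) -> List[Trajectory]:
    """Read a tracking CSV into one :class:`Trajectory` per fish.

    Rows need not be sorted; output is time-sorted per fish.  Points up to
    ``clamp_tol_mm`` outside the arena are clamped to the wall; points
    further out are flagged as missing (with a warning).  Short missing
    runs are interpolated via :func:`fill_gaps`.
    """
    df = pd.read_csv(path, dtype={"fish_id": str, "arena_id": str})
    missing_cols = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"malformed tracking header: missing columns {missing_cols}")
    out: List[Trajectory] = []
    for fish_id, g in df.groupby("fish_id", sort=True):
        g = g.sort_values("t_s", kind="mergesort")
        t = g["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"fish {fish_id!r} has duplicated or non-monotone timestamps"
            )
        x = g["x_mm"].to_numpy(dtype=float)
        y = g["y_mm"].to_numpy(dtype=float)
        x, y, far_out = _clamp_to_arena(arena, x, y, clamp_tol_mm)
        if far_out.any():
            warnings.warn(
                f"fish {fish_id!r}: {int(far_out.sum())} points more than "
                f"{clamp_tol_mm} mm outside arena {arena.arena_id!r}; flagged missing",
                stacklevel=2,
            )
            x[far_out] = np.nan
            y[far_out] = np.nan
        arena_ids = g["arena_id"].unique()
        if len(arena_ids) > 1:
            raise ValueError(f"fish {fish_id!r} appears in multiple arenas: {list(arena_ids)}")
        dt = np.median(np.diff(t))
        traj = Trajectory(
            fish_id=str(fish_id),
            arena_id=str(arena_ids[0]),
            frame_rate_hz=1.0 / dt,
            t_s=t,
            x_mm=x,
            y_mm=y,
        )
        out.append(fill_gaps(traj, max_gap_frames=max_gap_frames))
    return out


def write_tracking(trajs: Sequence[Trajectory], path) -> None:
    """Write trajectories to the tracking CSV format.

    Column order and number formatting are fixed (6 decimal places) so a
    seeded pipeline writes byte-identical files on rerun.
    """
    trajs = list(trajs)
    if trajs:
        rates = {round(t.frame_rate_hz, 9) for t in trajs}
        if len(rates) > 1:
            raise ValueError(f"trajectories have mixed frame rates: {sorted(rates)}")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(TRACKING_COLUMNS) + "\n")
        for traj in trajs:
            for i in range(len(traj)):
                if traj.missing[i]:
                    xs = ys = ""
                else:
                    xs = f"{traj.x_mm[i]:.6f}"
                    ys = f"{traj.y_mm[i]:.6f}"
                fh.write(
                    f"{traj.fish_id},{i},{traj.t_s[i]:.6f},{xs},{ys},{traj.arena_id}\n"
                )


def suppress_jitter(traj: Trajectory, min_step_mm: float = 0.2) -> Trajectory:
    """Apply a displacement deadband: sub-threshold steps are held in place.

    Centroid tracking wobbles by a fraction of a millimetre even for a
    stationary fish; summing those steps inflates distance travelled.  A
    position is only updated once it moves at least ``min_step_mm`` from
    the last accepted position, so downstream distances ignore
    sub-threshold noise.  Idempotent for a fixed threshold, and never
    increases total path length.  The default 0.2 mm suits larval tracks.
    """
    if min_step_mm < 0:
        raise ValueError("min_step_mm must be >= 0")
    if min_step_mm == 0:
        return traj
    x = traj.x_mm.copy()
    y = traj.y_mm.copy()
    held_x = held_y = None
    for i in range(len(x)):
        if traj.missing[i]:
            held_x = held_y = None  # a gap resets the deadband anchor
            continue
        if held_x is None:
            held_x, held_y = x[i], y[i]
            continue
        dx = x[i] - held_x
        dy = y[i] - held_y
        if dx * dx + dy * dy < min_step_mm * min_step_mm:
            x[i] = held_x
            y[i] = held_y
        else:
            held_x, held_y = x[i], y[i]
    return replace(traj, x_mm=x, y_mm=y)
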