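"""Rule-based repetitive-behaviour classifiers for juvenile zebrafish.

Three stereotypy classes are detected from centroid tracks in a tank:

- **stereotypic movement** ("small circling"): sustained swimming confined
  to a small area — positional span under 30 mm for longer than 5 s;
- **large circular movement**: full clockwise or counterclockwise
  revolutions along the tank walls, detected by accumulating the signed
  angle swept about the arena centre while the fish stays in the edge
  band;
- **back-and-forth motion**: an excursion along one wall or two adjacent
  walls that returns to its starting point.

"Span" is the maximum pairwise distance among the positions of the
candidate window (spatial diameter), not the net start-to-end
displacement: net displacement would label a full lap of the tank
"stereotypic", which the rule plainly does not intend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .geometry import ArenaGeometry
from .tracking import Trajectory

__all__ = [
    "SwimBout",
    "RepetitiveSummary",
    "positional_span",
    "segment_swimming",
    "detect_stereotypic",
    "detect_large_circle",
    "detect_back_and_forth",
    "summarize_repetitive",
    "evaluate_detections",
]

BOUT_LABELS = ("back_and_forth", "stereotypic", "large_circle_cw", "large_circle_ccw")


@dataclass
class SwimBout:
    """A labelled behaviour interval with its supporting metrics."""

    fish_id: str
    label: str
    start_s: float
    end_s: float
    metrics: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in BOUT_LABELS:
            raise ValueError(f"unknown bout label {self.label!r}")
        if self.end_s <= self.start_s:
            raise ValueError("bout must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def positional_span(points: np.ndarray) -> float:
    """Maximum pairwise distance (spatial diameter) of a point set.

    Uses the convex hull for large sets; the diameter of a point set is
    attained between hull vertices.  Falls back to all-pairs for small or
    degenerate (collinear) sets.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    if len(points) > 60:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # collinear / degenerate input
            pass
    return float(pdist(points).max())


def segment_swimming(
    traj: Trajectory,
    speed_threshold_mm_s: float = 1.0,
    bridge_gap_s: float = 0.2,
    smooth_s: float = 0.2,
) -> List[Tuple[float, float]]:
    """Maximal intervals of continuous swimming.

    Per-step speed is boxcar-smoothed over ``smooth_s`` and thresholded;
    sub-``bridge_gap_s`` pauses are bridged so a single glide does not
    split a bout.  Steps touching missing frames count as stationary.
    """
    if speed_threshold_mm_s < 0:
        raise ValueError("speed threshold must be >= 0")
    t = traj.t_s
    dt = np.diff(t)
    speed = np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm)) / dt
    speed[traj.missing[:-1] | traj.missing[1:]] = 0.0
    win = max(1, int(round(smooth_s * traj.frame_rate_hz)))
    if win > 1:
        kernel = np.ones(win) / win
        speed = np.convolve(speed, kernel, mode="same")
    moving = speed >= speed_threshold_mm_s
    # bridge short stationary gaps between swimming runs
    idx = np.flatnonzero(moving)
    if len(idx) == 0:
        return []
    gaps = np.flatnonzero(~moving)
    if len(gaps):
        runs = np.split(gaps, np.flatnonzero(np.diff(gaps) > 1) + 1)
        for run in runs:
            lo, hi = run[0], run[-1]
            if lo == 0 or hi == len(moving) - 1:
                continue
            if t[hi + 1] - t[lo] < bridge_gap_s:
                moving[run] = True
    # maximal True runs -> time intervals (step i spans [t[i], t[i+1]])
    out: List[Tuple[float, float]] = []
    idx = np.flatnonzero(moving)
    for run in np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1):
        out.append((float(t[run[0]]), float(t[run[-1] + 1])))
    return out


def _frames_in_interval(traj: Trajectory, start_s: float, end_s: float) -> np.ndarray:
    sel = (traj.t_s >= start_s - 1e-9) & (traj.t_s <= end_s + 1e-9) & ~traj.missing
    return np.flatnonzero(sel)


def detect_stereotypic(
    traj: Trajectory,
    max_span_mm: float = 30.0,
    min_dur_s: float = 5.0,
    speed_threshold_mm_s: float = 1.0,
) -> List[SwimBout]:
    """Detect confined-swimming ("stereotypic movement") bouts.

    Within each continuous-swimming interval, a greedy left-to-right scan
    finds maximal windows whose positional span stays strictly below
    ``max_span_mm``; windows strictly longer than ``min_dur_s`` are
    emitted.  When a window cannot be extended past a violating frame it
    is truncated before that frame.  Emitted bouts never overlap.

    The scan is a two-pointer sweep: the window [i..j] is kept span-valid,
    so admitting frame j+1 only requires its maximum distance to the
    current window — shrinking the window from the left can never break
    validity.
    """
    if max_span_mm <= 0 or min_dur_s <= 0:
        raise ValueError("thresholds must be positive")
    bouts: List[SwimBout] = []
    for start_s, end_s in segment_swimming(traj, speed_threshold_mm_s):
        frames = _frames_in_interval(traj, start_s, end_s)
        if len(frames) < 2:
            continue
        t = traj.t_s[frames]
        pts = np.column_stack([traj.x_mm[frames], traj.y_mm[frames]])
        n = len(frames)

        def emit(i: int, j: int) -> None:
            window = pts[i : j + 1]
            seg = np.hypot(np.diff(window[:, 0]), np.diff(window[:, 1]))
            bouts.append(
                SwimBout(
                    fish_id=traj.fish_id,
                    label="stereotypic",
                    start_s=float(t[i]),
                    end_s=float(t[j]),
                    metrics={
                        "max_span_mm": positional_span(window),
                        "path_mm": float(seg.sum()),
                    },
                )
            )

        i = j = 0
        while j < n - 1:
            cand = pts[j + 1]
            d_max = np.hypot(pts[i : j + 1, 0] - cand[0], pts[i : j + 1, 1] - cand[1]).max()
            if d_max < max_span_mm:
                j += 1
                continue
            if t[j] - t[i] > min_dur_s:
                emit(i, j)
                i = j = j + 1
            else:
                i += 1
                if i > j:
                    j = i
        if j > i and t[j] - t[i] > min_dur_s:
            emit(i, j)
    return bouts


def detect_large_circle(
    traj: Trajectory,
    arena: ArenaGeometry,
    min_loops: int = 1,
    reversal_tol_rad: float = math.pi / 2,
    exit_grace_s: float = 0.5,
    edge_band_only: bool = True,
) -> List[SwimBout]:
    """Detect full wall-following revolutions (large circular movement).

    The signed angle swept about the arena centre is accumulated while
    the fish is inside the edge band; each monotone accumulation reaching
    2π emits one loop, labelled ccw for positive (mathematical) winding
    and cw for negative.  The accumulator resets when the fish backtracks
    by more than ``reversal_tol_rad`` from its winding extremum, or stays
    out of the band longer than ``exit_grace_s``.  With ``min_loops`` > 1,
    only runs of at least that many consecutive same-direction loops are
    kept.  ``edge_band_only=False`` disables the band gate entirely (for
    sensitivity analyses).
    """
    if min_loops < 1:
        raise ValueError("min_loops must be >= 1")
    cx, cy = arena.center
    t = traj.t_s
    ok = ~traj.missing
    theta = np.arctan2(traj.y_mm - cy, traj.x_mm - cx)
    if edge_band_only:
        in_band = ok & (arena.wall_distance(traj.x_mm, traj.y_mm) <= arena.edge_band_mm)
    else:
        in_band = ok

    loops: List[SwimBout] = []
    acc = 0.0  # winding since the current anchor
    peak = 0.0  # extremal acc in the current direction
    anchor: Optional[int] = None
    anchor_peak: Optional[int] = None
    out_since: Optional[float] = None
    two_pi = 2 * math.pi

    def reset() -> None:
        nonlocal acc, peak, anchor, anchor_peak
        acc = peak = 0.0
        anchor = anchor_peak = None

    for k in range(1, len(t)):
        if not ok[k] or not ok[k - 1]:
            reset()
            out_since = None
            continue
        if not in_band[k]:
            if out_since is None:
                out_since = t[k]
            elif t[k] - out_since > exit_grace_s:
                reset()
                out_since = None
                continue
            if anchor is None:
                continue
        else:
            out_since = None
        dth = theta[k] - theta[k - 1]
        if dth > math.pi:
            dth -= two_pi
        elif dth <= -math.pi:
            dth += two_pi
        if anchor is None:
            if not in_band[k]:
                continue
            anchor = k - 1 if in_band[k - 1] else k
            acc = peak = 0.0
            anchor_peak = anchor
        acc += dth
        if abs(acc) > abs(peak) and (peak == 0.0 or acc * peak > 0):
            peak = acc
            anchor_peak = k
        elif peak != 0.0 and (peak - acc) * math.copysign(1.0, peak) > reversal_tol_rad:
            # direction reversal: credit progress made since the extremum
            acc -= peak
            anchor = anchor_peak
            peak = acc
            anchor_peak = k
        if abs(acc) >= two_pi:
            sign = math.copysign(1.0, acc)
            loops.append(
                SwimBout(
                    fish_id=traj.fish_id,
                    label="large_circle_ccw" if sign > 0 else "large_circle_cw",
                    start_s=float(t[anchor]),
                    end_s=float(t[k]),
                    metrics={"net_winding_rad": sign * two_pi},
                )
            )
            acc -= sign * two_pi
            peak = acc if acc * sign > 0 else 0.0
            anchor = anchor_peak = k

    if min_loops > 1:
        kept: List[SwimBout] = []
        run: List[SwimBout] = []
        for b in loops:
            if run and (b.label != run[-1].label or b.start_s - run[-1].end_s > 1e-6):
                if len(run) >= min_loops:
                    kept.extend(run)
                run = []
            run.append(b)
        if len(run) >= min_loops:
            kept.extend(run)
        return kept
    return loops


_OPPOSITE_WALLS = {0: 1, 1: 0, 2: 3, 3: 2}


def _perimeter_coordinate(arena: ArenaGeometry, x: np.ndarray, y: np.ndarray):
    """Arc-length position along the tank perimeter (ccw from the origin
    corner), via nearest-wall projection; also returns the wall index."""
    w, h = arena.width_mm, arena.height_mm
    wall = arena.nearest_wall(x, y)
    s = np.empty_like(x)
    s[wall == 2] = x[wall == 2]  # bottom
    s[wall == 1] = w + y[wall == 1]  # right
    s[wall == 3] = w + h + (w - x[wall == 3])  # top
    s[wall == 0] = 2 * w + h + (h - y[wall == 0])  # left
    return s, wall


def _swing_pivots(s: np.ndarray, hysteresis: float) -> List[int]:
    """Turn-around points of a 1-D series, ignoring retraces below
    ``hysteresis``; the first index is always a pivot."""
    pivots = [0]
    ext_max = ext_min = 0
    direction = 0
    for k in range(1, len(s)):
        if s[k] > s[ext_max]:
            ext_max = k
        if s[k] < s[ext_min]:
            ext_min = k
        if direction >= 0 and s[ext_max] - s[k] > hysteresis:
            if ext_max != pivots[-1]:
                pivots.append(ext_max)
            direction = -1
            ext_min = k
        elif direction <= 0 and s[k] - s[ext_min] > hysteresis:
            if ext_min != pivots[-1]:
                pivots.append(ext_min)
            direction = 1
            ext_max = k
    final = ext_max if direction > 0 else ext_min if direction < 0 else len(s) - 1
    if final != pivots[-1]:
        pivots.append(final)
    return pivots


def detect_back_and_forth(
    traj: Trajectory,
    arena: ArenaGeometry,
    return_radius_mm: float = 15.0,
    min_leg_mm: float = 50.0,
    exit_grace_s: float = 0.5,
) -> List[SwimBout]:
    """Detect edge-bound out-and-back excursions (back-and-forth motion).

    An event is an excursion inside the edge band of a rectangular tank
    that travels at least ``min_leg_mm`` along one wall or two adjacent
    walls and then returns to within ``return_radius_mm`` of its start.
    Excursions touching opposite walls do not qualify.  ``min_leg_mm``
    prevents millimetre-scale oscillation from counting as an event.

    Detection works in a perimeter arc-length coordinate: in-band
    positions are projected onto the wall outline, turn-around pivots of
    the resulting 1-D series are found with a ``return_radius_mm``
    hysteresis, and an event is a pivot-to-pivot swing of at least
    ``min_leg_mm`` whose back-swing re-enters the return radius of the
    outbound pivot.
    """
    if arena.shape != "rectangle":
        raise ValueError("back-and-forth detection requires a rectangular arena")
    t = traj.t_s
    ok = ~traj.missing
    in_band = ok & (arena.wall_distance(traj.x_mm, traj.y_mm) <= arena.edge_band_mm)
    # bridge brief band exits so touching the band edge does not split a run
    out_idx = np.flatnonzero(~in_band)
    if len(out_idx):
        for gap in np.split(out_idx, np.flatnonzero(np.diff(out_idx) > 1) + 1):
            lo, hi = gap[0], gap[-1]
            if lo == 0 or hi == len(t) - 1:
                continue
            if ok[gap].all() and t[hi] - t[lo] <= exit_grace_s:
                in_band[gap] = True

    bouts: List[SwimBout] = []
    band_idx = np.flatnonzero(in_band)
    if len(band_idx) == 0:
        return bouts
    perimeter = 2 * (arena.width_mm + arena.height_mm)
    for run in np.split(band_idx, np.flatnonzero(np.diff(band_idx) > 1) + 1):
        if len(run) < 3:
            continue
        xs = traj.x_mm[run]
        ys = traj.y_mm[run]
        s, wall = _perimeter_coordinate(arena, xs, ys)
        ds = np.diff(s)
        ds -= perimeter * np.round(ds / perimeter)
        # the projection is discontinuous across corner diagonals; a real
        # step can never advance along the wall faster than the fish moves
        step2d = np.hypot(np.diff(xs), np.diff(ys)) + 1.0
        ds = np.clip(ds, -step2d, step2d)
        s = np.concatenate([[s[0]], s[0] + np.cumsum(ds)])  # unwrapped
        pivots = _swing_pivots(s, hysteresis=return_radius_mm)
        emitted_until = -1
        for pi in range(len(pivots) - 1):
            a, b = pivots[pi], pivots[pi + 1]
            if a < emitted_until:
                continue
            if abs(s[b] - s[a]) < min_leg_mm:
                continue
            stop = pivots[pi + 2] if pi + 2 < len(pivots) else len(run) - 1
            back = np.flatnonzero(
                np.hypot(xs[b : stop + 1] - xs[a], ys[b : stop + 1] - ys[a])
                <= return_radius_mm
            )
            if len(back) == 0:
                continue
            k = b + back[0]
            touched = set(wall[a : k + 1].tolist())
            if any(_OPPOSITE_WALLS[wl] in touched for wl in touched):
                continue
            bouts.append(
                SwimBout(
                    fish_id=traj.fish_id,
                    label="back_and_forth",
                    start_s=float(t[run[a]]),
                    end_s=float(t[run[k]]),
                    metrics={
                        "leg_mm": float(abs(s[b] - s[a])),
                        "n_walls": float(len(touched)),
                    },
                )
            )
            emitted_until = k
    return bouts


@dataclass
class RepetitiveSummary:
    """Per-label bout counts and total durations over an analysis window."""

    window_s: float
    counts: Dict[str, int]
    durations_s: Dict[str, float]


def summarize_repetitive(
    bouts: Sequence[SwimBout], window: Tuple[float, float]
) -> RepetitiveSummary:
    """Tally bout counts and durations per label over ``window``."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy t0 < t1")
    counts = {label: 0 for label in BOUT_LABELS}
    durations = {label: 0.0 for label in BOUT_LABELS}
    for b in bouts:
        if b.start_s < t0 - 1e-9 or b.end_s > t1 + 1e-9:
            raise ValueError(f"bout [{b.start_s}, {b.end_s}] outside window [{t0}, {t1}]")
        counts[b.label] += 1
        durations[b.label] += b.duration_s
    return RepetitiveSummary(window_s=t1 - t0, counts=counts, durations_s=durations)


def evaluate_detections(
    detected: Sequence[SwimBout],
    truth: Sequence[Tuple[float, float]],
    min_overlap_frac: float = 0.3,
) -> Tuple[int, int, int]:
    """Match detections to ground-truth intervals; return (tp, fp, fn).

    A detection matches a truth interval when their overlap exceeds
    ``min_overlap_frac`` of the shorter of the two; each truth interval
    absorbs any number of detections (a long true bout split into several
    detections is not penalised as false positives).  The default
    fraction tolerates the systematic boundary offset between a rule's
    trigger radius and the underlying event while still requiring the
    detection to lie on the event.
    """
    matched_truth = [False] * len(truth)
    fp = 0
    for d in detected:
        hit = False
        for i, (s, e) in enumerate(truth):
            ov = min(d.end_s, e) - max(d.start_s, s)
            if ov > min_overlap_frac * min(d.duration_s, e - s):
                matched_truth[i] = True
                hit = True
        if not hit:
            fp += 1
    tp = sum(matched_truth)
    fn = len(truth) - tp
    return tp, fp, fn
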