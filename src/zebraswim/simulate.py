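"""Agent-based synthetic swim simulator with ground-truth labels.

Fish are simulated as discrete-time correlated random walks at the video
frame rate: per-frame speed is gamma-distributed, heading diffuses by
wrapped-normal noise and is blended with steering terms — wall
attraction/following (weight ``wall_bias``), attraction to the social
region (``social_weight``) and attraction to the shoal centroid
(``cohesion``).  Speed is multiplied by ``dark_multiplier`` during dark
epochs, emulating the larval photomotor response.  Walls reflect.

Repetitive-behaviour bouts can be injected on top of the walk with
label-specific kinematics (confined jitter, wall-following revolutions,
edge out-and-back runs); every injected bout is recorded in a
ground-truth log so detector recall and precision are measurable.  By
default injected bouts are generated at least two-fold clear of the
detector thresholds; ``hard=True`` generates near-threshold bouts for
sensitivity analyses.

A single integer seed determines everything; per-agent streams are
derived by fixed seed-sequence splitting, so cohorts are reproducible
independent of agent count.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry import (
    ArenaGeometry,
    LightSchedule,
    constant_light_schedule,
    make_pmr_schedule,
    make_standard_arena,
)
from .tracking import Trajectory, write_tracking

__all__ = [
    "AgentParams",
    "GroundTruthLog",
    "CohortManifest",
    "simulate_fish",
    "simulate_group",
    "simulate_shoal",
    "make_cohort",
    "default_params",
    "classifier_validation_params",
    "ASSAYS",
]

TWO_PI = 2 * math.pi

# distance from a wall at which collision-avoidance steering engages
AVOID_MARGIN_MM = 10.0


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated fish.

    Speeds are mm/s; ``turn_sd_rad`` is per-frame heading noise;
    ``wall_bias``, ``social_weight`` and ``cohesion`` are steering blend
    weights in [0, 1]; ``dark_multiplier`` scales speed in dark epochs;
    ``bout_rates`` maps a bout label (``stereotypic``, ``large_circle``,
    ``back_and_forth``) to a Poisson rate in events per second.
    """

    mean_speed_mm_s: float = 25.0
    speed_shape: float = 3.0
    turn_sd_rad: float = 0.3
    wall_bias: float = 0.2
    dark_multiplier: float = 1.0
    social_weight: float = 0.0
    cohesion: float = 0.0
    bout_rates: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.mean_speed_mm_s <= 0 or self.speed_shape <= 0:
            raise ValueError("speed parameters must be positive")
        if self.turn_sd_rad < 0:
            raise ValueError("turn_sd_rad must be >= 0")
        for name in ("wall_bias", "social_weight", "cohesion"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.dark_multiplier <= 0:
            raise ValueError("dark_multiplier must be > 0")
        for label, rate in self.bout_rates.items():
            if label not in ("stereotypic", "large_circle", "back_and_forth"):
                raise ValueError(f"unknown bout label {label!r}")
            if rate < 0:
                raise ValueError("bout rates must be >= 0")


@dataclass
class GroundTruthLog:
    """Simulator-emitted truth: injected bout intervals and agent parameters."""

    seed: int
    agent_params: Dict[str, dict]
    bouts: List[dict] = field(default_factory=list)  # fish_id,label,start_s,end_s

    def bouts_for(self, fish_id: str, label: str) -> List[Tuple[float, float]]:
        return [
            (b["start_s"], b["end_s"])
            for b in self.bouts
            if b["fish_id"] == fish_id and b["label"] == label
        ]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"seed": self.seed, "agent_params": self.agent_params, "bouts": self.bouts},
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruthLog":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(seed=d["seed"], agent_params=d["agent_params"], bouts=d["bouts"])


# ---------------------------------------------------------------------------
# steering helpers


def _social_center(arena: ArenaGeometry) -> Optional[Tuple[float, float]]:
    region = arena.regions.get("social")
    if region is None or region.kind != "rectangle":
        return None
    x0, y0, x1, y1 = region.params
    return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def _wall_frame(arena: ArenaGeometry, x, y):
    """Unit vectors at each point: inward wall normal and ccw tangent.

    For circles the tangent is the circle tangent; for rectangles it is
    the nearest-wall tangent oriented counterclockwise around the arena.
    Also returns the wall distance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if arena.shape == "circle":
        r = np.hypot(x, y)
        safe = np.where(r > 1e-9, r, 1.0)
        ox, oy = x / safe, y / safe  # outward radial
        nx, ny = -ox, -oy
        tx, ty = -oy, ox  # ccw
        dist = arena.radius_mm - r
    else:
        wall = arena.nearest_wall(x, y)
        nx = np.choose(wall, [np.ones_like(x), -np.ones_like(x), np.zeros_like(x), np.zeros_like(x)])
        ny = np.choose(wall, [np.zeros_like(x), np.zeros_like(x), np.ones_like(x), -np.ones_like(x)])
        # ccw tangent = inward normal rotated -90 degrees
        tx, ty = ny, -nx
        dist = arena.wall_distance(x, y)
    return nx, ny, tx, ty, dist


def _reflect(arena: ArenaGeometry, x, y, hx, hy):
    """Reflect positions/heading vectors that stepped through a wall."""
    if arena.shape == "circle":
        r = np.hypot(x, y)
        out = r > arena.radius_mm
        if np.any(out):
            scale = (2 * arena.radius_mm - r[out]) / r[out]
            ox, oy = x[out] / r[out], y[out] / r[out]
            x[out] *= scale
            y[out] *= scale
            dot = hx[out] * ox + hy[out] * oy
            hx[out] -= 2 * dot * ox
            hy[out] -= 2 * dot * oy
            # pathological steps (reflection past the centre): clamp inside
            r2 = np.hypot(x[out], y[out])
            bad = r2 > arena.radius_mm
            if np.any(bad):
                idx = np.flatnonzero(out)[bad]
                x[idx] *= 0.99 * arena.radius_mm / r2[bad]
                y[idx] *= 0.99 * arena.radius_mm / r2[bad]
    else:
        w, h = arena.width_mm, arena.height_mm
        lo = x < 0
        x[lo] = -x[lo]
        hx[lo] = -hx[lo]
        hi = x > w
        x[hi] = 2 * w - x[hi]
        hx[hi] = -hx[hi]
        lo = y < 0
        y[lo] = -y[lo]
        hy[lo] = -hy[lo]
        hi = y > h
        y[hi] = 2 * h - y[hi]
        hy[hi] = -hy[hi]
        np.clip(x, 0.0, w, out=x)
        np.clip(y, 0.0, h, out=y)
    return x, y, hx, hy


def _initial_positions(arena: ArenaGeometry, n: int, rng: np.random.Generator):
    if arena.shape == "circle":
        r = arena.radius_mm * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(-math.pi, math.pi, n)
        return r * np.cos(th), r * np.sin(th)
    return rng.uniform(0, arena.width_mm, n), rng.uniform(0, arena.height_mm, n)


def _simulate_walk(
    n: int,
    params: AgentParams,
    arena: ArenaGeometry,
    schedule: Optional[LightSchedule],
    duration_s: float,
    rng: np.random.Generator,
    frame_rate_hz: float,
    cohesion: float = 0.0,
) -> np.ndarray:
    """Vectorised correlated random walk for ``n`` coupled agents.

    Returns positions of shape (n, n_frames, 2).  ``cohesion`` > 0 steers
    every agent toward the instantaneous group centroid.
    """
    dt = 1.0 / frame_rate_hz
    n_steps = int(round(duration_s * frame_rate_hz))
    times = dt * np.arange(n_steps)
    if schedule is not None and any(e.condition == "dark" for e in schedule.epochs):
        dark = np.asarray(schedule.condition_at(times)) == "dark"
    else:
        dark = np.zeros(n_steps, dtype=bool)

    x, y = _initial_positions(arena, n, rng)
    heading = rng.uniform(-math.pi, math.pi, n)
    soc = _social_center(arena) if params.social_weight > 0 else None
    kappa, w_soc = params.wall_bias, params.social_weight if soc else 0.0
    w_self = max(0.0, 1.0 - kappa - w_soc - cohesion)
    scale = params.mean_speed_mm_s / params.speed_shape
    band = arena.edge_band_mm
    avoid_margin = AVOID_MARGIN_MM
    # persistent wall-turning sense: updated only when the heading clearly
    # agrees or opposes the wall tangent, so corners are rounded, not
    # bounced back from
    tan_sign = np.where(rng.uniform(size=n) < 0.5, 1.0, -1.0)

    out = np.empty((n, n_steps + 1, 2))
    out[:, 0, 0] = x
    out[:, 0, 1] = y
    for k in range(n_steps):
        heading = heading + rng.normal(0.0, params.turn_sd_rad, n)
        hx = np.cos(heading)
        hy = np.sin(heading)
        vx = w_self * hx
        vy = w_self * hy
        nx, ny, tx, ty, dist = _wall_frame(arena, x, y)
        dot = hx * tx + hy * ty
        tan_sign = np.where(np.abs(dot) > 0.3, np.sign(dot), tan_sign)
        if kappa > 0:
            # far from the wall: head toward it; in the band: follow it,
            # keeping the persistent turning sense
            toward = dist > band
            wx = np.where(toward, -nx, tan_sign * tx)
            wy = np.where(toward, -ny, tan_sign * ty)
            vx += kappa * wx
            vy += kappa * wy
        # collision avoidance: a fish closing on a wall veers tangentially
        # instead of bouncing off it (prevents billiard corner returns)
        closing = -(hx * nx + hy * ny)  # >0 when heading into the wall
        a = np.clip(1.0 - dist / avoid_margin, 0.0, 1.0) * np.clip(closing, 0.0, 1.0)
        if np.any(a > 0):
            vx = (1.0 - a) * vx + a * tan_sign * tx
            vy = (1.0 - a) * vy + a * tan_sign * ty
        if w_soc > 0:
            dxs = soc[0] - x
            dys = soc[1] - y
            d = np.hypot(dxs, dys)
            safe = np.where(d > 1e-9, d, 1.0)
            vx += w_soc * dxs / safe
            vy += w_soc * dys / safe
        if cohesion > 0:
            cxm = x.mean()
            cym = y.mean()
            dxc = cxm - x
            dyc = cym - y
            d = np.hypot(dxc, dyc)
            safe = np.where(d > 1e-9, d, 1.0)
            vx += cohesion * dxc / safe
            vy += cohesion * dyc / safe
        norm = np.hypot(vx, vy)
        ok = norm > 1e-9
        hx = np.where(ok, vx / np.where(ok, norm, 1.0), hx)
        hy = np.where(ok, vy / np.where(ok, norm, 1.0), hy)
        speed = rng.gamma(params.speed_shape, scale, n)
        if dark[k]:
            speed = speed * params.dark_multiplier
        x = x + speed * dt * hx
        y = y + speed * dt * hy
        x, y, hx, hy = _reflect(arena, x, y, hx, hy)
        heading = np.arctan2(hy, hx)
        out[:, k + 1, 0] = x
        out[:, k + 1, 1] = y
    return out


# ---------------------------------------------------------------------------
# bout injection (scalar per-agent walk)


def _schedule_bouts(
    params: AgentParams,
    duration_s: float,
    rng: np.random.Generator,
    hard: bool,
) -> List[dict]:
    """Draw a non-overlapping injected-bout agenda from the Poisson rates."""
    agenda: List[dict] = []
    for label, rate in sorted(params.bout_rates.items()):
        n_events = rng.poisson(rate * duration_s)
        for _ in range(n_events):
            start = rng.uniform(0.0, duration_s)
            if label == "stereotypic":
                dur = rng.uniform(10.0, 14.0) if not hard else rng.uniform(5.2, 6.5)
                spec = {"radius_mm": 6.0 if not hard else 13.0}
            elif label == "large_circle":
                spec = {
                    "loops": 1.25 if not hard else 1.02,
                    "ccw": bool(rng.integers(0, 2)),
                }
                dur = 40.0  # generous estimate incl. wall approach
            else:  # back_and_forth
                spec = {"leg_mm": 100.0 if not hard else 55.0}
                dur = 40.0
            agenda.append({"label": label, "start_s": start, "est_dur_s": dur, **spec})
    agenda.sort(key=lambda b: b["start_s"])
    kept: List[dict] = []
    t_free = 20.0  # leave an initial stretch of plain walking
    for b in agenda:
        if b["start_s"] >= t_free and b["start_s"] + b["est_dur_s"] + 10.0 <= duration_s:
            kept.append(b)
            t_free = b["start_s"] + b["est_dur_s"] + 10.0
    return kept


def _simulate_with_bouts(
    params: AgentParams,
    arena: ArenaGeometry,
    schedule: Optional[LightSchedule],
    duration_s: float,
    rng: np.random.Generator,
    frame_rate_hz: float,
    fish_id: str,
    hard: bool,
) -> Tuple[np.ndarray, List[dict]]:
    """Scalar walk with injected repetitive-behaviour bouts.

    Returns positions (n_frames, 2) and the emitted truth bout records.
    """
    dt = 1.0 / frame_rate_hz
    n_steps = int(round(duration_s * frame_rate_hz))
    agenda = _schedule_bouts(params, duration_s, rng, hard)
    truth: List[dict] = []

    turn_noise = rng.normal(0.0, 1.0, n_steps)
    speeds = rng.gamma(params.speed_shape, params.mean_speed_mm_s / params.speed_shape, n_steps)
    if schedule is not None and any(e.condition == "dark" for e in schedule.epochs):
        dark = np.asarray(schedule.condition_at(dt * np.arange(n_steps))) == "dark"
        speeds = np.where(dark, speeds * params.dark_multiplier, speeds)
    speeds = speeds.tolist()
    turn_noise = turn_noise.tolist()

    soc = _social_center(arena) if params.social_weight > 0 else None
    kappa, w_soc = params.wall_bias, params.social_weight if soc else 0.0
    band = arena.edge_band_mm
    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    x0, y0 = _initial_positions(arena, 1, rng)
    x, y = float(x0[0]), float(y0[0])
    heading = float(rng.uniform(-math.pi, math.pi))
    hx, hy = math.cos(heading), math.sin(heading)
    xs[0], ys[0] = x, y
    cx, cy = arena.center

    mode = "walk"
    bout: dict = {}
    agenda_i = 0
    follow_target = band / 2.0
    w_self = max(0.0, 1.0 - kappa - w_soc)
    tan_sign = 1.0 if rng.uniform() < 0.5 else -1.0
    perimeter_len = (
        2 * (arena.width_mm + arena.height_mm)
        if arena.shape == "rectangle"
        else TWO_PI * arena.radius_mm
    )

    def reflect_scalar(px: float, py: float, hx: float, hy: float):
        if arena.shape == "circle":
            R = arena.radius_mm
            r = math.hypot(px, py)
            if r > R:
                ox, oy = px / r, py / r
                scale = (2 * R - r) / r
                px *= scale
                py *= scale
                dot = hx * ox + hy * oy
                hx -= 2 * dot * ox
                hy -= 2 * dot * oy
                if math.hypot(px, py) > R:
                    f = 0.99 * R / math.hypot(px, py)
                    px *= f
                    py *= f
            return px, py, hx, hy
        w, h = arena.width_mm, arena.height_mm
        if px < 0:
            px, hx = -px, -hx
        elif px > w:
            px, hx = 2 * w - px, -hx
        if py < 0:
            py, hy = -py, -hy
        elif py > h:
            py, hy = 2 * h - py, -hy
        return min(max(px, 0.0), w), min(max(py, 0.0), h), hx, hy

    def perimeter_scalar(px: float, py: float) -> float:
        w, h = arena.width_mm, arena.height_mm
        d = (px, w - px, py, h - py)
        wall = d.index(min(d))
        if wall == 2:
            return px
        if wall == 1:
            return w + py
        if wall == 3:
            return w + h + (w - px)
        return 2 * w + h + (h - py)

    def wall_frame_scalar(px: float, py: float):
        if arena.shape == "circle":
            r = math.hypot(px, py)
            if r < 1e-9:
                return 1.0, 0.0, 0.0, 1.0, arena.radius_mm
            ox, oy = px / r, py / r
            return -ox, -oy, -oy, ox, arena.radius_mm - r
        w, h = arena.width_mm, arena.height_mm
        d = (px, w - px, py, h - py)
        wall = d.index(min(d))
        nx, ny = ((1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0))[wall]
        return nx, ny, ny, -nx, min(d)

    for k in range(n_steps):
        t_now = k * dt
        if mode == "walk" and agenda_i < len(agenda) and t_now >= agenda[agenda_i]["start_s"]:
            spec = agenda[agenda_i]
            agenda_i += 1
            if spec["label"] == "stereotypic":
                # pull the jitter anchor inward so the confinement disk fits
                nx, ny, _, _, dist = wall_frame_scalar(x, y)
                margin = spec["radius_mm"] + 2.0
                ax, ay = x, y
                if dist < margin:
                    ax += nx * (margin - dist)
                    ay += ny * (margin - dist)
                bout = {
                    "label": "stereotypic",
                    "anchor": (ax, ay),
                    "radius": spec["radius_mm"],
                    "start_s": t_now,
                    "end_s": t_now + spec["est_dur_s"],
                }
                mode = "stereo"
            elif spec["label"] == "large_circle":
                bout = {
                    "label": "large_circle",
                    "sign": 1.0 if spec["ccw"] else -1.0,
                    "loops": spec["loops"],
                    "winding": 0.0,
                    "start_s": None,
                }
                mode = "approach_circle"
            else:
                bout = {
                    "label": "back_and_forth",
                    "leg": spec["leg_mm"],
                    "path": 0.0,
                    "phase": "out",
                    "start_s": None,
                    "sign": 1.0 if rng.integers(0, 2) else -1.0,
                }
                mode = "approach_bnf"

        speed = speeds[k]
        if mode == "walk":
            heading += params.turn_sd_rad * turn_noise[k]
            hx, hy = math.cos(heading), math.sin(heading)
            vx = w_self * hx
            vy = w_self * hy
            nx, ny, tx, ty, dist = wall_frame_scalar(x, y)
            dot = hx * tx + hy * ty
            if abs(dot) > 0.3:
                tan_sign = math.copysign(1.0, dot)
            if kappa > 0:
                if dist > band:
                    vx += -kappa * nx
                    vy += -kappa * ny
                else:
                    vx += kappa * tan_sign * tx
                    vy += kappa * tan_sign * ty
            if w_soc > 0:
                dxs, dys = soc[0] - x, soc[1] - y
                d = math.hypot(dxs, dys)
                if d > 1e-9:
                    vx += w_soc * dxs / d
                    vy += w_soc * dys / d
            # collision avoidance near walls (see _simulate_walk)
            closing = -(hx * nx + hy * ny)
            if closing > 0 and dist < AVOID_MARGIN_MM:
                a = (1.0 - dist / AVOID_MARGIN_MM) * min(closing, 1.0)
                vx = (1.0 - a) * vx + a * tan_sign * tx
                vy = (1.0 - a) * vy + a * tan_sign * ty
        elif mode == "stereo":
            # confined jitter around the anchor at a modest speed
            speed = min(speed, 10.0)
            heading += 0.8 * turn_noise[k]
            hx, hy = math.cos(heading), math.sin(heading)
            dxa, dya = bout["anchor"][0] - x, bout["anchor"][1] - y
            d = math.hypot(dxa, dya)
            pull = min(1.0, (d / bout["radius"]) ** 2)
            vx = (1 - pull) * hx + (pull * dxa / d if d > 1e-9 else 0.0)
            vy = (1 - pull) * hy + (pull * dya / d if d > 1e-9 else 0.0)
            speed = max(speed, 4.0)  # stay clearly above the swim threshold
            if t_now >= bout["end_s"]:
                truth.append(
                    {
                        "fish_id": fish_id,
                        "label": "stereotypic",
                        "start_s": bout["start_s"],
                        "end_s": t_now,
                    }
                )
                mode = "walk"
        elif mode in ("approach_circle", "approach_bnf"):
            nx, ny, tx, ty, dist = wall_frame_scalar(x, y)
            if dist <= follow_target * 1.5:
                if mode == "approach_circle":
                    bout["start_s"] = t_now
                    th = math.atan2(y - cy, x - cx)
                    bout["theta"] = th
                    mode = "circle"
                else:
                    bout["start_s"] = t_now
                    bout["anchor"] = (x, y)
                    bout["s0"] = perimeter_scalar(x, y)
                    bout["s"] = bout["s0"]
                    # set off against the arrival drift so the start point
                    # is a genuine turn-around, as "returning to the
                    # origin" implies
                    drift = hx * tx + hy * ty
                    if abs(drift) > 0.1:
                        bout["sign"] = -math.copysign(1.0, drift)
                    mode = "bnf"
                vx, vy = -nx, -ny
            else:
                vx, vy = -nx, -ny  # head straight for the wall
        if mode == "circle":
            nx, ny, tx, ty, dist = wall_frame_scalar(x, y)
            s = bout["sign"]
            corr = 0.25 * (follow_target - dist)
            vx = s * tx + corr * nx
            vy = s * ty + corr * ny
            speed = max(speed, 0.6 * params.mean_speed_mm_s)
            th = math.atan2(y - cy, x - cx)
            dth = th - bout["theta"]
            if dth > math.pi:
                dth -= TWO_PI
            elif dth <= -math.pi:
                dth += TWO_PI
            bout["winding"] += dth
            bout["theta"] = th
            if abs(bout["winding"]) >= bout["loops"] * TWO_PI:
                truth.append(
                    {
                        "fish_id": fish_id,
                        "label": "large_circle_ccw" if bout["winding"] > 0 else "large_circle_cw",
                        "start_s": bout["start_s"],
                        "end_s": t_now,
                    }
                )
                mode = "walk"
        elif mode == "bnf":
            nx, ny, tx, ty, dist = wall_frame_scalar(x, y)
            # track progress in the perimeter coordinate (unwrap steps)
            s_now = perimeter_scalar(x, y)
            ds = s_now - (bout["s"] % perimeter_len)
            ds -= perimeter_len * round(ds / perimeter_len)
            bout["s"] += ds
            excursion = abs(bout["s"] - bout["s0"])
            d_home = math.hypot(x - bout["anchor"][0], y - bout["anchor"][1])
            sgn = bout["sign"] if bout["phase"] == "out" else -bout["sign"]
            if bout["phase"] == "back" and excursion < 30.0 and d_home > 1e-9:
                # home straight onto the anchor for an unambiguous return
                vx = (bout["anchor"][0] - x) / d_home
                vy = (bout["anchor"][1] - y) / d_home
            else:
                corr = 0.25 * (follow_target - dist)
                vx = sgn * tx + corr * nx
                vy = sgn * ty + corr * ny
            speed = max(speed, 0.6 * params.mean_speed_mm_s)
            bout["path"] += speed * dt
            if bout["phase"] == "out" and excursion >= bout["leg"]:
                bout["phase"] = "back"
            elif bout["phase"] == "back" and d_home <= 7.0:
                truth.append(
                    {
                        "fish_id": fish_id,
                        "label": "back_and_forth",
                        "start_s": bout["start_s"],
                        "end_s": t_now,
                    }
                )
                mode = "walk"
            elif bout["path"] > 6 * bout["leg"]:
                mode = "walk"  # abort without truth; should not happen

        norm = math.hypot(vx, vy)
        if norm > 1e-9:
            hx, hy = vx / norm, vy / norm
        x += speed * dt * hx
        y += speed * dt * hy
        x, y, hx, hy = reflect_scalar(x, y, hx, hy)
        heading = math.atan2(hy, hx)
        xs[k + 1], ys[k + 1] = x, y
    return np.column_stack([xs, ys]), truth


# ---------------------------------------------------------------------------
# public entry points


def _to_trajectory(
    pos: np.ndarray, fish_id: str, arena: ArenaGeometry, frame_rate_hz: float
) -> Trajectory:
    n = pos.shape[0]
    return Trajectory(
        fish_id=fish_id,
        arena_id=arena.arena_id,
        frame_rate_hz=frame_rate_hz,
        t_s=np.arange(n) / frame_rate_hz,
        x_mm=pos[:, 0],
        y_mm=pos[:, 1],
    )


def simulate_fish(
    params: AgentParams,
    arena: ArenaGeometry,
    schedule: Optional[LightSchedule],
    duration_s: float,
    seed: int,
    frame_rate_hz: float = 25.0,
    fish_id: str = "fish0",
    hard: bool = False,
) -> Tuple[Trajectory, GroundTruthLog]:
    """Simulate one fish; fully determined by ``seed``."""
    params.validate()
    if duration_s <= 0 or frame_rate_hz <= 0:
        raise ValueError("duration and frame rate must be positive")
    if params.bout_rates.get("back_and_forth", 0) > 0 and arena.shape != "rectangle":
        raise ValueError("back_and_forth bouts require a rectangular arena")
    rng = np.random.default_rng(seed)
    log = GroundTruthLog(seed=seed, agent_params={fish_id: asdict(params)})
    pos, truth = _simulate_with_bouts(
        params, arena, schedule, duration_s, rng, frame_rate_hz, fish_id, hard
    )
    log.bouts = truth
    return _to_trajectory(pos, fish_id, arena, frame_rate_hz), log


def simulate_group(
    n: int,
    params: AgentParams,
    arena: ArenaGeometry,
    schedule: Optional[LightSchedule],
    duration_s: float,
    seed: int,
    frame_rate_hz: float = 25.0,
) -> List[Trajectory]:
    """Batched simulation of ``n`` independent fish from one seed.

    Vectorised across agents (a single shared random stream), so large
    cohorts of plain walkers are cheap; bout injection is not supported
    here — use :func:`simulate_fish` for that.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params.validate()
    if params.bout_rates:
        raise ValueError("simulate_group does not inject bouts; use simulate_fish")
    rng = np.random.default_rng(seed)
    pos = _simulate_walk(n, params, arena, schedule, duration_s, rng, frame_rate_hz)
    return [_to_trajectory(pos[i], f"fish{i}", arena, frame_rate_hz) for i in range(n)]


def simulate_shoal(
    k: int,
    params: AgentParams,
    arena: ArenaGeometry,
    duration_s: float,
    seed: int,
    frame_rate_hz: float = 25.0,
) -> Tuple[List[Trajectory], GroundTruthLog]:
    """Simulate ``k`` coupled agents steered toward the group centroid."""
    if k < 2:
        raise ValueError("a shoal needs k >= 2 fish")
    params.validate()
    rng = np.random.default_rng(seed)
    pos = _simulate_walk(
        k, params, arena, None, duration_s, rng, frame_rate_hz, cohesion=params.cohesion
    )
    trajs = [_to_trajectory(pos[i], f"fish{i}", arena, frame_rate_hz) for i in range(k)]
    log = GroundTruthLog(
        seed=seed, agent_params={t.fish_id: asdict(params) for t in trajs}
    )
    return trajs, log


ASSAYS = ("pmr_7dpf", "open_field", "social_preference", "shoaling", "repetitive")

# Study-condition parameter sets per assay and group.  The wild-type/mutant
# contrast follows the phenotype under study: hypoactive larvae with an
# intact photomotor response; at juvenile stages hyperactivity, stronger
# wall preference, weaker social attraction, looser shoaling and injected
# repetitive bouts in the mutant group.
_GROUP_DEFAULTS: Dict[str, Dict[str, AgentParams]] = {
    "pmr_7dpf": {
        "wt": AgentParams(mean_speed_mm_s=2.5, turn_sd_rad=0.5, wall_bias=0.3, dark_multiplier=2.0),
        "mut": AgentParams(mean_speed_mm_s=1.5, turn_sd_rad=0.5, wall_bias=0.5, dark_multiplier=2.0),
    },
    "open_field": {
        "wt": AgentParams(mean_speed_mm_s=25.0, wall_bias=0.2),
        "mut": AgentParams(mean_speed_mm_s=35.0, wall_bias=0.4),
    },
    "social_preference": {
        "wt": AgentParams(mean_speed_mm_s=30.0, wall_bias=0.1, social_weight=0.8),
        "mut": AgentParams(mean_speed_mm_s=30.0, wall_bias=0.1, social_weight=0.1),
    },
    "shoaling": {
        "wt": AgentParams(mean_speed_mm_s=30.0, wall_bias=0.1, cohesion=0.7),
        "mut": AgentParams(mean_speed_mm_s=30.0, wall_bias=0.1, cohesion=0.1),
    },
    "repetitive": {
        "wt": AgentParams(mean_speed_mm_s=30.0, wall_bias=0.1),
        "mut": AgentParams(
            mean_speed_mm_s=30.0,
            wall_bias=0.1,
            bout_rates={"stereotypic": 1 / 150.0, "large_circle": 1 / 150.0, "back_and_forth": 1 / 150.0},
        ),
    },
}

_ASSAY_ARENA = {
    "pmr_7dpf": "well24_7dpf",
    "open_field": "tank300_open",
    "social_preference": "mating_tank",
    "shoaling": "tank300_open",
    "repetitive": "tank300_open",
}

_ASSAY_DURATION_S = {
    "open_field": 600.0,
    "social_preference": 1800.0,
    "shoaling": 1800.0,
    "repetitive": 1800.0,
}


def classifier_validation_params(label: str) -> AgentParams:
    """Generative conditions for validating one repetitive-behaviour detector.

    A quiet, weakly wall-biased ballistic background (so spontaneous
    rule-crossing events are rare) with frequent injected bouts of a
    single label, well clear of the detector thresholds.  Used with
    900-s sessions.
    """
    if label not in ("stereotypic", "large_circle", "back_and_forth"):
        raise ValueError(f"unknown bout label {label!r}")
    return AgentParams(
        mean_speed_mm_s=30.0,
        wall_bias=0.0,
        turn_sd_rad=0.12,
        bout_rates={label: 1.0 / 45.0},
    )


def default_params(assay: str, group: str) -> AgentParams:
    """The default generative parameters for one assay group (wt|mut)."""
    try:
        return _GROUP_DEFAULTS[assay][group]
    except KeyError:
        raise ValueError(f"unknown assay/group {assay!r}/{group!r}") from None


@dataclass
class CohortManifest:
    """Paths and metadata for one simulated two-group cohort."""

    assay: str
    seed: int
    arena: ArenaGeometry
    schedule: Optional[LightSchedule]
    frame_rate_hz: float
    files: Dict[str, List[Path]]  # group -> tracking files
    truth_path: Path


def make_cohort(
    n_per_group: int,
    wt_params: Optional[AgentParams],
    mut_params: Optional[AgentParams],
    assay: str,
    seed: int,
    out_dir,
    duration_s: Optional[float] = None,
    frame_rate_hz: float = 25.0,
    shoal_size: int = 6,
) -> CohortManifest:
    """Simulate and write a two-group cohort for one assay.

    One tracking file per fish (per shoal for the shoaling assay), plus a
    single ground-truth JSON.  Group parameter sets default to
    :func:`default_params`.  Per-unit seeds are split deterministically
    from the single cohort seed.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; valid: {', '.join(ASSAYS)}")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arena = make_standard_arena(_ASSAY_ARENA[assay])
    if assay == "pmr_7dpf":
        schedule = make_pmr_schedule("methods")
        dur = schedule.span_s if duration_s is None else float(duration_s)
        if duration_s is not None and duration_s < schedule.span_s:
            raise ValueError("pmr_7dpf duration cannot be shorter than the protocol span")
    else:
        dur = _ASSAY_DURATION_S[assay] if duration_s is None else float(duration_s)
        schedule = constant_light_schedule(dur)
    group_params = {
        "wt": wt_params or default_params(assay, "wt"),
        "mut": mut_params or default_params(assay, "mut"),
    }
    seeds = np.random.SeedSequence(seed).spawn(2 * n_per_group)
    truth = GroundTruthLog(seed=seed, agent_params={})
    files: Dict[str, List[Path]] = {"wt": [], "mut": []}
    unit = 0
    for group in ("wt", "mut"):
        params = group_params[group]
        params.validate()
        for i in range(n_per_group):
            unit_seed = seeds[unit]
            unit += 1
            uid = f"{group}_{i:03d}"
            if assay == "shoaling":
                rng_seed = int(unit_seed.generate_state(1)[0] % (2**31))
                trajs, log = simulate_shoal(
                    shoal_size, params, arena, dur, rng_seed, frame_rate_hz
                )
                trajs = [replace_fish_id(t, f"{uid}_f{j}") for j, t in enumerate(trajs)]
                for t in trajs:
                    truth.agent_params[t.fish_id] = asdict(params)
            else:
                rng_seed = int(unit_seed.generate_state(1)[0] % (2**31))
                traj, log = simulate_fish(
                    params, arena, schedule, dur, rng_seed, frame_rate_hz, fish_id=uid
                )
                trajs = [traj]
                truth.agent_params[uid] = asdict(params)
                truth.bouts.extend(log.bouts)
            path = out_dir / f"{uid}.csv"
            write_tracking(trajs, path)
            files[group].append(path)
    truth_path = out_dir / "ground_truth.json"
    truth.to_json(truth_path)
    return CohortManifest(
        assay=assay,
        seed=seed,
        arena=arena,
        schedule=schedule,
        frame_rate_hz=frame_rate_hz,
        files=files,
        truth_path=truth_path,
    )


def replace_fish_id(traj: Trajectory, fish_id: str) -> Trajectory:
    return Trajectory(
        fish_id=fish_id,
        arena_id=traj.arena_id,
        frame_rate_hz=traj.frame_rate_hz,
        t_s=traj.t_s,
        x_mm=traj.x_mm,
        y_mm=traj.y_mm,
        missing=traj.missing,
    )
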