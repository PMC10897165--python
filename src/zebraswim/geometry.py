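"""Arenas, regions, and light/dark protocol schedules.

All coordinates are millimetres.  Circular arenas are centred on the
origin; rectangular arenas have their lower-left corner at the origin,
x to the right and y up.  Depth is ignored: tracking is 2-D top view.

Region membership is boundary-inclusive, so a point lying exactly on a
zone boundary counts as inside -- a deterministic tie-break that keeps
partition fractions summing to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "Region",
    "ArenaGeometry",
    "Epoch",
    "LightSchedule",
    "make_standard_arena",
    "make_inner_zone",
    "make_outer_zone",
    "make_pmr_schedule",
    "ARENA_PRESETS",
]


@dataclass(frozen=True)
class Region:
    """A named planar region inside an arena.

    ``kind`` selects the geometry and ``params`` its lengths (mm):

    - ``disk``: ``(cx, cy, r)``
    - ``rectangle``: ``(x0, y0, x1, y1)``
    - ``annulus``: ``(cx, cy, r_in, r_out)``
    - ``half_plane``: ``(a, b, c)`` for the set ``a*x + b*y <= c``
    """

    name: str
    kind: str
    params: Tuple[float, ...]

    def __post_init__(self) -> None:
        n_expected = {"disk": 3, "rectangle": 4, "annulus": 4, "half_plane": 3}
        if self.kind not in n_expected:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if len(self.params) != n_expected[self.kind]:
            raise ValueError(
                f"region kind {self.kind!r} takes {n_expected[self.kind]} "
                f"parameters, got {len(self.params)}"
            )
        if self.area() <= 0:
            raise ValueError(f"region {self.name!r} has non-positive area")

    def area(self) -> float:
        if self.kind == "disk":
            return math.pi * self.params[2] ** 2
        if self.kind == "rectangle":
            x0, y0, x1, y1 = self.params
            return (x1 - x0) * (y1 - y0)
        if self.kind == "annulus":
            _, _, r_in, r_out = self.params
            if r_in < 0 or r_out <= r_in:
                return -1.0
            return math.pi * (r_out**2 - r_in**2)
        return math.inf  # half plane

    def contains(self, x, y):
        """Boundary-inclusive membership; accepts scalars or arrays."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "disk":
            cx, cy, r = self.params
            return (x - cx) ** 2 + (y - cy) ** 2 <= r**2
        if self.kind == "rectangle":
            x0, y0, x1, y1 = self.params
            return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
        if self.kind == "annulus":
            cx, cy, r_in, r_out = self.params
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            return (d2 >= r_in**2) & (d2 <= r_out**2)
        a, b, c = self.params
        return a * x + b * y <= c


@dataclass(frozen=True)
class ArenaGeometry:
    """A swim arena: a circular well/dish or a rectangular tank.

    ``edge_band_mm`` is the distance-from-wall band that operationalises
    "along the edges" for wall-following behaviours.
    """

    arena_id: str
    shape: str  # "circle" | "rectangle"
    radius_mm: float = 0.0
    width_mm: float = 0.0
    height_mm: float = 0.0
    edge_band_mm: float = 0.0
    regions: Dict[str, Region] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape == "circle":
            if self.radius_mm <= 0:
                raise ValueError("circular arena needs radius_mm > 0")
        elif self.shape == "rectangle":
            if self.width_mm <= 0 or self.height_mm <= 0:
                raise ValueError("rectangular arena needs positive width/height")
        else:
            raise ValueError(f"unknown arena shape {self.shape!r}")
        if not 0 < self.edge_band_mm < self.half_extent_mm:
            raise ValueError(
                "edge_band_mm must lie in (0, arena half-extent "
                f"{self.half_extent_mm} mm), got {self.edge_band_mm}"
            )

    @property
    def half_extent_mm(self) -> float:
        if self.shape == "circle":
            return self.radius_mm
        return min(self.width_mm, self.height_mm) / 2.0

    @property
    def center(self) -> Tuple[float, float]:
        if self.shape == "circle":
            return (0.0, 0.0)
        return (self.width_mm / 2.0, self.height_mm / 2.0)

    @property
    def bounds(self) -> Tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        if self.shape == "circle":
            r = self.radius_mm
            return (-r, -r, r, r)
        return (0.0, 0.0, self.width_mm, self.height_mm)

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "circle":
            return x**2 + y**2 <= self.radius_mm**2
        return (x >= 0) & (x <= self.width_mm) & (y >= 0) & (y <= self.height_mm)

    def wall_distance(self, x, y):
        """Signed distance to the nearest wall: positive inside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "circle":
            return self.radius_mm - np.hypot(x, y)
        return np.minimum(np.minimum(x, self.width_mm - x), np.minimum(y, self.height_mm - y))

    def nearest_wall(self, x, y):
        """For rectangles: index of the nearest wall per point.

        0=left(x=0), 1=right(x=w), 2=bottom(y=0), 3=top(y=h); ties go to
        the lowest index.
        """
        if self.shape != "rectangle":
            raise ValueError("nearest_wall is defined for rectangular arenas")
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d = np.stack([x, self.width_mm - x, y, self.height_mm - y])
        return np.argmin(d, axis=0)

    def with_region(self, region: Region) -> "ArenaGeometry":
        regions = dict(self.regions)
        regions[region.name] = region
        return ArenaGeometry(
            arena_id=self.arena_id,
            shape=self.shape,
            radius_mm=self.radius_mm,
            width_mm=self.width_mm,
            height_mm=self.height_mm,
            edge_band_mm=self.edge_band_mm,
            regions=regions,
        )


@dataclass(frozen=True)
class Epoch:
    start_s: float
    end_s: float
    condition: str  # "light" | "dark"
    label: str  # adaptation | L0 | L1 | D1 | L2 | D2 | open_field ...
    cycle: int = 0  # 0 for baseline, 1.. for light/dark cycle pairs

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("epoch must have end_s > start_s")
        if self.condition not in ("light", "dark"):
            raise ValueError(f"unknown light condition {self.condition!r}")


@dataclass(frozen=True)
class LightSchedule:
    """Ordered, contiguous light/dark epochs covering a recording."""

    epochs: Tuple[Epoch, ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule needs at least one epoch")
        if self.epochs[0].start_s != 0:
            raise ValueError("first epoch must start at t=0")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.start_s != a.end_s:
                raise ValueError("epochs must be contiguous and non-overlapping")

    @property
    def span_s(self) -> float:
        return self.epochs[-1].end_s

    def label_at(self, t_s):
        """Epoch label covering each time (end-exclusive except the last)."""
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        edges = np.array([e.start_s for e in self.epochs] + [self.span_s])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self.epochs) - 1)
        labels = np.array([e.label for e in self.epochs])
        out = labels[idx]
        return out if np.ndim(t_s) else out[0]

    def condition_at(self, t_s):
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        edges = np.array([e.start_s for e in self.epochs] + [self.span_s])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self.epochs) - 1)
        dark = np.array([e.condition == "dark" for e in self.epochs])
        out = np.where(dark[idx], "dark", "light")
        return out if np.ndim(t_s) else out[0]

    def epoch(self, label: str) -> Epoch:
        for e in self.epochs:
            if e.label == label:
                return e
        raise KeyError(f"no epoch labelled {label!r}")


def _circle_arena(arena_id: str, radius: float, band: float) -> ArenaGeometry:
    return ArenaGeometry(arena_id=arena_id, shape="circle", radius_mm=radius, edge_band_mm=band)


def _social_regions(length: float, height: float, strip: float) -> Dict[str, Region]:
    # divider wall sits at x = length; the social strip abuts it
    return {
        "social": Region("social", "rectangle", (length - strip, 0.0, length, height)),
        "nonsocial": Region("nonsocial", "rectangle", (0.0, 0.0, length - strip, height)),
    }


ARENA_PRESETS = {
    # 24-well plate well for 7-dpf larvae: 18 mm inner diameter
    "well24_7dpf": lambda: _circle_arena("well24_7dpf", 9.0, 1.8),
    # 35-mm dish for 15-dpf fish
    "dish35_15dpf": lambda: _circle_arena("dish35_15dpf", 17.5, 3.5),
    # 30 x 30 cm open-field / novel tank (30-dpf and 2-mpf fish)
    "tank300_open": lambda: ArenaGeometry(
        arena_id="tank300_open", shape="rectangle", width_mm=300.0, height_mm=300.0,
        edge_band_mm=30.0,
    ),
    # 21 x 10 cm mating tank with a divider; the third of the tank nearest
    # the divider is the social region, the rest nonsocial
    "mating_tank": lambda: ArenaGeometry(
        arena_id="mating_tank", shape="rectangle", width_mm=210.0, height_mm=100.0,
        edge_band_mm=25.0, regions=_social_regions(210.0, 100.0, 70.0),
    ),
}


def make_standard_arena(preset: str) -> ArenaGeometry:
    """Build one of the standard assay arenas by preset name."""
    try:
        factory = ARENA_PRESETS[preset]
    except KeyError:
        valid = ", ".join(sorted(ARENA_PRESETS))
        raise ValueError(f"unknown arena preset {preset!r}; valid presets: {valid}") from None
    return factory()


def make_inner_zone(arena: ArenaGeometry, inner_fraction: float = 0.5) -> Region:
    """Concentric inner disk used for thigmotaxis, radius = fraction x well radius."""
    if arena.shape != "circle":
        raise ValueError("inner/outer thigmotaxis zones are defined for circular wells only")
    if not 0 < inner_fraction < 1:
        raise ValueError("inner_fraction must lie strictly between 0 and 1")
    return Region("inner", "disk", (0.0, 0.0, inner_fraction * arena.radius_mm))


def make_outer_zone(arena: ArenaGeometry, inner_fraction: float = 0.5) -> Region:
    """Complementary outer annulus of :func:`make_inner_zone`.

    The shared boundary circle is inclusive on both sides, so the two zones
    cover the well; points exactly on the boundary count as inner by the
    partition convention used in :mod:`zebraswim.zones`.
    """
    if arena.shape != "circle":
        raise ValueError("inner/outer thigmotaxis zones are defined for circular wells only")
    if not 0 < inner_fraction < 1:
        raise ValueError("inner_fraction must lie strictly between 0 and 1")
    return Region(
        "outer", "annulus", (0.0, 0.0, inner_fraction * arena.radius_mm, arena.radius_mm)
    )


def make_pmr_schedule(variant: str = "methods") -> LightSchedule:
    """Photomotor-response light/dark protocol for the 7-dpf assay.

    Two published descriptions of the same protocol disagree on the
    baseline length, so both are provided:

    - ``methods``: 55 min continuous light (L0) then two 5-min-light /
      5-min-dark transition cycles; 75 min total.
    - ``figure``: 20 min adaptation, 40 min baseline light (L0), then the
      same two cycles; 80 min total, with analysis conventionally starting
      at minute 21.

    Neither variant is canonical here; pick per experiment.
    """
    if variant == "methods":
        t0 = 0.0
        epochs: List[Epoch] = [Epoch(0.0, 55 * 60.0, "light", "L0", 0)]
        t0 = 55 * 60.0
    elif variant == "figure":
        epochs = [
            Epoch(0.0, 20 * 60.0, "light", "adaptation", 0),
            Epoch(20 * 60.0, 60 * 60.0, "light", "L0", 0),
        ]
        t0 = 60 * 60.0
    else:
        raise ValueError("schedule variant must be 'figure' or 'methods'")
    for cycle in (1, 2):
        epochs.append(Epoch(t0, t0 + 300.0, "light", f"L{cycle}", cycle))
        epochs.append(Epoch(t0 + 300.0, t0 + 600.0, "dark", f"D{cycle}", cycle))
        t0 += 600.0
    return LightSchedule(tuple(epochs))


def constant_light_schedule(duration_s: float, label: str = "open_field") -> LightSchedule:
    """A single light epoch spanning the whole recording (open-field assays)."""
    return LightSchedule((Epoch(0.0, float(duration_s), "light", label, 0),))
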