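"""Shared fixtures: arenas and synthetic trajectory builders."""

import numpy as np
import pytest

from zebraswim import Trajectory, make_standard_arena


@pytest.fixture(scope="session")
def well():
    return make_standard_arena("well24_7dpf")


@pytest.fixture(scope="session")
def dish():
    return make_standard_arena("dish35_15dpf")


@pytest.fixture(scope="session")
def tank():
    return make_standard_arena("tank300_open")


@pytest.fixture(scope="session")
def mating_tank():
    return make_standard_arena("mating_tank")


def make_traj(x, y, fps=25.0, fish_id="f0", arena_id="arena", t=None):
    x = np.asarray(x, dtype=float)
    if t is None:
        t = np.arange(len(x)) / fps
    return Trajectory(
        fish_id=fish_id,
        arena_id=arena_id,
        frame_rate_hz=fps,
        t_s=t,
        x_mm=x,
        y_mm=np.asarray(y, dtype=float),
    )


def circle_path(radius, angular_speed, duration_s, fps=25.0, center=(0.0, 0.0), phase=0.0):
    """Analytic circular trajectory sampled at the frame rate."""
    t = np.arange(0.0, duration_s, 1.0 / fps)
    ang = phase + angular_speed * t
    return make_traj(center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang), fps=fps, t=t)
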