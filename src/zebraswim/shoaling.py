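"""Shoal cohesion via interindividual distance (IID).

IID at a time point is the mean of all k(k-1)/2 pairwise Euclidean
distances among the shoal members; the assay statistic is its time
average over the analysis window.  Frames where any fish is untracked
are dropped rather than interpolated, because a pairwise mean over a
partial shoal is biased; the fraction dropped is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tracking import Trajectory

__all__ = ["ShoalingResult", "interindividual_distance"]


@dataclass
class ShoalingResult:
    mean_iid_mm: float
    t_s: np.ndarray
    iid_mm: np.ndarray  # per-frame series over retained frames
    dropped_fraction: float
    n_fish: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "iid_mm": self.iid_mm})


def interindividual_distance(
    trajs: Sequence[Trajectory],
    window: Optional[Tuple[float, float]] = None,
) -> ShoalingResult:
    """Time-averaged mean pairwise distance of a shoal.

    Trajectories must be frame-synchronised: equal length with timestamps
    agreeing to within one frame interval.
    """
    trajs = list(trajs)
    k = len(trajs)
    if k < 2:
        raise ValueError("shoaling metrics need at least two fish")
    n = len(trajs[0])
    tol = 1.0 / trajs[0].frame_rate_hz
    t_ref = trajs[0].t_s
    for tr in trajs[1:]:
        if len(tr) != n or np.max(np.abs(tr.t_s - t_ref)) > tol:
            raise ValueError(
                f"trajectories are not frame-synchronised (fish {tr.fish_id!r})"
            )
    keep = ~np.any([tr.missing for tr in trajs], axis=0)
    if window is not None:
        t0, t1 = window
        keep &= (t_ref >= t0) & (t_ref <= t1)
        n_window = int(np.sum((t_ref >= t0) & (t_ref <= t1)))
    else:
        n_window = n
    if not keep.any():
        raise ValueError("no frames where all fish are tracked")
    xs = np.stack([tr.x_mm[keep] for tr in trajs])  # (k, m)
    ys = np.stack([tr.y_mm[keep] for tr in trajs])
    total = np.zeros(xs.shape[1])
    for i in range(k):
        for j in range(i + 1, k):
            total += np.hypot(xs[i] - xs[j], ys[i] - ys[j])
    iid = total / (k * (k - 1) / 2)
    return ShoalingResult(
        mean_iid_mm=float(iid.mean()),
        t_s=t_ref[keep],
        iid_mm=iid,
        dropped_fraction=1.0 - keep.sum() / n_window,
        n_fish=k,
    )
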