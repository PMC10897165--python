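"""End-to-end assay pipeline: simulate or load → metrics → group tables.

A run is described by a :class:`RunConfig` (typically loaded from a YAML
file), executed by :func:`run_pipeline`, and written out as CSV tables
plus a plain-text provenance block echoing every threshold and the seed,
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import make_inner_zone
from .kinematics import bin_activity, light_dark_ratio, mean_distance_per_min, path_distance
from .repetitive import (
    detect_back_and_forth,
    detect_large_circle,
    detect_stereotypic,
    summarize_repetitive,
)
from .shoaling import interindividual_distance
from .simulate import ASSAYS, AgentParams, default_params, make_cohort
from .stats import compare_groups
from .tracking import read_tracking, suppress_jitter
from .zones import occupancy_heatmap, social_preference, zone_occupancy

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    All analysis thresholds default to the assay conventions; every value
    is echoed into the provenance block of the output directory.
    """

    assay: str
    out_dir: str
    seed: int = 0
    n_per_group: int = 8
    duration_s: Optional[float] = None
    frame_rate_hz: float = 25.0
    schedule_variant: str = "methods"  # pmr protocol variant: methods | figure
    inner_fraction: float = 0.5
    jitter_min_step_mm: float = 0.2
    bin_s: float = 60.0
    heatmap_grid_mm: float = 5.0
    shoal_size: int = 6
    group_params: Dict[str, dict] = field(default_factory=dict)  # optional overrides

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise PipelineError(
                f"config: unknown assay {self.assay!r}; valid: {', '.join(ASSAYS)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "assay" not in raw or "out_dir" not in raw:
            raise PipelineError("config: 'assay' and 'out_dir' keys are required")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def resolved_params(self, group: str) -> AgentParams:
        if group in self.group_params:
            return AgentParams(**self.group_params[group])
        return default_params(self.assay, group)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def _comparison_rows(per_fish: pd.DataFrame, metrics: List[str]) -> pd.DataFrame:
    rows = []
    for metric in metrics:
        a = per_fish.loc[per_fish["group"] == "wt", metric].to_numpy()
        b = per_fish.loc[per_fish["group"] == "mut", metric].to_numpy()
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            continue
        c = compare_groups(a, b, "wt", "mut")
        rows.append(
            {
                "metric": metric,
                "mean_wt": c.mean_a,
                "sem_wt": c.sem_a,
                "n_wt": c.n_a,
                "mean_mut": c.mean_b,
                "sem_mut": c.sem_b,
                "n_mut": c.n_b,
                "t": c.t,
                "p": c.p,
                "stars": c.stars,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Execute one assay end to end; returns the written artifact paths.

    Stages: simulate cohort → load tracking files → jitter suppression →
    per-fish metrics → group comparison tables → provenance.  Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_dir = out_dir / "tracking"

    try:
        manifest = make_cohort(
            n_per_group=config.n_per_group,
            wt_params=config.resolved_params("wt"),
            mut_params=config.resolved_params("mut"),
            assay=config.assay,
            seed=config.seed,
            out_dir=data_dir,
            duration_s=config.duration_s,
            frame_rate_hz=config.frame_rate_hz,
            shoal_size=config.shoal_size,
        )
    except Exception as e:
        raise PipelineError(f"stage simulate ({config.assay}): {e}") from e

    outputs: Dict[str, Path] = {"tracking_dir": data_dir, "truth": manifest.truth_path}
    arena = manifest.arena

    def load(path: Path):
        try:
            trajs = read_tracking(path, arena)
        except Exception as e:
            raise PipelineError(f"stage load ({path.name}): {e}") from e
        return [suppress_jitter(t, config.jitter_min_step_mm) for t in trajs]

    try:
        if config.assay == "shoaling":
            rows = []
            for group in ("wt", "mut"):
                for path in manifest.files[group]:
                    trajs = load(path)
                    res = interindividual_distance(trajs)
                    rows.append(
                        {
                            "group": group,
                            "unit": path.stem,
                            "mean_iid_mm": res.mean_iid_mm,
                            "dropped_fraction": res.dropped_fraction,
                        }
                    )
            per_fish = pd.DataFrame(rows)
            metrics = ["mean_iid_mm"]
        else:
            rows = []
            binned_frames = []
            group_trajs: Dict[str, list] = {"wt": [], "mut": []}
            for group in ("wt", "mut"):
                for path in manifest.files[group]:
                    (traj,) = load(path)
                    group_trajs[group].append(traj)
                    row = {"group": group, "unit": traj.fish_id}
                    if config.assay == "pmr_7dpf":
                        schedule = manifest.schedule
                        binned = bin_activity(traj, schedule, config.bin_s)
                        binned_frames.append(binned.to_frame().assign(group=group))
                        row["mean_l0_mm_per_min"] = mean_distance_per_min(binned, "L0")
                        for cyc in (1, 2):
                            row[f"ld_ratio_cycle{cyc}"] = light_dark_ratio(binned, cyc).ratio
                        inner = make_inner_zone(arena, config.inner_fraction)
                        l0 = schedule.epoch("L0")
                        occ = zone_occupancy(traj, inner, (l0.start_s, l0.end_s))
                        row["inner_time_fraction"] = occ.time_fraction
                        row["inner_distance_fraction"] = occ.distance_fraction
                    elif config.assay == "open_field":
                        t0, t1 = traj.span_s
                        row["mean_mm_per_min"] = path_distance(traj, t0, t1) / ((t1 - t0) / 60.0)
                    elif config.assay == "social_preference":
                        pref = social_preference(traj, arena)
                        row["time_fraction_social"] = pref.time_fraction_social
                        row["distance_fraction_social"] = pref.distance_fraction_social
                        row["distance_fraction_away"] = pref.distance_fraction_away
                    elif config.assay == "repetitive":
                        bouts = (
                            detect_stereotypic(traj)
                            + detect_large_circle(traj, arena)
                            + detect_back_and_forth(traj, arena)
                        )
                        summary = summarize_repetitive(bouts, traj.span_s)
                        for label, n in summary.counts.items():
                            row[f"count_{label}"] = n
                            row[f"duration_{label}_s"] = summary.durations_s[label]
                    rows.append(row)
            per_fish = pd.DataFrame(rows)
            metrics = [c for c in per_fish.columns if c not in ("group", "unit")]
            if binned_frames:
                binned_path = out_dir / "binned_activity.csv"
                _write_csv(pd.concat(binned_frames, ignore_index=True), binned_path)
                outputs["binned_activity"] = binned_path
            if config.assay == "social_preference":
                for group in ("wt", "mut"):
                    hm = occupancy_heatmap(group_trajs[group], arena, config.heatmap_grid_mm)
                    hm_path = out_dir / f"heatmap_{group}.txt"
                    hm.to_text(hm_path)
                    outputs[f"heatmap_{group}"] = hm_path
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage metrics ({config.assay}): {e}") from e

    per_fish_path = out_dir / "per_fish_metrics.csv"
    _write_csv(per_fish, per_fish_path)
    outputs["per_fish_metrics"] = per_fish_path

    comparisons = _comparison_rows(per_fish, metrics)
    comp_path = out_dir / "group_comparisons.csv"
    _write_csv(comparisons, comp_path)
    outputs["group_comparisons"] = comp_path

    prov_path = out_dir / "provenance.txt"
    with open(prov_path, "w", encoding="utf-8") as fh:
        fh.write(f"zebraswim version: {__version__}\n")
        fh.write("note: no multiple-testing correction applied across panels\n")
        for key, value in sorted(asdict(config).items()):
            fh.write(f"{key}: {value}\n")
    outputs["provenance"] = prov_path
    return outputs
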