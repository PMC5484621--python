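"""End-to-end orchestration: frames -> traces -> metrics -> records.

Recordings are processed epoch by epoch so that arbitrarily long
experiments fit in memory: each epoch's frames are differenced at both
intervals (5 s and 60 s), reduced to per-well metrics, and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .activity import FrameStack, trace_for_interval
from .behavior import EpochSchedule, epoch_metrics_table
from .decline import decline_summaries
from .geometry import WellMap
from .lifespan import WormRecord, build_worm_records

__all__ = ["AnalysisResult", "analyze_epoch_stacks", "analyze_recording", "analyze_simulated"]


@dataclass
class AnalysisResult:
    """Everything downstream statistics need from one recording."""

    metrics: pd.DataFrame
    records: list[WormRecord]
    schedule: EpochSchedule
    well_map: WellMap

    def death_times(self) -> dict[int, float]:
        return {r.well_index: r.death_time_h for r in self.records if not r.censored}

    def stim_series(self) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for well, sub in self.metrics.groupby("well_index"):
            sub = sub.sort_values("time_h")
            out[int(well)] = (sub["time_h"].to_numpy(), sub["stimulated"].to_numpy(dtype=float))
        return out

    def decline_table(self) -> pd.DataFrame:
        return decline_summaries(self.stim_series(), self.death_times())


def analyze_epoch_stacks(
    stacks: Iterable[FrameStack],
    well_map: WellMap,
    schedule: EpochSchedule,
    strain: str = "",
    adulthood_start_h: float = 0.0,
    activity_floor: float = 0.0,
    manual_censor: set[int] | None = None,
) -> AnalysisResult:
    """Analyze an iterable of per-epoch frame stacks (one per schedule epoch)."""
    chunks = []
    for e, stack in enumerate(stacks):
        sub_schedule = EpochSchedule(
            [schedule.epoch_starts[e]],
            epoch_duration_s=schedule.epoch_duration_s,
            stimulus_onset_s=schedule.stimulus_onset_s,
            stimulus_duration_s=schedule.stimulus_duration_s,
        )
        t5 = trace_for_interval(stack, well_map, 5.0)
        t60 = trace_for_interval(stack, well_map, 60.0)
        tbl = epoch_metrics_table(t5, t60, sub_schedule, plate_id=well_map.plate_id,
                                  adulthood_start_h=adulthood_start_h)
        tbl["epoch_index"] = e
        chunks.append(tbl)
    metrics = pd.concat(chunks, ignore_index=True)
    end_h = float(schedule.epoch_starts[-1] + schedule.epoch_duration_s) / 3600.0
    censor = set(manual_censor or set())
    censor |= {int(w) for w in np.flatnonzero(well_map.censor_mask)}
    records = build_worm_records(metrics, end_h, strain=strain,
                                 activity_floor=activity_floor,
                                 manual_censor=censor)
    return AnalysisResult(metrics, records, schedule, well_map)


def analyze_recording(
    stack: FrameStack,
    well_map: WellMap,
    schedule: EpochSchedule,
    **kw,
) -> AnalysisResult:
    """Analyze a single contiguous stack by splitting it at epoch boundaries."""
    def _epochs():
        for e in range(schedule.n_epochs):
            t0, t1 = schedule.epoch_window(e)
            yield stack.select(t0, t1)

    return analyze_epoch_stacks(_epochs(), well_map, schedule, **kw)


def analyze_simulated(sim, seed: int | None = None, **kw) -> AnalysisResult:
    """Render a simulation epoch-by-epoch and push it through the pipeline."""
    from .simulate import render_epochs

    config = sim.config
    return analyze_epoch_stacks(
        render_epochs(sim, seed=seed), config.well_map(), config.schedule(), **kw
    )
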