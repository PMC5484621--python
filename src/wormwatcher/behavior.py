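"""Per-epoch behavioral metrics around blue-light stimuli.

A recording is organized into 30-minute imaging *epochs* taken twice daily;
fifteen minutes into each epoch a 10-s blue-light stimulus evokes an escape
response.  From the 60-s and 5-s activity traces of an epoch we compute:

* **spontaneous locomotion** — maximum 60-s activity before the stimulus;
* **stimulated locomotion** — maximum 60-s activity after the stimulus;
* **response duration** — total post-stimulus time with nonzero 5-s
  activity (a multiple of the 5-s sampling step);
* **response latency** — delay from the *end* of the stimulus to the start
  of the first frame pair with nonzero 5-s activity; animals that never
  move in the 15-minute post-stimulus window receive the sentinel 900 s
  (not a missing value — the sentinel is what makes population latency
  curves well defined).

Frame pairs that straddle the stimulus window are excluded from every
metric: the bright flash corrupts differencing, so those pairs measure the
illumination change rather than the animal.

Continuous mode (used for acute-stress recordings) has no epoch structure;
stimuli recur at a fixed period and stimulated activity is the maximum 60-s
activity between consecutive stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import ActivityTrace
from .errors import ConfigurationError, InvalidEpochError

__all__ = [
    "EpochSchedule",
    "spontaneous_and_stimulated",
    "response_duration",
    "response_latency",
    "continuous_stimulated",
    "epoch_metrics_table",
    "windowed_means",
    "survivor_population_curve",
]


@dataclass
class EpochSchedule:
    """Epoch and stimulus timing for a recording.

    ``epoch_starts`` are absolute seconds.  In ``"epoch"`` mode each epoch
    lasts ``epoch_duration_s`` with a stimulus at ``stimulus_onset_s`` after
    epoch start.  In ``"continuous"`` mode frames run without gaps and
    stimuli recur every ``continuous_stim_period_s`` starting at
    ``epoch_starts[0]``.
    """

    epoch_starts: np.ndarray
    epoch_duration_s: float = 1800.0
    stimulus_onset_s: float = 900.0
    stimulus_duration_s: float = 10.0
    mode: str = "epoch"
    continuous_stim_period_s: float = 3600.0

    def __post_init__(self) -> None:
        self.epoch_starts = np.atleast_1d(np.asarray(self.epoch_starts, dtype=float))
        if self.mode not in ("epoch", "continuous"):
            raise ConfigurationError(f"unknown schedule mode {self.mode!r}")
        if self.stimulus_onset_s + self.stimulus_duration_s >= self.epoch_duration_s:
            raise ConfigurationError("stimulus must end before the epoch does")
        starts = np.sort(self.epoch_starts)
        if self.mode == "epoch" and np.any(np.diff(starts) < self.epoch_duration_s):
            raise ConfigurationError("epochs overlap given epoch_duration_s")

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_starts)

    @classmethod
    def twice_daily(
        cls, n_epochs: int, first_start_s: float = 0.0, period_s: float = 43200.0, **kw
    ) -> "EpochSchedule":
        """The standard intermittent protocol: one epoch every 12 h."""
        return cls(first_start_s + period_s * np.arange(n_epochs), **kw)

    # -- window helpers (absolute seconds) --------------------------------
    def epoch_window(self, epoch_index: int) -> tuple[float, float]:
        t0 = float(self.epoch_starts[epoch_index])
        return t0, t0 + self.epoch_duration_s

    def stimulus_window(self, epoch_index: int) -> tuple[float, float]:
        t0 = float(self.epoch_starts[epoch_index]) + self.stimulus_onset_s
        return t0, t0 + self.stimulus_duration_s

    @property
    def post_window_s(self) -> float:
        """Nominal post-stimulus observation window (the latency sentinel)."""
        return self.epoch_duration_s - self.stimulus_onset_s

    def stimulus_onsets(self, recording_end_s: float) -> np.ndarray:
        """Stimulus onset times for continuous mode."""
        if self.mode != "continuous":
            raise ConfigurationError("stimulus_onsets is for continuous mode")
        t0 = float(self.epoch_starts[0]) + self.stimulus_onset_s
        return np.arange(t0, recording_end_s, self.continuous_stim_period_s)

    def epoch_days(self, adulthood_start_h: float = 0.0) -> np.ndarray:
        """Day-of-adulthood label per epoch: day d covers [24(d-1), 24d) hours."""
        hours = self.epoch_starts / 3600.0 - adulthood_start_h
        return np.floor(hours / 24.0).astype(int) + 1


def _select(
    trace: ActivityTrace, t0: float, t1: float, end_exclusive: bool = False
) -> np.ndarray:
    """Boolean mask of pairs lying entirely inside the window.

    Pre-stimulus windows use ``end_exclusive=True``: the frame captured at
    stimulus onset already carries the flash, so a pair ending exactly at
    onset measures the illumination change and must not count.
    """
    upper = trace.pair_ends < t1 if end_exclusive else trace.pair_ends <= t1
    return (trace.pair_starts >= t0) & upper


def spontaneous_and_stimulated(
    trace60: ActivityTrace, schedule: EpochSchedule, epoch_index: int
) -> tuple[int, int]:
    """(max 60-s activity before stimulus, max 60-s activity after stimulus).

    Pairs overlapping the stimulus window contribute to neither maximum.
    An epoch with no pre- or no post-stimulus pairs is invalid
    (:class:`InvalidEpochError`): the max of an empty set is an error, not 0.
    """
    if trace60.interval_s != 60:
        raise ValueError("spontaneous/stimulated locomotion uses the 60-s trace")
    e0, e1 = schedule.epoch_window(epoch_index)
    s0, s1 = schedule.stimulus_window(epoch_index)
    pre = _select(trace60, e0, s0, end_exclusive=True)
    post = _select(trace60, s1, e1)
    if not pre.any() or not post.any():
        raise InvalidEpochError(f"epoch {epoch_index}: missing pre- or post-stimulus pairs")
    return int(trace60.values[pre].max()), int(trace60.values[post].max())


def response_duration(
    trace5: ActivityTrace, schedule: EpochSchedule, epoch_index: int
) -> float:
    """Total post-stimulus time (s) with nonzero 5-s activity."""
    if trace5.interval_s != 5:
        raise ValueError("response duration uses the 5-s trace")
    _, e1 = schedule.epoch_window(epoch_index)
    _, s1 = schedule.stimulus_window(epoch_index)
    post = _select(trace5, s1, e1)
    if not post.any():
        raise InvalidEpochError(f"epoch {epoch_index}: no post-stimulus 5-s pairs")
    return float(np.count_nonzero(trace5.values[post] > 0) * trace5.interval_s)


def response_latency(
    trace5: ActivityTrace, schedule: EpochSchedule, epoch_index: int
) -> float:
    """Seconds from stimulus end to the start of the first moving 5-s pair.

    Resolution equals the 5-s sampling step.  With no movement anywhere in
    the post-stimulus window the sentinel — the nominal window length,
    900 s under the standard schedule — is returned exactly.
    """
    if trace5.interval_s != 5:
        raise ValueError("response latency uses the 5-s trace")
    _, e1 = schedule.epoch_window(epoch_index)
    _, s1 = schedule.stimulus_window(epoch_index)
    post = _select(trace5, s1, e1)
    if not post.any():
        raise InvalidEpochError(f"epoch {epoch_index}: no post-stimulus 5-s pairs")
    starts = trace5.pair_starts[post]
    values = trace5.values[post]
    moving = values > 0
    if not moving.any():
        return float(schedule.post_window_s)
    return float(starts[moving][0] - s1)


def continuous_stimulated(
    trace60: ActivityTrace,
    schedule: EpochSchedule,
    recording_end_s: float | None = None,
) -> pd.DataFrame:
    """Per-interstimulus-interval stimulated activity (continuous mode).

    One row per complete interval between consecutive stimuli: the maximum
    60-s activity among pairs lying in ``(stim_i end, stim_{i+1} onset]``.
    Intervals with no pairs yield NaN.
    """
    if trace60.interval_s != 60:
        raise ValueError("continuous stimulated activity uses the 60-s trace")
    end = recording_end_s if recording_end_s is not None else float(trace60.pair_ends[-1])
    onsets = schedule.stimulus_onsets(end)
    if len(onsets) < 2:
        raise InvalidEpochError("continuous mode needs at least two stimuli")
    rows = []
    for k in range(len(onsets) - 1):
        lo = onsets[k] + schedule.stimulus_duration_s
        hi = onsets[k + 1]
        sel = _select(trace60, lo, hi, end_exclusive=True)
        rows.append(
            {
                "interval_index": k,
                "t_start_s": lo,
                "t_end_s": hi,
                "stimulated": float(trace60.values[sel].max()) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


METRIC_COLUMNS = ["spontaneous", "stimulated", "duration_s", "latency_s"]


def epoch_metrics_table(
    traces5: list[ActivityTrace],
    traces60: list[ActivityTrace],
    schedule: EpochSchedule,
    plate_id: str = "plate",
    adulthood_start_h: float = 0.0,
) -> pd.DataFrame:
    """Tidy per-well, per-epoch metrics table.

    Columns: ``plate_id, well_index, epoch_index, time_h, day, spontaneous,
    stimulated, duration_s, latency_s, valid``.  Epochs whose traces lack
    the required windows are kept with NaN metrics and ``valid=False``.
    """
    days = schedule.epoch_days(adulthood_start_h)
    by_well5 = {t.well_index: t for t in traces5}
    by_well60 = {t.well_index: t for t in traces60}
    rows = []
    for w in sorted(by_well60):
        t5, t60 = by_well5[w], by_well60[w]
        for e in range(schedule.n_epochs):
            row = {
                "plate_id": plate_id,
                "well_index": w,
                "epoch_index": e,
                "time_h": float(schedule.epoch_starts[e]) / 3600.0,
                "day": int(days[e]),
            }
            try:
                spont, stim = spontaneous_and_stimulated(t60, schedule, e)
                row.update(
                    spontaneous=spont,
                    stimulated=stim,
                    duration_s=response_duration(t5, schedule, e),
                    latency_s=response_latency(t5, schedule, e),
                    valid=True,
                )
            except InvalidEpochError:
                row.update(
                    spontaneous=np.nan, stimulated=np.nan,
                    duration_s=np.nan, latency_s=np.nan, valid=False,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def windowed_means(
    metrics: pd.DataFrame,
    day_windows: list[tuple[int, int]],
    death_times_h: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Per-animal mean of each metric over day-of-adulthood windows.

    Windows are inclusive on both ends (days "1–10" means day 1 through day
    10).  When death times are supplied, epochs at or after an animal's
    death are excluded, and an animal dead before a window opens yields NaN
    for that window — an empty window is missing, never 0.
    """
    rows = []
    for well, sub in metrics.groupby("well_index"):
        sub = sub[sub["valid"]] if "valid" in sub.columns else sub
        death = None if death_times_h is None else death_times_h.get(int(well))
        for lo, hi in day_windows:
            sel = sub[(sub["day"] >= lo) & (sub["day"] <= hi)]
            if death is not None:
                sel = sel[sel["time_h"] < death]
            row = {"well_index": int(well), "window": f"{lo}-{hi}"}
            for col in METRIC_COLUMNS:
                row[col] = float(sel[col].mean()) if len(sel) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def survivor_population_curve(
    metrics: pd.DataFrame, records
) -> pd.DataFrame:
    """Mean metrics at each epoch over the animals still alive then.

    ``records`` is an iterable of :class:`~wormwatcher.lifespan.WormRecord`.
    Censored animals never contribute.  The curve ends at the last epoch
    with at least one survivor.
    """
    death = {r.well_index: r.death_time_h for r in records if not r.censored}
    rows = []
    for (e, t_h), sub in metrics.groupby(["epoch_index", "time_h"]):
        sub = sub[sub["valid"]] if "valid" in sub.columns else sub
        alive = sub[sub["well_index"].map(lambda w: death.get(w, -np.inf) > t_h)]
        if len(alive) == 0:
            continue
        row = {"epoch_index": int(e), "time_h": float(t_h), "n_alive": len(alive)}
        for col in METRIC_COLUMNS:
            row[col] = float(alive[col].mean())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("time_h", ignore_index=True)
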