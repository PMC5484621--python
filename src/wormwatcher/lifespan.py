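"""Automated lifespan calling, censoring, and survival statistics.

Death is called from the post-stimulus activity record: the time of death
is the epoch time immediately after the last epoch whose maximum
post-stimulus 60-s activity was nonzero.  This rule can only ever call
death at or before the first daily manual observation of death, which is
why automated lifespans are never longer than manual ones.

Censoring rules, applied *before* death calling:

* a well whose activity (spontaneous and stimulated) is uniformly zero from
  day 2 of adulthood onward is assumed empty or escaped and censored with
  reason ``zero_from_day2`` — it never receives a death time;
* an animal still moving in the final epoch is right-censored at recording
  end (``alive_at_end``);
* known escapees may be censored via an external list (reason ``manual``).

Survival curves are Kaplan–Meier estimates (censored animals removed at
their censor time); mean ± SD lifespan is reported over uncensored deaths,
and groups are compared with a two-sided Wilcoxon rank-sum test on death
times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "WormRecord",
    "call_death",
    "censor_inactive",
    "build_worm_records",
    "survival_curve",
    "compare_survival",
    "auto_vs_manual",
    "SurvivalCurve",
    "SurvivalComparison",
]


@dataclass
class WormRecord:
    """Per-animal outcome: death time or censoring, plus linked metrics."""

    well_index: int
    strain: str = ""
    death_time_h: float | None = None
    censored: bool = False
    censor_reason: str | None = None  # "zero_from_day2" | "alive_at_end" | "manual"
    censor_time_h: float | None = None
    epoch_metrics: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.censored == (self.death_time_h is not None):
            raise ValueError("record must have a death time XOR be censored")


def call_death(
    post_stimulus_activity: np.ndarray,
    epoch_times_h: np.ndarray,
    activity_floor: float = 0.0,
) -> tuple[float | None, str | None]:
    """Apply the death-call rule to a per-epoch post-stimulus activity series.

    Returns ``(death_time_h, None)`` on a death call, or ``(None, reason)``
    when the animal is alive at the end of the recording.  "Nonzero" means
    strictly greater than ``activity_floor`` (default 0 — the 0.25
    differencing threshold already suppresses pixel noise, so no extra
    floor is needed under the default noise model).

    The death time is the epoch time immediately after the last nonzero
    epoch; a series that is zero throughout yields death at the first epoch
    time (such wells are normally intercepted by :func:`censor_inactive`
    first).
    """
    values = np.asarray(post_stimulus_activity, dtype=float)
    times = np.asarray(epoch_times_h, dtype=float)
    if values.size == 0:
        raise ValueError("empty activity series")
    if values.shape != times.shape:
        raise ValueError("one epoch time per activity value required")
    nonzero = np.flatnonzero(values > activity_floor)
    if nonzero.size == 0:
        return float(times[0]), None
    last = int(nonzero[-1])
    if last == len(values) - 1:
        return None, "alive_at_end"
    return float(times[last + 1]), None


def censor_inactive(metrics: pd.DataFrame) -> set[int]:
    """Wells to censor under the day-2 zero-activity rule.

    A well is censored when every epoch from day 2 of adulthood onward has
    zero spontaneous *and* zero stimulated activity (a well that is zero on
    day 1 as well still qualifies).  Wells with no epochs on day >= 2 are
    not judged.
    """
    censored: set[int] = set()
    for well, sub in metrics.groupby("well_index"):
        late = sub[sub["day"] >= 2]
        if len(late) == 0:
            continue
        spont = late["spontaneous"].fillna(0)
        stim = late["stimulated"].fillna(0)
        if (spont == 0).all() and (stim == 0).all():
            censored.add(int(well))
    return censored


def build_worm_records(
    metrics: pd.DataFrame,
    recording_end_h: float,
    strain: str = "",
    activity_floor: float = 0.0,
    manual_censor: set[int] | None = None,
) -> list[WormRecord]:
    """Censor, then call death, for every well in an epoch-metrics table.

    Censoring precedence: manual censor list, then the day-2 rule, then
    death calling (with alive-at-end right-censoring).
    """
    manual_censor = manual_censor or set()
    day2_censored = censor_inactive(metrics)
    records = []
    for well, sub in metrics.groupby("well_index"):
        sub = sub.sort_values("time_h")
        well = int(well)
        kw = dict(well_index=well, strain=strain, epoch_metrics=sub.reset_index(drop=True))
        if well in manual_censor:
            records.append(
                WormRecord(censored=True, censor_reason="manual",
                           censor_time_h=float(sub["time_h"].iloc[0]), **kw)
            )
            continue
        if well in day2_censored:
            active = sub[(sub["spontaneous"].fillna(0) > 0) | (sub["stimulated"].fillna(0) > 0)]
            t_cens = float(active["time_h"].iloc[-1]) if len(active) else float(sub["time_h"].iloc[0])
            records.append(
                WormRecord(censored=True, censor_reason="zero_from_day2",
                           censor_time_h=t_cens, **kw)
            )
            continue
        death, reason = call_death(
            sub["stimulated"].fillna(0).to_numpy(),
            sub["time_h"].to_numpy(),
            activity_floor=activity_floor,
        )
        if death is None:
            records.append(
                WormRecord(censored=True, censor_reason=reason,
                           censor_time_h=recording_end_h, **kw)
            )
        else:
            records.append(WormRecord(death_time_h=death, **kw))
    return records


@dataclass
class SurvivalCurve:
    """Kaplan–Meier estimate with the summary stats reported alongside."""

    label: str
    table: pd.DataFrame  # time_h, fraction_alive, n_at_risk
    mean_lifespan_h: float
    sd_lifespan_h: float
    n_deaths: int
    n_censored: int


def survival_curve(records: list[WormRecord], group_label: str = "") -> SurvivalCurve:
    """Kaplan–Meier survival estimate for a group of records.

    Censored animals are removed (at risk until) their censor time; mean ±
    SD lifespan is computed over uncensored deaths only.
    """
    durations, observed = [], []
    deaths = []
    for r in records:
        if r.censored:
            if r.censor_time_h is not None:
                durations.append(r.censor_time_h)
                observed.append(0)
        else:
            durations.append(r.death_time_h)
            observed.append(1)
            deaths.append(r.death_time_h)
    if not deaths:
        raise InsufficientDataError("no uncensored deaths in group")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed, label=group_label or "S")
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index)
    table = pd.DataFrame(
        {
            "time_h": sf.index.to_numpy(dtype=float),
            "fraction_alive": sf.iloc[:, 0].to_numpy(),
            "n_at_risk": at_risk.to_numpy(),
        }
    )
    deaths = np.asarray(deaths, dtype=float)
    sd = float(deaths.std(ddof=1)) if len(deaths) > 1 else 0.0
    return SurvivalCurve(
        label=group_label,
        table=table,
        mean_lifespan_h=float(deaths.mean()),
        sd_lifespan_h=sd,
        n_deaths=len(deaths),
        n_censored=sum(r.censored for r in records),
    )


@dataclass
class SurvivalComparison:
    group_a: str
    group_b: str
    mean_a_h: float
    sd_a_h: float
    mean_b_h: float
    sd_b_h: float
    statistic: float
    p_value: float


def compare_survival(
    group_a: list[WormRecord], group_b: list[WormRecord],
    label_a: str = "A", label_b: str = "B",
) -> SurvivalComparison:
    """Two-sided Wilcoxon rank-sum test on uncensored death times.

    Uses the exact null distribution at small sample sizes without ties and
    the tie-corrected normal approximation otherwise.  Requires at least
    three uncensored deaths per group.
    """
    a = np.array([r.death_time_h for r in group_a if not r.censored], dtype=float)
    b = np.array([r.death_time_h for r in group_b if not r.censored], dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError("need >= 3 uncensored deaths per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return SurvivalComparison(
        group_a=label_a, group_b=label_b,
        mean_a_h=float(a.mean()), sd_a_h=float(a.std(ddof=1)),
        mean_b_h=float(b.mean()), sd_b_h=float(b.std(ddof=1)),
        statistic=float(res.statistic), p_value=float(res.pvalue),
    )


def auto_vs_manual(
    auto_death_times: np.ndarray, manual_death_times: np.ndarray
) -> dict:
    """Audit automated against paired manual death calls.

    Returns the mean and SD of ``manual - auto`` and the indices of any
    pairs where the automated call exceeds the manual one — which the
    death-call rule should never produce, since an animal can only be
    scored dead automatically once it has stopped moving.
    """
    auto = np.asarray(auto_death_times, dtype=float)
    manual = np.asarray(manual_death_times, dtype=float)
    if auto.shape != manual.shape:
        raise ValueError("auto and manual death times must be paired")
    diff = manual - auto
    sd = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
    return {
        "n": int(len(diff)),
        "mean_diff_h": float(diff.mean()),
        "sd_diff_h": sd,
        "violations": np.flatnonzero(diff < 0),
    }
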