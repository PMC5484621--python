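"""Life-fraction behavioral-decline analysis.

To compare the *shape* of aging across individuals with different
lifespans, each animal's stimulated-activity trajectory is re-expressed on
a life-fraction axis (time divided by that individual's death time, so 1.0
is death) and linearly interpolated onto a common uniform grid.  Two
ordinary-least-squares fits summarize the trajectory:

* **early-life decline rate** — negative slope over 20–60% of life;
* **late-life decline rate** — negative slope over 60–100% of life;
* **change in decline rate** — late minus early, in pixels per life
  fraction.

A negative change means the animal declined early then plateaued
("decline and plateau", the extended-twilight signature); zero change
means a straight-line decline.  Under pure temporal scaling every
individual shares one fraction-space template, the change in decline rate
is constant across animals, and it cannot correlate with lifespan — so the
correlation of rate change with lifespan discriminates the two aging
models.

The aging-vs-stress comparison offsets the stress curve by the mean
difference (activity amplitude correction) and reports the mean normalized
absolute difference across the fraction grid as a percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "DEFAULT_FRACTION_GRID",
    "FractionCurve",
    "to_life_fraction",
    "decline_rates",
    "decline_summaries",
    "rate_change_vs_lifespan",
    "quartile_curves",
    "compare_aging_vs_stress",
    "strain_level_stats",
]

logger = logging.getLogger(__name__)

#: 50 uniform life-fraction bins of width 0.02 ending at death (1.0)
DEFAULT_FRACTION_GRID = np.round(np.linspace(0.02, 1.0, 50), 10)

EARLY_WINDOW = (0.2, 0.6)
LATE_WINDOW = (0.6, 1.0)


@dataclass
class FractionCurve:
    """Mean activity per life-fraction bin with per-bin sample sizes."""

    fraction_grid: np.ndarray
    values: np.ndarray
    n_per_bin: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.fraction_grid, dtype=float)
        if np.any(np.diff(g) <= 0) or g[0] < 0 or g[-1] > 1:
            raise ValueError("fraction grid must be strictly increasing within [0, 1]")
        self.fraction_grid = g
        self.values = np.asarray(self.values, dtype=float)
        self.n_per_bin = np.asarray(self.n_per_bin)


def to_life_fraction(
    times_h: np.ndarray,
    values: np.ndarray,
    lifespan_h: float,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Interpolate an activity series onto the common life-fraction grid.

    Each sample time maps to ``time / lifespan``; values are linearly
    interpolated onto ``grid`` with NaN outside the observed fraction range
    (no extrapolation).  Interpolation is exact for affine trajectories.
    Fewer than two observed samples is an error; batch callers should skip
    such animals with a log entry.
    """
    if lifespan_h <= 0:
        raise ValueError("lifespan must be positive")
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(v) & (t <= lifespan_h)
    t, v = t[keep], v[keep]
    if len(t) < 2:
        raise InsufficientDataError("need >= 2 observed epochs for a fraction curve")
    frac = t / lifespan_h
    grid = DEFAULT_FRACTION_GRID if grid is None else np.asarray(grid, dtype=float)
    out = np.interp(grid, frac, v)
    out[(grid < frac[0]) | (grid > frac[-1])] = np.nan
    return out


@dataclass
class DeclineRates:
    early_rate: float
    late_rate: float

    @property
    def rate_change(self) -> float:
        return self.late_rate - self.early_rate


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    # closed-form OLS; exact (to machine precision) on collinear input
    xm, ym = x.mean(), y.mean()
    return float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())


def decline_rates(
    fraction_values: np.ndarray,
    grid: np.ndarray | None = None,
    early_window: tuple[float, float] = EARLY_WINDOW,
    late_window: tuple[float, float] = LATE_WINDOW,
) -> DeclineRates | None:
    """Early and late decline rates of one fraction-gridded trajectory.

    The decline rate is the *negative* OLS slope of activity against life
    fraction within the window, so declining activity gives a positive
    rate.  Returns ``None`` (summary omitted) when either window has fewer
    than two finite points.
    """
    grid = DEFAULT_FRACTION_GRID if grid is None else np.asarray(grid, dtype=float)
    v = np.asarray(fraction_values, dtype=float)
    rates = []
    for lo, hi in (early_window, late_window):
        sel = (grid >= lo) & (grid <= hi) & np.isfinite(v)
        if sel.sum() < 2:
            return None
        rates.append(-_ols_slope(grid[sel], v[sel]))
    return DeclineRates(early_rate=rates[0], late_rate=rates[1])


def decline_summaries(
    stim_series: dict[int, tuple[np.ndarray, np.ndarray]],
    lifespans_h: dict[int, float],
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-animal decline summary table.

    ``stim_series`` maps well index to ``(times_h, stimulated_values)``;
    ``lifespans_h`` supplies each animal's (automated) death time, which
    defines fraction 1.0.  Only epochs strictly before death enter the fit:
    the called death time is the first epoch at which the animal no longer
    moved, so the activity recorded there is structurally zero rather than
    behavior, and including it would bias the late-life slope sharply
    downward for every animal.  Animals without a lifespan (censored) or
    with insufficient samples are skipped with a log entry.
    """
    rows = []
    for well, (t, v) in stim_series.items():
        L = lifespans_h.get(well)
        if L is None:
            continue
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        alive = t < L
        try:
            fv = to_life_fraction(t[alive], v[alive], L, grid=grid)
        except InsufficientDataError:
            logger.info("well %s excluded from decline analysis: too few epochs", well)
            continue
        rates = decline_rates(fv, grid=grid)
        if rates is None:
            logger.info("well %s excluded from decline analysis: sparse fit window", well)
            continue
        rows.append(
            {
                "well_index": well,
                "lifespan_h": float(L),
                "early_rate": rates.early_rate,
                "late_rate": rates.late_rate,
                "rate_change": rates.rate_change,
            }
        )
    return pd.DataFrame(rows)


def rate_change_vs_lifespan(
    summaries: pd.DataFrame, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation (R, p) between per-animal rate change and lifespan."""
    if len(summaries) < 4:
        raise InsufficientDataError("need >= 4 decline summaries")
    x = summaries["rate_change"].to_numpy(dtype=float)
    y = summaries["lifespan_h"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in rate change or lifespan")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass
class QuartileCurves:
    """Mean trajectories for the shortest- and longest-lived quartiles."""

    low_wells: list[int]
    high_wells: list[int]
    low_fraction: FractionCurve
    high_fraction: FractionCurve
    low_chrono: pd.DataFrame  # time_h, mean, n
    high_chrono: pd.DataFrame


def _mean_fraction_curve(curves: list[np.ndarray], grid: np.ndarray) -> FractionCurve:
    arr = np.vstack(curves)
    n = np.isfinite(arr).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(arr, axis=0)
    return FractionCurve(grid, mean, n)


def _mean_chrono_curve(series: list[tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    frames = [pd.Series(v, index=np.round(t, 6)) for t, v in series]
    tbl = pd.concat(frames, axis=1)
    return pd.DataFrame(
        {"time_h": tbl.index.to_numpy(), "mean": tbl.mean(axis=1).to_numpy(),
         "n": tbl.notna().sum(axis=1).to_numpy()}
    ).reset_index(drop=True)


def quartile_curves(
    stim_series: dict[int, tuple[np.ndarray, np.ndarray]],
    lifespans_h: dict[int, float],
    grid: np.ndarray | None = None,
) -> QuartileCurves:
    """Mean stimulated-activity trajectories of the extreme lifespan quartiles.

    Animals are ranked by lifespan (ties broken deterministically by well
    index); the lowest and highest ``ceil(n/4)`` form the quartile groups.
    Requires at least eight animals with lifespans.
    """
    wells = sorted(w for w in stim_series if w in lifespans_h)
    if len(wells) < 8:
        raise InsufficientDataError("quartile curves need >= 8 uncensored animals")
    order = sorted(wells, key=lambda w: (lifespans_h[w], w))
    q = int(np.ceil(len(order) / 4))
    low, high = order[:q], order[-q:]
    grid = DEFAULT_FRACTION_GRID if grid is None else np.asarray(grid, dtype=float)

    def frac_curves(group):
        return [to_life_fraction(*stim_series[w], lifespans_h[w], grid=grid) for w in group]

    def chrono(group):
        out = []
        for w in group:
            t, v = stim_series[w]
            keep = t < lifespans_h[w]
            out.append((t[keep], np.asarray(v, dtype=float)[keep]))
        return out

    return QuartileCurves(
        low_wells=low,
        high_wells=high,
        low_fraction=_mean_fraction_curve(frac_curves(low), grid),
        high_fraction=_mean_fraction_curve(frac_curves(high), grid),
        low_chrono=_mean_chrono_curve(chrono(low)),
        high_chrono=_mean_chrono_curve(chrono(high)),
    )


def compare_aging_vs_stress(aging, stress) -> float:
    """Percentage difference between aging and stress decline curves.

    Both curves must live on the same fraction grid.  The stress curve is
    first offset-corrected by the mean difference (so any constant shift is
    removed exactly); the per-bin normalized difference is
    ``|aging - corrected stress| / mean(aging)`` — normalizing by the grand
    mean of the aging curve rather than per-bin values, which would blow up
    near death where activity approaches zero — and the result is 100x the
    mean over bins.
    """
    a = aging.values if isinstance(aging, FractionCurve) else np.asarray(aging, dtype=float)
    s = stress.values if isinstance(stress, FractionCurve) else np.asarray(stress, dtype=float)
    if a.shape != s.shape:
        raise ValueError("curves must share a fraction grid")
    keep = np.isfinite(a) & np.isfinite(s)
    if not keep.any():
        raise ValueError("no overlapping bins")
    a, s = a[keep], s[keep]
    scale = a.mean()
    if scale == 0:
        raise ValueError("aging curve has zero mean; normalized difference undefined")
    offset = (a - s).mean()
    corrected = s + offset
    return float(100.0 * (np.abs(a - corrected) / scale).mean())


def strain_level_stats(summaries_by_strain: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-strain mean/SD of rate change against mean lifespan.

    Reuses the per-animal machinery at the strain level: the returned table
    can be fed to :func:`rate_change_vs_lifespan` (with ``rate_change`` set
    to the strain mean or SD) to test whether the shape of decline tracks
    lifespan across strains as well as across individuals.
    """
    rows = []
    for strain, df in summaries_by_strain.items():
        rows.append(
            {
                "strain": strain,
                "n": len(df),
                "mean_lifespan_h": float(df["lifespan_h"].mean()),
                "mean_rate_change": float(df["rate_change"].mean()),
                "sd_rate_change": float(df["rate_change"].std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)
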