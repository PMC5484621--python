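"""Figure helpers: activity heat maps and survival curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["activity_heatmap", "plot_survival"]


def activity_heatmap(metrics: pd.DataFrame, column: str = "stimulated", ax=None,
                     sort_by_lifespan: dict | None = None):
    """Wells x epochs heat map of a metric (one row per animal)."""
    pivot = metrics.pivot_table(index="well_index", columns="time_h", values=column)
    if sort_by_lifespan:
        order = sorted(pivot.index, key=lambda w: sort_by_lifespan.get(w, np.inf))
        pivot = pivot.loc[order]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", interpolation="nearest",
                   extent=(pivot.columns.min(), pivot.columns.max(), len(pivot), 0))
    ax.set_xlabel("time (h)")
    ax.set_ylabel("animal")
    plt.colorbar(im, ax=ax, label=f"{column} (px)")
    return ax


def plot_survival(curves, ax=None):
    """Step plot of one or more Kaplan-Meier survival curves."""
    if ax is None:
        _, ax = plt.subplots()
    for c in np.atleast_1d(curves):
        ax.step(c.table["time_h"] / 24.0, c.table["fraction_alive"], where="post",
                label=f"{c.label} (n={c.n_deaths}+{c.n_censored}c)")
    ax.set_xlabel("days of adulthood")
    ax.set_ylabel("fraction alive")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
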