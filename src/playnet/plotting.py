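"""Optional plotting helpers (matplotlib): notched boxplots per group and
age-trend scatter with a quadratic fit line and 68% prediction band.
Visualisation only — the statistical contract lives in
:mod:`playnet.cohort`."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["notched_boxplot", "age_trend_plot"]


def notched_boxplot(table: pd.DataFrame, metric: str, group_col: str = "group", ax=None):
    """Notched boxplot of one metric per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    groups = sorted(table[group_col].dropna().unique())
    data = [table.loc[table[group_col] == g, metric].dropna() for g in groups]
    ax.boxplot(data, notch=True, tick_labels=[str(g) for g in groups])
    ax.set_ylabel(metric)
    ax.set_xlabel(group_col)
    return ax


def age_trend_plot(
    table: pd.DataFrame, metric: str, age_col: str = "age_months", ax=None
):
    """Scatter of a metric against age with an ordinary-least-squares
    quadratic fit and an illustrative 68% prediction interval."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = table[[age_col, metric]].dropna()
    x = sub[age_col].to_numpy(dtype=float)
    y = sub[metric].to_numpy(dtype=float)
    ax.scatter(x, y, s=12, alpha=0.6)
    if len(x) >= 4 and np.ptp(x) > 0:
        coef = np.polyfit(x, y, 2)
        xx = np.linspace(x.min(), x.max(), 100)
        yy = np.polyval(coef, xx)
        resid_sd = float(np.std(y - np.polyval(coef, x), ddof=3))
        ax.plot(xx, yy, color="k")
        ax.fill_between(xx, yy - resid_sd, yy + resid_sd, alpha=0.2, color="k")
    ax.set_xlabel("age (months)")
    ax.set_ylabel(metric)
    return ax
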