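"""Optional matplotlib helpers mirroring the study's figure layouts."""

from __future__ import annotations

import numpy as np
import pandas as pd


def heatmap(df: pd.DataFrame, metric: str, ax=None):
    """Heat map of one metric from a long-format sweep table, averaging
    over seeds.  Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    sub = df[df["metric"] == metric]
    pivot = sub.pivot_table(index="y", columns="x", values="value", aggfunc="mean")
    if ax is None:
        _, ax = plt.subplots()
    x_name = sub["x_name"].iloc[0]
    y_name = sub["y_name"].iloc[0]
    im = ax.pcolormesh(pivot.columns.values, pivot.index.values, pivot.values,
                       shading="nearest")
    ax.figure.colorbar(im, ax=ax, label=metric)
    ax.set_xlabel(f"{x_name} (nS)")
    ax.set_ylabel(f"{y_name} (nS)")
    return ax


def raster(raster_df: pd.DataFrame, ax=None, **scatter_kw):
    """Scatter raster from a :func:`~aeifnet.experiments.raster_export`
    table.  Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    kw = dict(s=1, marker=".", color="k")
    kw.update(scatter_kw)
    ax.scatter(raster_df["time_ms"] / 1000.0, raster_df["row"], **kw)
    ax.set_xlabel("t (s)")
    ax.set_ylabel("neuron")
    return ax
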