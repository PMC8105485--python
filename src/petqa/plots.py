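"""Plotting helpers: Bland-Altman and metric-trend figures."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compare import bland_altman


def bland_altman_plot(series_a, series_b, label_a: str = "A", label_b: str = "B", ax=None):
    """Scatter of pairwise differences against pair means with the bias and
    1.96 SD limits of agreement drawn as horizontal lines."""
    import matplotlib.pyplot as plt

    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    res = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, s=25, color="tab:blue")
    ax.axhline(res.bias, color="k", lw=1.2, label=f"bias {res.bias:.2f}")
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="k", ls="--", lw=1.0)
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_a} − {label_b}")
    ax.legend(frameon=False)
    return ax


def metric_trend_plot(metrics: pd.DataFrame, metric: str, ax=None):
    """Metric value per reconstruction (one line per sphere size where the
    metric is sphere-resolved)."""
    import matplotlib.pyplot as plt

    df = metrics[metrics["metric"] == metric]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    if df["sphere_diameter_mm"].notna().any():
        for d, grp in df.groupby("sphere_diameter_mm"):
            ax.plot(grp["recon"], grp["value"], marker="o", label=f"{d:g} mm")
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.plot(df["recon"], df["value"], marker="o", color="tab:red")
    ax.set_ylabel(metric)
    ax.tick_params(axis="x", rotation=75, labelsize=7)
    return ax
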