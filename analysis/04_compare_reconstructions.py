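#!/usr/bin/env python
"""Compare reconstructions against the FBP 5 mm reference.

Produces the difference table (reference − method, the study's sign
convention), Bland-Altman agreement between FBP 5 mm and each BSREM beta for
the sphere-resolved NEMA metrics, and per-group summary statistics
(mean/SD/median/CV%).  Tables go to results/; diagnostic figures to
scratch/figures.
"""

import os
import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

sys.path.insert(0, os.path.dirname(__file__))
from study_config import RESULTS_DIR  # noqa: E402

from petqa.compare import bland_altman, difference_vs_reference, summary_stats  # noqa: E402
from petqa.plots import bland_altman_plot, metric_trend_plot  # noqa: E402

FIG_DIR = "scratch/figures"


def main() -> None:
    metrics = pd.read_csv(os.path.join(RESULTS_DIR, "metrics.csv"))
    os.makedirs(FIG_DIR, exist_ok=True)

    diffs, exclusions = difference_vs_reference(metrics)
    diffs.to_csv(os.path.join(RESULTS_DIR, "differences_vs_FBP_5mm.csv"), index=False)
    print(f"difference table: {len(diffs)} rows; "
          f"{len(exclusions)} groups lacked the FBP_5mm reference")

    ba_rows = []
    nema = metrics[metrics.metric.isin(["contrast", "contrast_cold", "bv"])]
    for (dataset, metric), grp in nema.groupby(["dataset", "metric"]):
        piv = grp.pivot_table(index="sphere_diameter_mm", columns="recon", values="value")
        if "FBP_5mm" not in piv.columns:
            continue
        for col in sorted(c for c in piv.columns if c.startswith("QClear")):
            r = bland_altman(piv["FBP_5mm"].to_numpy(), piv[col].to_numpy())
            ba_rows.append({"dataset": dataset, "metric": metric,
                            "a": "FBP_5mm", "b": col, "bias": r.bias,
                            "abs_bias": abs(r.bias), "sd_diff": r.sd_diff,
                            "loa_low": r.loa_low, "loa_high": r.loa_high,
                            "n_pairs": r.n_pairs})
            ax = bland_altman_plot(piv["FBP_5mm"], piv[col], "FBP_5mm", col)
            ax.set_title(f"{dataset} {metric}")
            ax.figure.savefig(os.path.join(FIG_DIR, f"ba_{dataset}_{metric}_{col}.png"),
                              dpi=110, bbox_inches="tight")
            plt.close(ax.figure)
    ba = pd.DataFrame(ba_rows)
    ba.to_csv(os.path.join(RESULTS_DIR, "bland_altman.csv"), index=False)
    if not ba.empty:
        best = ba.loc[ba.groupby("metric").abs_bias.idxmin()]
        for _, row in best.iterrows():
            print(f"smallest |bias| for {row.metric}: {row.b} "
                  f"(bias {row.bias:.2f}, LoA [{row.loa_low:.2f}, {row.loa_high:.2f}])")

    rows = []
    for (dataset, metric, sphere), grp in metrics.groupby(
        ["dataset", "metric", "sphere_diameter_mm"], dropna=False
    ):
        if len(grp) < 2 or grp.value.mean() == 0:
            continue
        s = summary_stats(grp.value.to_numpy())
        rows.append({"dataset": dataset, "metric": metric,
                     "sphere_diameter_mm": sphere, "mean": round(s.mean, 3),
                     "sd": round(s.sd, 3), "median": round(s.median, 3),
                     "cv_percent": round(s.cv_percent, 1), "n": len(grp)})
    pd.DataFrame(rows).to_csv(os.path.join(RESULTS_DIR, "summary_stats.csv"), index=False)

    for metric in ("contrast", "bv", "fwhm_xy", "snr", "uniformity"):
        sub = metrics[metrics.metric == metric]
        if sub.empty:
            continue
        ax = metric_trend_plot(metrics, metric)
        ax.figure.savefig(os.path.join(FIG_DIR, f"trend_{metric}.png"),
                          dpi=110, bbox_inches="tight")
        plt.close(ax.figure)
    print(f"tables -> {RESULTS_DIR}; figures -> {FIG_DIR}")


if __name__ == "__main__":
    main()
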