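"""Publication-style summary plots of parameter trends across cohorts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_parameter_trends"]

_GROUP_ORDER_KEY = {"CTR 0m": -2.0, "CTR 120m": -1.0}


def _group_order(group: str) -> float:
    if group in _GROUP_ORDER_KEY:
        return _GROUP_ORDER_KEY[group]
    return float(group.split()[1].rstrip("m"))


def plot_parameter_trends(
    table: pd.DataFrame,
    parameters=("Srwi", "Shw", "Stdi"),
    out_path: str | Path = "trends.png",
) -> Path:
    """Mean +/- sd of each parameter per cohort, one panel per (param, channel)."""
    channels = sorted(table["channel"].unique())
    fig, axes = plt.subplots(
        len(parameters),
        len(channels),
        figsize=(3.2 * len(channels), 2.6 * len(parameters)),
        squeeze=False,
    )
    for i, param in enumerate(parameters):
        for j, ch in enumerate(channels):
            ax = axes[i][j]
            sub = table[(table["parameter"] == param) & (table["channel"] == ch)]
            g = sub.groupby("group")["value"].agg(["mean", "std"]).reset_index()
            g["order"] = g["group"].map(_group_order)
            g = g.sort_values("order")
            ax.errorbar(
                range(len(g)), g["mean"], yerr=g["std"], fmt="o-", capsize=3, ms=4
            )
            ax.set_xticks(range(len(g)))
            ax.set_xticklabels(g["group"], rotation=60, fontsize=7)
            if j == 0:
                ax.set_ylabel(param)
            if i == 0:
                ax.set_title(ch, fontsize=9)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
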