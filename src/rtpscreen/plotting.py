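"""Figure builders: dose-response panels, sigma-tau scatters, count bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

CONDITION_COLORS = {
    "none": "tab:blue",
    "RTP1S": "tab:red",
    "RTP2": "tab:green",
    "both": "tab:purple",
}


def dose_response_panel(
    summaries: pd.DataFrame, or_name: str, odorant: str, ax=None
):
    """Mean +/- SEM vs log10 concentration, one series per chaperone condition.

    The 0 µM baseline cannot sit on the log axis; it is drawn as a dashed
    reference level per condition instead.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    sub = summaries[
        (summaries["or_name"] == or_name) & (summaries["odorant"] == odorant)
    ]
    base = summaries[
        (summaries["or_name"] == or_name) & (summaries["concentration"] == 0)
    ]
    for cond, color in CONDITION_COLORS.items():
        series = sub[sub["rtp_condition"] == cond].sort_values("concentration")
        if len(series):
            conc_uM = series["concentration"] * 1e6
            ax.errorbar(
                np.log10(conc_uM),
                series["mean"],
                yerr=series["sem"],
                color=color,
                marker="o",
                markersize=3,
                capsize=2,
                label=cond,
            )
        base_row = base[base["rtp_condition"] == cond]
        if len(base_row):
            ax.axhline(base_row["mean"].iloc[0], color=color, lw=0.5, ls="--", alpha=0.5)
    ax.set_xlabel("log10 concentration (µM)")
    ax.set_ylabel("normalized activity")
    ax.set_title(f"{or_name} / {odorant}", fontsize=9)
    ax.legend(fontsize=6)
    return ax


def sigma_tau_scatter(points: pd.DataFrame, title: str = "", ax=None):
    """Scatter of valid interaction points with the sigma=1 line and diagonals.

    Diagonals sigma = tau and sigma = 1 - tau partition the hypo-addition
    region by the ordering of the mixture response against each single
    response. Axes are [0, 1] x [0, max(1.2, sigma_max)].
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    valid = points[points["valid"]]
    ax.scatter(valid["tau_rtp1s"], valid["sigma"], s=12, alpha=0.7, color="k")
    ax.axhline(1.0, color="gray", lw=1)
    ax.plot([0, 1], [0, 1], color="gray", lw=0.7, ls=":")
    ax.plot([0, 1], [1, 0], color="gray", lw=0.7, ls=":")
    ymax = max(1.2, float(valid["sigma"].max()) if len(valid) else 1.2)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, ymax)
    ax.set_xlabel(r"$\tau_{RTP1S}$")
    ax.set_ylabel(r"$\sigma$")
    if title:
        ax.set_title(title, fontsize=9)
    return ax


def localization_bars(
    summary: pd.DataFrame, comparisons: pd.DataFrame | None = None, ax=None
):
    """Star-annotated bar plot of counting-session means per compartment."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    x = np.arange(len(summary))
    ax.bar(
        x,
        summary["mean_count"],
        yerr=summary["sem"],
        capsize=3,
        color="lightsteelblue",
        edgecolor="k",
    )
    ax.set_xticks(x)
    ax.set_xticklabels(
        summary["condition"] + "\n" + summary["compartment"], fontsize=6
    )
    ax.set_ylabel("positive cells / session")
    if comparisons is not None:
        lookup = summary.reset_index(drop=True)
        top = float((summary["mean_count"] + summary["sem"]).max())
        h = top * 0.05
        level = top + h
        for _, row in comparisons.iterrows():
            if row["stars"] == "ns":
                continue
            ia = lookup.index[
                (lookup["condition"] == row["condition_a"])
                & (lookup["compartment"] == row["compartment"])
            ]
            ib = lookup.index[
                (lookup["condition"] == row["condition_b"])
                & (lookup["compartment"] == row["compartment"])
            ]
            if len(ia) and len(ib):
                xa, xb = ia[0], ib[0]
                ax.plot([xa, xa, xb, xb], [level, level + h, level + h, level], lw=0.8, c="k")
                ax.text((xa + xb) / 2, level + h, row["stars"], ha="center", fontsize=8)
                level += 2.5 * h
    return ax
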