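"""Markdown report assembly from a completed analysis directory."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd
import yaml

from . import plotting


def generate_report(analysis_dir: str | Path, out_path: str | Path) -> Path:
    """Render a single Markdown report with figures for one analysis run.

    Expects the tables written by :func:`rtpscreen.pipeline.write_results`.
    Figures (dose-response panels per receptor, sigma-tau scatters per
    receptor and per odorant, category table, dependence summary) are written
    as PNG next to the report.
    """
    analysis_dir = Path(analysis_dir)
    out_path = Path(out_path)
    figdir = out_path.parent / (out_path.stem + "_figures")
    figdir.mkdir(parents=True, exist_ok=True)

    summaries = pd.read_csv(analysis_dir / "response_summary.tsv", sep="\t")
    points = pd.read_csv(analysis_dir / "interaction_points.tsv", sep="\t")
    categories = pd.read_csv(analysis_dir / "receptor_categories.tsv", sep="\t")
    thresholds = pd.read_csv(analysis_dir / "thresholds.tsv", sep="\t")
    config = yaml.safe_load((analysis_dir / "config.yaml").read_text())
    dep_path = analysis_dir / "dependence.json"
    dependence = json.loads(dep_path.read_text()) if dep_path.exists() else None

    lines = ["# Screen analysis report", ""]
    lines += ["## Configuration", "", "```yaml", yaml.safe_dump(config).strip(), "```", ""]

    lines += ["## Dose-response curves", ""]
    or_names = sorted(
        summaries.loc[summaries["or_name"] != "pCI", "or_name"].unique()
    )
    for or_name in or_names:
        odorants = sorted(
            summaries.loc[
                (summaries["or_name"] == or_name) & (summaries["concentration"] > 0),
                "odorant",
            ].unique()
        )
        if not odorants:
            continue
        fig, axes = plt.subplots(
            1, len(odorants), figsize=(4 * len(odorants), 3), squeeze=False
        )
        for ax, odorant in zip(axes[0], odorants):
            plotting.dose_response_panel(summaries, or_name, odorant, ax=ax)
        fig.tight_layout()
        fname = figdir / f"dose_response_{or_name}.png"
        fig.savefig(fname, dpi=100)
        plt.close(fig)
        lines.append(f"![dose-response {or_name}]({fname.name})")
    lines.append("")

    lines += ["## Interaction scatter diagrams (sigma vs tau)", ""]
    for col, label in (("or_name", "receptor"), ("odorant", "odorant")):
        for name, group in points.groupby(col, sort=True):
            if not group["valid"].any():
                continue
            ax = plotting.sigma_tau_scatter(group, title=f"{label}: {name}")
            fname = figdir / f"sigma_tau_{label}_{name}.png"
            ax.figure.savefig(fname, dpi=100)
            plt.close(ax.figure)
            lines.append(f"![sigma-tau {name}]({fname.name})")
    lines.append("")

    lines += ["## Receptor categories", "", "```", categories.to_string(index=False), "```", ""]
    lines += ["## Detection thresholds", "", "```", thresholds.to_string(index=False), "```", ""]

    surface_path = analysis_dir / "surface_expression.tsv"
    if surface_path.exists():
        surface = pd.read_csv(surface_path, sep="\t")
        lines += ["## Cell-surface expression (fold over vector)", "", "```",
                  surface.to_string(index=False), "```", ""]

    coloc_path = analysis_dir / "colocalization_summary.tsv"
    if coloc_path.exists():
        summary = pd.read_csv(coloc_path, sep="\t")
        cmp_path = analysis_dir / "colocalization_comparisons.tsv"
        comparisons = pd.read_csv(cmp_path, sep="\t") if cmp_path.exists() else None
        ax = plotting.localization_bars(summary, comparisons)
        ax.figure.tight_layout()
        fname = figdir / "colocalization_bars.png"
        ax.figure.savefig(fname, dpi=100)
        plt.close(ax.figure)
        lines += ["## Colocalization counting sessions", "",
                  f"![colocalization]({fname.name})", ""]

    if dependence is not None:
        lines += [
            "## Interaction-mode dependence",
            "",
            f"- within-receptor dispersion: {dependence['by_or']['statistic']:.4f} "
            f"(p = {dependence['by_or']['p']:.4g})",
            f"- within-odorant dispersion: {dependence['by_odorant']['statistic']:.4f} "
            f"(p = {dependence['by_odorant']['p']:.4g})",
            f"- {dependence['interpretation']}",
            "",
        ]

    out_path.write_text("\n".join(lines))
    return out_path
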