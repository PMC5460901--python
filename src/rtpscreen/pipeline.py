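"""End-to-end orchestration: normalize -> curves -> interaction -> categories.

This is the programmatic counterpart of the command-line pipeline: one call
takes raw measurement + layout tables and a :class:`PipelineConfig` and
returns every analysis product as tidy tables, reusable from tests and
notebooks without touching the filesystem.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import dose_response, interaction, plate_model

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All analysis knobs in one serializable record.

    The config that produced a run is written verbatim into its output
    directory, so any result can be reproduced byte for byte.
    """

    normalization_scope: str = "per_batch"
    alpha: float = 0.05
    k_sem: float = 3.0
    eps: float = 1e-3
    tolerance: float = 0.05
    tau_cat: float = 0.65
    min_points: int = 2
    psi_mode: str = "baseline_subtracted"
    surface_threshold: float = 1.5
    n_perm: int = 999
    seed: int | None = None

    def activation_rule(self) -> dose_response.ActivationRule:
        return dose_response.ActivationRule(alpha=self.alpha, k_sem=self.k_sem)

    def interaction_config(self) -> interaction.InteractionConfig:
        return interaction.InteractionConfig(
            eps=self.eps,
            tolerance=self.tolerance,
            tau_cat=self.tau_cat,
            min_points=self.min_points,
            psi_mode=self.psi_mode,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass
class ScreenResult:
    """Every product of one screen analysis."""

    config: PipelineConfig
    normalized: pd.DataFrame = field(repr=False)
    summaries: pd.DataFrame = field(repr=False)
    curves: list = field(repr=False)
    thresholds: pd.DataFrame = field(repr=False)
    responsive: pd.DataFrame = field(repr=False)
    points: pd.DataFrame = field(repr=False)
    categories: pd.DataFrame = field(repr=False)
    dependence: dict | None = None


def analyze_screen(
    measurements,
    layout,
    config: PipelineConfig | None = None,
    run_dependence: bool = True,
) -> ScreenResult:
    """Run the full analysis on raw measurement + layout tables."""
    config = config or PipelineConfig()
    rule = config.activation_rule()
    icfg = config.interaction_config()

    ms = plate_model.read_measurements(
        measurements, layout, normalization_scope=config.normalization_scope
    )
    normalized = plate_model.normalize_activities(ms)
    summaries = plate_model.summarize_replicates(normalized)

    curves = dose_response.build_curves(summaries, normalized)
    thresholds = dose_response.threshold_table(
        [dose_response.detect_threshold(c, rule) for c in curves]
    )
    responsive = dose_response.responsive_ligand_matrix(summaries, rule=rule)

    pairs = interaction.build_response_pairs(summaries, icfg, rule)
    points = interaction.select_valid_points(pairs, icfg)
    categories = interaction.categorize_receptors(points, icfg)

    dependence = None
    if run_dependence:
        try:
            dependence = interaction.compare_dependence(
                points, n_perm=config.n_perm, seed=config.seed
            )
        except ValueError as exc:
            logger.warning("dependence analysis skipped: %s", exc)

    return ScreenResult(
        config=config,
        normalized=normalized,
        summaries=summaries,
        curves=curves,
        thresholds=thresholds,
        responsive=responsive,
        points=points,
        categories=categories,
        dependence=dependence,
    )


def analyze_expression(
    surface: pd.DataFrame | None = None,
    sessions: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Surface-expression and colocalization statistics, when data exist.

    ``surface`` needs (or_name, rtp_condition, luminescence) rows including
    pCI vector controls; ``sessions`` needs (condition, compartment, counted,
    positive_count). Paired comparisons cover every unordered pair of
    conditions per compartment.
    """
    from . import expression_stats

    config = config or PipelineConfig()
    out: dict[str, pd.DataFrame] = {}
    if surface is not None:
        means = surface.groupby(
            ["or_name", "rtp_condition"], as_index=False
        )["luminescence"].mean()
        out["surface"] = expression_stats.surface_table(
            means, threshold=config.surface_threshold
        )
    if sessions is not None:
        out["session_summary"] = expression_stats.summarize_sessions(sessions)
        conditions = sorted(sessions["condition"].unique())
        pairs = [
            (a, b)
            for i, a in enumerate(conditions)
            for b in conditions[i + 1 :]
        ]
        out["comparisons"] = expression_stats.compare_conditions(sessions, pairs)
    return out


def write_results(result: ScreenResult, outdir: str | Path) -> Path:
    """Write all analysis tables (TSV), the dependence report and the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "config.yaml")
    result.normalized.to_csv(outdir / "normalized_activity.tsv", sep="\t", index=False)
    result.summaries.to_csv(outdir / "response_summary.tsv", sep="\t", index=False)
    result.thresholds.to_csv(outdir / "thresholds.tsv", sep="\t", index=False)
    result.responsive.to_csv(outdir / "responsive_ligands.tsv", sep="\t", index=False)
    result.points.to_csv(outdir / "interaction_points.tsv", sep="\t", index=False)
    result.categories.to_csv(outdir / "receptor_categories.tsv", sep="\t", index=False)
    if result.dependence is not None:
        (outdir / "dependence.json").write_text(
            json.dumps(result.dependence, indent=2, sort_keys=True)
        )
    return outdir
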