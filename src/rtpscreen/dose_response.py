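"""Dose-response curves, Hill fits, detection thresholds and threshold shifts.

Each (receptor, chaperone condition, odorant) group defines one concentration
series with a 0 µM baseline. The detection threshold is the lowest *tested*
concentration called active by a dual rule: the mean response must exceed the
baseline mean by ``k_sem`` pooled SEMs, and a one-sided Welch t test against
the baseline replicates must reject at level ``alpha``. Curves are fitted with
the four-parameter Hill equation

    psi(c) = bottom + (top - bottom) * c**n / (ec50**n + c**n)

by least squares on the positive-concentration points (replicate-level values
when available), with the bottom anchored near the measured baseline. The
0 µM point never enters the fit: it is the baseline reference only, since it
has no position on a log-concentration axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

CURVE_KEYS = ["or_name", "rtp_condition", "odorant"]


@dataclass
class ActivationRule:
    """Dual activation criterion: SEM exceedance plus one-sided t test."""

    alpha: float = 0.05
    k_sem: float = 3.0

    def as_dict(self) -> dict:
        return {"alpha": self.alpha, "k_sem": self.k_sem}


@dataclass
class DoseResponseCurve:
    or_name: str
    rtp_condition: str
    odorant: str
    #: concentration (molar, ascending), mean, sem, n_replicates[, values]
    points: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        conc = self.points["concentration"].to_numpy()
        if len(conc) == 0 or conc[0] != 0.0:
            raise ValueError(f"curve {self._label()} lacks a 0 M baseline point")
        if not np.all(np.diff(conc) > 0):
            raise ValueError(
                f"duplicate or unsorted concentrations in curve {self._label()}"
            )

    def _label(self) -> str:
        return f"({self.or_name}, {self.rtp_condition}, {self.odorant})"

    @property
    def baseline(self) -> pd.Series:
        return self.points.iloc[0]

    @property
    def positive_points(self) -> pd.DataFrame:
        return self.points.iloc[1:]


@dataclass
class HillFit:
    bottom: float
    top: float
    ec50: float  # molar
    hill_n: float
    converged: bool
    rss: float


@dataclass
class ThresholdCall:
    or_name: str
    rtp_condition: str
    odorant: str
    threshold: Optional[float]  # molar; None = no tested concentration active
    rule_params: dict = field(default_factory=dict)


def build_curves(
    summaries: pd.DataFrame, normalized: pd.DataFrame | None = None
) -> list[DoseResponseCurve]:
    """Assemble one sorted curve per (receptor, condition, odorant) group.

    ``summaries`` comes from :func:`rtpscreen.plate_model.summarize_replicates`.
    The 0 µM vehicle rows of each (receptor, condition) pair serve as the
    shared baseline for every odorant of that pair. If ``normalized`` (the
    per-well activity table) is given, replicate-level values are attached to
    each point for honest weighting in fits and t tests. Groups without a
    baseline are excluded with a warning; duplicate concentrations raise.
    """
    values = None
    if normalized is not None:
        from .plate_model import replicate_values

        values = replicate_values(normalized).set_index(
            ["or_name", "rtp_condition", "odorant", "concentration"]
        )["values"]

    baselines = summaries[summaries["concentration"] == 0].set_index(
        ["or_name", "rtp_condition"]
    )
    curves: list[DoseResponseCurve] = []
    positive = summaries[summaries["concentration"] > 0]
    for (or_name, cond, odorant), group in positive.groupby(CURVE_KEYS, sort=True):
        try:
            base = baselines.loc[(or_name, cond)]
        except KeyError:
            logger.warning(
                "no 0 M baseline for (%s, %s); curve for %s excluded",
                or_name,
                cond,
                odorant,
            )
            continue
        if isinstance(base, pd.DataFrame):  # multiple vehicle rows: first wins
            base = base.iloc[0]
        rows = [
            {
                "concentration": 0.0,
                "mean": base["mean"],
                "sem": base["sem"],
                "n_replicates": base["n_replicates"],
                "odorant_key": base["odorant"],
            }
        ]
        for _, row in group.sort_values("concentration").iterrows():
            rows.append(
                {
                    "concentration": row["concentration"],
                    "mean": row["mean"],
                    "sem": row["sem"],
                    "n_replicates": row["n_replicates"],
                    "odorant_key": odorant,
                }
            )
        points = pd.DataFrame(rows)
        if values is not None:
            points["values"] = [
                values.get((or_name, cond, r["odorant_key"], r["concentration"]))
                for _, r in points.iterrows()
            ]
        points = points.drop(columns="odorant_key")
        curves.append(DoseResponseCurve(or_name, cond, odorant, points))
    return curves


def hill(c, bottom, top, ec50, hill_n):
    """Four-parameter Hill equation, vectorized over concentration ``c``."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) * c**hill_n / (ec50**hill_n + c**hill_n)


def fit_hill(curve: DoseResponseCurve, bottom_slack: float = 0.1) -> HillFit:
    """Least-squares Hill fit on the positive-concentration points.

    Fits replicate-level values when the curve carries them, means otherwise.
    ``ec50`` is optimized as log10(EC50) for stability; the bottom is bounded
    within ``bottom_slack`` of the measured baseline mean. Failure to converge
    returns ``converged=False`` with best-effort parameters, never raises.
    """
    pos = curve.positive_points
    if pos["concentration"].nunique() < 4:
        raise ValueError("Hill fit requires >= 4 distinct positive concentrations")

    if "values" in pos.columns and pos["values"].notna().all():
        conc = np.concatenate(
            [np.full(len(v), c) for c, v in zip(pos["concentration"], pos["values"])]
        )
        resp = np.concatenate([np.asarray(v, float) for v in pos["values"]])
    else:
        conc = pos["concentration"].to_numpy(float)
        resp = pos["mean"].to_numpy(float)

    base = float(curve.baseline["mean"])
    span = float(resp.max() - resp.min())
    if span < 1e-12:  # flat curve: nothing to fit
        return HillFit(
            bottom=float(resp.mean()),
            top=float(resp.mean()),
            ec50=float(np.median(conc)),
            hill_n=1.0,
            converged=False,
            rss=float(np.sum((resp - resp.mean()) ** 2)),
        )

    def model(c, bottom, top, log_ec50, hill_n):
        return hill(c, bottom, top, 10.0**log_ec50, hill_n)

    log_c = np.log10(conc)
    half = base + 0.5 * (resp.max() - base)
    above = conc[resp >= half]
    ec50_guess = float(above.min()) if len(above) else float(np.median(conc))
    p0 = [base, float(resp.max()), math.log10(ec50_guess), 1.0]
    lo = [base - bottom_slack, base - bottom_slack, log_c.min() - 3.0, 1e-3]
    hi = [base + bottom_slack, max(2.0, resp.max() * 1.5), log_c.max() + 3.0, 10.0]
    p0 = np.clip(p0, lo, hi)
    try:
        popt, _ = optimize.curve_fit(
            model, conc, resp, p0=p0, bounds=(lo, hi), maxfev=20000
        )
        converged = True
    except (RuntimeError, ValueError):
        popt, converged = p0, False
    bottom, top, log_ec50, hill_n = (float(x) for x in popt)
    rss = float(np.sum((model(conc, *popt) - resp) ** 2))
    if top < bottom:
        converged = False
    return HillFit(bottom, top, 10.0**log_ec50, hill_n, converged, rss)


def one_sided_p(
    base_mean: float,
    base_sem: float,
    base_n: int,
    mean: float,
    sem: float,
    n: int,
) -> float:
    """One-sided Welch p-value for H1: mean > base_mean, from summary stats.

    With replicate-free (zero-variance) groups on both sides the t statistic
    degenerates; the call is then decided by the sign of the difference
    (p -> 0 for a positive difference, 1 otherwise). Groups too small to test
    (n < 2 on either side with nonzero variance) return p = 1.
    """
    diff = mean - base_mean
    s2 = base_sem**2 + sem**2
    if s2 == 0.0:
        return 0.0 if diff > 0 else 1.0
    if base_n < 2 or n < 2:
        return 1.0
    t = diff / math.sqrt(s2)
    num = s2**2
    den = 0.0
    if base_sem > 0:
        den += base_sem**4 / (base_n - 1)
    if sem > 0:
        den += sem**4 / (n - 1)
    df = num / den
    return float(stats.t.sf(t, df))


def responsive_ligand_call(
    summary: pd.Series, baseline: pd.Series, alpha: float = 0.05
) -> bool:
    """True iff the response exceeds baseline with one-sided significance.

    Used to count responsive ligands per chaperone condition in fixed-
    concentration selectivity panels.
    """
    if summary["mean"] <= baseline["mean"]:
        return False
    p = one_sided_p(
        baseline["mean"],
        baseline["sem"],
        int(baseline["n_replicates"]),
        summary["mean"],
        summary["sem"],
        int(summary["n_replicates"]),
    )
    return p < alpha


def responsive_ligand_matrix(
    summaries: pd.DataFrame,
    concentration: float | None = None,
    rule: ActivationRule | None = None,
) -> pd.DataFrame:
    """Boolean responsive-ligand matrix per (OR, odorant, condition).

    Calls :func:`responsive_ligand_call` against each condition's own 0 µM
    baseline at ``concentration`` (molar), or at each group's highest tested
    concentration when None — the fixed-concentration selectivity-panel
    readout. Groups lacking a baseline are skipped.
    """
    rule = rule or ActivationRule()
    baselines = summaries[summaries["concentration"] == 0].set_index(
        ["or_name", "rtp_condition"]
    )
    rows = []
    positive = summaries[summaries["concentration"] > 0]
    for (or_name, cond, odorant), group in positive.groupby(CURVE_KEYS, sort=True):
        try:
            base = baselines.loc[(or_name, cond)]
        except KeyError:
            continue
        if isinstance(base, pd.DataFrame):
            base = base.iloc[0]
        if concentration is None:
            row = group.loc[group["concentration"].idxmax()]
        else:
            match = group[np.isclose(group["concentration"], concentration)]
            if len(match) == 0:
                continue
            row = match.iloc[0]
        rows.append(
            {
                "or_name": or_name,
                "odorant": odorant,
                "rtp_condition": cond,
                "concentration": row["concentration"],
                "responsive": responsive_ligand_call(row, base, rule.alpha),
            }
        )
    return pd.DataFrame(rows)


def detect_threshold(
    curve: DoseResponseCurve, rule: ActivationRule | None = None
) -> ThresholdCall:
    """Lowest tested concentration passing the dual activation rule.

    A concentration qualifies when its mean exceeds ``baseline mean +
    k_sem * sqrt(sem_baseline**2 + sem_c**2)`` and the one-sided Welch test
    against baseline rejects at ``alpha``. Returns ``threshold=None`` when no
    concentration qualifies.
    """
    rule = rule or ActivationRule()
    base = curve.baseline
    threshold = None
    for _, row in curve.positive_points.iterrows():
        pooled = math.sqrt(base["sem"] ** 2 + row["sem"] ** 2)
        if row["mean"] <= base["mean"] + rule.k_sem * pooled:
            continue
        p = one_sided_p(
            base["mean"],
            base["sem"],
            int(base["n_replicates"]),
            row["mean"],
            row["sem"],
            int(row["n_replicates"]),
        )
        if p < rule.alpha:
            threshold = float(row["concentration"])
            break
    return ThresholdCall(
        curve.or_name,
        curve.rtp_condition,
        curve.odorant,
        threshold,
        rule_params=rule.as_dict(),
    )


def threshold_shift(a: ThresholdCall, b: ThresholdCall) -> Optional[float]:
    """Fold-change of detection threshold between two chaperone conditions.

    Returns ``b.threshold / a.threshold`` (>1 means the second condition needs
    more odorant, i.e. a rightward shift), or None when either condition never
    reaches threshold; the not-restored case is logged.
    """
    if (a.or_name, a.odorant) != (b.or_name, b.odorant):
        raise ValueError(
            "threshold_shift compares one receptor-odorant pair across "
            f"conditions; got {a.or_name}/{a.odorant} vs {b.or_name}/{b.odorant}"
        )
    if a.threshold is None or b.threshold is None:
        if a.threshold is not None and b.threshold is None:
            logger.info(
                "%s + %s: response not restored under %s at any tested "
                "concentration",
                a.or_name,
                a.odorant,
                b.rtp_condition,
            )
        return None
    return b.threshold / a.threshold


def threshold_table(calls: list[ThresholdCall]) -> pd.DataFrame:
    """Tidy table of threshold calls (concentration reported in µM)."""
    return pd.DataFrame(
        {
            "or_name": [c.or_name for c in calls],
            "rtp_condition": [c.rtp_condition for c in calls],
            "odorant": [c.odorant for c in calls],
            "threshold_uM": [
                None if c.threshold is None else c.threshold * 1e6 for c in calls
            ],
        }
    )
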