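"""Cell-surface expression and colocalization counting statistics.

Surface expression is read out by a chemiluminescent immunoassay against an
N-terminal epitope tag; each receptor/chaperone condition is normalized as
fold over the empty-vector control (OR/pCI), and a condition is called
surface-positive when that fold exceeds a declared minimum threshold (the
threshold is a reporting convention, not a biological constant, so it is
carried with every call).

Colocalization data arrive as counting sessions: a fixed number of
transfected cells (nominally 100) scored per session for overlap with an
ER/Golgi marker or for punctate surface signal. Sessions are summarized as
mean +/- SEM and compared across conditions with the paired two-tailed
t test, pairing sessions by index; significance labels follow the usual
star convention (* p < 0.05, ** p < 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COMPARTMENTS = ("ER", "Golgi", "surface")


@dataclass
class PairedComparison:
    condition_a: str
    condition_b: str
    t_statistic: float
    degrees_of_freedom: int
    p_two_tailed: float
    stars: str
    zero_variance: bool = False


def normalize_surface(lum_or: float, lum_pci: float) -> float:
    """Fold cell-surface luminescence over the empty-vector control (OR/pCI)."""
    if lum_pci <= 0:
        raise ValueError("vector-control luminescence must be > 0")
    return float(lum_or) / float(lum_pci)


def surface_positive_call(fold: float, threshold: float = 1.5) -> bool:
    """Call a condition surface-positive at the declared fold threshold.

    The tie goes to positive (>=). ``threshold`` must exceed 1 — a fold of 1
    is indistinguishable from the vector control by construction.
    """
    if threshold <= 1:
        raise ValueError("surface threshold must be > 1")
    return fold >= threshold


def surface_table(
    luminescence: pd.DataFrame, threshold: float = 1.5
) -> pd.DataFrame:
    """Normalize a surface-luminescence table against its vector control.

    Expects columns (or_name, rtp_condition, luminescence); the row with
    or_name == "pCI" is the vector control. Returns fold_over_vector and the
    positive call, with the threshold used recorded on every row.
    """
    vec = luminescence.loc[luminescence["or_name"] == "pCI", "luminescence"]
    if len(vec) == 0:
        raise ValueError("surface table lacks a pCI vector-control row")
    vec_mean = float(vec.mean())
    out = luminescence[luminescence["or_name"] != "pCI"].copy()
    out["fold_over_vector"] = [
        normalize_surface(v, vec_mean) for v in out["luminescence"]
    ]
    out["positive"] = [
        surface_positive_call(f, threshold) for f in out["fold_over_vector"]
    ]
    out["threshold"] = threshold
    return out.reset_index(drop=True)


def summarize_sessions(sessions: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of positive-cell counts per condition x compartment.

    ``sessions`` has one row per counting session with columns (condition,
    compartment, counted, positive_count). SEM uses the sample standard
    deviation; singleton cells get SEM 0 and a flag. The positive fraction is
    computed against each session's own denominator, which need not be 100.
    """
    bad = (sessions["positive_count"] < 0) | (
        sessions["positive_count"] > sessions["counted"]
    )
    if bad.any():
        raise ValueError("positive_count must lie in [0, counted]")
    grouped = sessions.groupby(["condition", "compartment"], sort=True)
    out = grouped.agg(
        mean_count=("positive_count", "mean"),
        sd=("positive_count", lambda s: s.std(ddof=1)),
        n_sessions=("positive_count", "count"),
        mean_fraction=("positive_count", "sum"),
    ).reset_index()
    totals = grouped["counted"].sum().to_numpy()
    out["mean_fraction"] = out["mean_fraction"] / totals
    singleton = out["n_sessions"] == 1
    out["sem"] = np.where(singleton, 0.0, out["sd"] / np.sqrt(out["n_sessions"]))
    out["singleton"] = singleton
    return out.drop(columns="sd")


def paired_t_test(
    a, b, label_a: str = "a", label_b: str = "b"
) -> PairedComparison:
    """Paired two-tailed t test on counts paired by session index.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a - b and n-1 degrees of freedom.
    When every difference is identical and nonzero the statistic is infinite;
    the comparison is flagged and p reported as 0.0 (below any representable
    level). Identical vectors give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("paired t test needs >= 2 pairs")
    d = a - b
    n = len(d)
    if np.std(d, ddof=1) == 0.0:
        if d.mean() == 0.0:
            t, p, zero_var = 0.0, 1.0, False
        else:
            t = math_inf_signed(d.mean())
            p, zero_var = 0.0, True
            logger.warning(
                "paired differences have zero variance and nonzero mean; "
                "p reported as 0"
            )
    else:
        res = stats.ttest_rel(a, b)
        t, p, zero_var = float(res.statistic), float(res.pvalue), False
    return PairedComparison(
        condition_a=label_a,
        condition_b=label_b,
        t_statistic=t,
        degrees_of_freedom=n - 1,
        p_two_tailed=p,
        stars=significance_stars(p),
        zero_variance=zero_var,
    )


def math_inf_signed(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")


def significance_stars(p: float) -> str:
    """Conventional significance label: ** p<0.01, * p<0.05, else ns."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_conditions(
    sessions: pd.DataFrame,
    pairs: list[tuple[str, str]],
    holm: bool = False,
) -> pd.DataFrame:
    """Paired comparisons between named conditions, per compartment.

    Sessions are paired by their order within each condition x compartment
    cell. No multiplicity correction is applied by default; ``holm=True``
    applies a Holm step-down adjustment across the requested grid.
    """
    rows = []
    for compartment, comp_group in sessions.groupby("compartment", sort=True):
        by_cond = {
            cond: g.sort_index()["positive_count"].to_numpy(float)
            for cond, g in comp_group.groupby("condition")
        }
        for cond_a, cond_b in pairs:
            if cond_a not in by_cond or cond_b not in by_cond:
                continue
            cmp = paired_t_test(by_cond[cond_a], by_cond[cond_b], cond_a, cond_b)
            rows.append(
                {
                    "compartment": compartment,
                    "condition_a": cond_a,
                    "condition_b": cond_b,
                    "t": cmp.t_statistic,
                    "df": cmp.degrees_of_freedom,
                    "p": cmp.p_two_tailed,
                    "stars": cmp.stars,
                    "zero_variance": cmp.zero_variance,
                }
            )
    out = pd.DataFrame(rows)
    if holm and len(out):
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
        out["stars"] = [significance_stars(p) for p in out["p_holm"]]
    return out
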