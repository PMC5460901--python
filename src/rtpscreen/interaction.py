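"""Sigma-tau mixture-interaction analysis for chaperone co-expression.

When a receptor is driven by two chaperones singly and in combination, the
relation between the combined response and the two single responses is
summarized by two dimensionless statistics:

    tau_RTP1S = psi_RTP1S / (psi_RTP1S + psi_RTP2)      (tau_RTP2 = 1 - tau_RTP1S)
    sigma     = psi_mix   / (psi_RTP1S + psi_RTP2)

where psi is the receptor response level (normalized luciferase activity)
under the named transfection condition. sigma > 1 is hyper-addition
(synergy), sigma = 1 complete addition, sigma < 1 hypo-addition
(competition between the co-expressed chaperones). On the sigma = f(tau)
scatter diagram the two diagonals sigma = tau and sigma = 1 - tau partition
the hypo-addition region by the ordering of psi_mix relative to the single
responses: sigma > tau iff psi_mix > psi_RTP1S, and sigma > 1 - tau iff
psi_mix > psi_RTP2.

Points aggregating toward tau = 1 mark receptors whose activation is driven
by RTP1S alone (Category 1); points near tau = 0.5 mark receptors helped
comparably by both chaperones (Category 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import ActivationRule, one_sided_p
from .plate_model import VEHICLE_NAME

logger = logging.getLogger(__name__)

HYPER, COMPLETE, HYPO = "hyper", "complete", "hypo"
MIX_ABOVE_BOTH, MIX_BETWEEN, MIX_BELOW_BOTH = (
    "mix_above_both",
    "mix_between",
    "mix_below_both",
)
CATEGORY1, CATEGORY2, UNCATEGORIZED = "category1", "category2", "uncategorized"


class UndefinedPointError(ValueError):
    """Raised when the tau/sigma denominator psi1 + psi2 is below the floor."""


@dataclass
class InteractionConfig:
    """Knobs of the interaction analysis.

    eps
        Denominator floor (normalized units) below which tau and sigma are
        undefined; guards ratio blow-up at sub-threshold responses.
    tolerance
        Half-width of the band around sigma = 1 labelled complete addition.
    tau_cat
        Median-tau cut separating Category 1 (above) from Category 2.
    min_points
        Minimum number of valid points needed to categorize a receptor.
    psi_mode
        "baseline_subtracted" (default): psi is the activity at concentration
        c minus the same condition's 0 µM activity, floored at 0;
        "raw": psi is the normalized activity as-is.
    """

    eps: float = 1e-3
    tolerance: float = 0.05
    tau_cat: float = 0.65
    min_points: int = 2
    psi_mode: str = "baseline_subtracted"

    def __post_init__(self) -> None:
        if self.psi_mode not in ("baseline_subtracted", "raw"):
            raise ValueError(f"unknown psi_mode {self.psi_mode!r}")


@dataclass
class ReceptorCategory:
    or_name: str
    category: str
    median_tau: float
    n_valid: int
    n_rtp2_active_ligands: int


def compute_tau(psi1: float, psi2: float, eps: float = 1e-3) -> tuple[float, float]:
    """Fractional contributions (tau_RTP1S, tau_RTP2); they sum to 1."""
    total = psi1 + psi2
    if total <= eps:
        raise UndefinedPointError(f"psi1 + psi2 = {total} <= eps = {eps}")
    return psi1 / total, psi2 / total


def compute_sigma(psi_mix: float, psi1: float, psi2: float, eps: float = 1e-3) -> float:
    """Mixture-to-sum response ratio sigma = psi_mix / (psi1 + psi2)."""
    total = psi1 + psi2
    if total <= eps:
        raise UndefinedPointError(f"psi1 + psi2 = {total} <= eps = {eps}")
    return psi_mix / total


def classify_addition(sigma: float, tolerance: float = 0.05) -> str:
    """Hyper / complete / hypo addition with a tolerance band around 1."""
    if sigma > 1.0 + tolerance:
        return HYPER
    if sigma < 1.0 - tolerance:
        return HYPO
    return COMPLETE


def assign_subregion(tau_rtp1s: float, sigma: float) -> str:
    """Diagonal sub-region of the scatter diagram.

    Exploits sigma > tau iff psi_mix > psi_RTP1S and sigma > 1 - tau iff
    psi_mix > psi_RTP2. A point exactly on a diagonal is mix_between by
    convention.
    """
    hi, lo = max(tau_rtp1s, 1.0 - tau_rtp1s), min(tau_rtp1s, 1.0 - tau_rtp1s)
    if sigma > hi:
        return MIX_ABOVE_BOTH
    if sigma < lo:
        return MIX_BELOW_BOTH
    return MIX_BETWEEN


def build_response_pairs(
    summaries: pd.DataFrame,
    config: InteractionConfig | None = None,
    rule: ActivationRule | None = None,
) -> pd.DataFrame:
    """Assemble (psi_RTP1S, psi_RTP2, psi_mix) triples per pair-concentration.

    One row per (receptor, odorant, positive concentration) with baseline-
    adjusted psi for each condition plus activation flags (the one-sided
    activation rule of each single-chaperone condition against its own 0 µM
    baseline), which downstream validity filtering consumes.
    """
    config = config or InteractionConfig()
    rule = rule or ActivationRule()
    idx = summaries.set_index(
        ["or_name", "rtp_condition", "odorant", "concentration"]
    ).sort_index()

    def base_row(or_name, cond):
        try:
            return idx.loc[(or_name, cond, VEHICLE_NAME, 0.0)]
        except KeyError:
            return None

    rows = []
    positive = summaries[summaries["concentration"] > 0]
    for (or_name, odorant, conc), group in positive.groupby(
        ["or_name", "odorant", "concentration"], sort=True
    ):
        by_cond = group.set_index("rtp_condition")
        if not {"RTP1S", "RTP2", "both"}.issubset(by_cond.index):
            continue
        psi, active = {}, {}
        for cond in ("none", "RTP1S", "RTP2", "both"):
            if cond not in by_cond.index:
                psi[cond] = np.nan
                continue
            row = by_cond.loc[cond]
            base = base_row(or_name, cond)
            if config.psi_mode == "baseline_subtracted" and base is not None:
                psi[cond] = max(0.0, row["mean"] - base["mean"])
            else:
                psi[cond] = row["mean"]
            if cond in ("RTP1S", "RTP2") and base is not None:
                p = one_sided_p(
                    base["mean"],
                    base["sem"],
                    int(base["n_replicates"]),
                    row["mean"],
                    row["sem"],
                    int(row["n_replicates"]),
                )
                active[cond] = bool(row["mean"] > base["mean"] and p < rule.alpha)
            elif cond in ("RTP1S", "RTP2"):
                active[cond] = False
        rows.append(
            {
                "or_name": or_name,
                "odorant": odorant,
                "concentration": conc,
                "psi_rtp1s": psi["RTP1S"],
                "psi_rtp2": psi["RTP2"],
                "psi_mix": psi["both"],
                "psi_or_only": psi.get("none", np.nan),
                "active_rtp1s": active["RTP1S"],
                "active_rtp2": active["RTP2"],
            }
        )
    return pd.DataFrame(rows)


def select_valid_points(
    pairs: pd.DataFrame, config: InteractionConfig | None = None
) -> pd.DataFrame:
    """Attach tau, sigma, class and sub-region; mark validity.

    A pair-concentration is valid when at least one single-chaperone
    condition passes the activation rule (sub-threshold responses carry no
    interaction information) and the tau/sigma denominator exceeds the eps
    floor. Invalid points are retained with ``valid = False``; points whose
    denominator is below the floor have NaN statistics.
    """
    config = config or InteractionConfig()
    out = pairs.copy()
    tau1 = np.full(len(out), np.nan)
    sigma = np.full(len(out), np.nan)
    add_class = np.full(len(out), None, dtype=object)
    subregion = np.full(len(out), None, dtype=object)
    valid = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        total = row.psi_rtp1s + row.psi_rtp2
        defined = np.isfinite(total) and total > config.eps
        if defined:
            t1, _ = compute_tau(row.psi_rtp1s, row.psi_rtp2, config.eps)
            s = compute_sigma(row.psi_mix, row.psi_rtp1s, row.psi_rtp2, config.eps)
            tau1[i], sigma[i] = t1, s
            add_class[i] = classify_addition(s, config.tolerance)
            subregion[i] = assign_subregion(t1, s)
        valid[i] = defined and (row.active_rtp1s or row.active_rtp2)
    out["tau_rtp1s"] = tau1
    out["tau_rtp2"] = 1.0 - tau1
    out["sigma"] = sigma
    out["addition_class"] = add_class
    out["subregion"] = subregion
    out["valid"] = valid
    return out


def categorize_receptor(
    points: pd.DataFrame, config: InteractionConfig | None = None
) -> ReceptorCategory:
    """Categorize one receptor from its valid interaction points.

    Category 1: RTP1S dominates (median tau above ``tau_cat``). Category 2:
    both chaperones contribute (median tau at or below the cut) and RTP2
    demonstrably activates the receptor for at least one ligand. Receptors
    with fewer than ``min_points`` valid points stay uncategorized.
    """
    config = config or InteractionConfig()
    or_names = points["or_name"].unique()
    if len(or_names) != 1:
        raise ValueError("categorize_receptor expects points from a single receptor")
    valid = points[points["valid"]]
    n_rtp2 = int(valid.loc[valid["active_rtp2"], "odorant"].nunique())
    if len(valid) < config.min_points:
        return ReceptorCategory(or_names[0], UNCATEGORIZED, float("nan"), len(valid), n_rtp2)
    med = float(valid["tau_rtp1s"].median())
    if med > config.tau_cat:
        cat = CATEGORY1
    elif n_rtp2 >= 1:
        cat = CATEGORY2
    else:
        cat = UNCATEGORIZED
    return ReceptorCategory(or_names[0], cat, med, len(valid), n_rtp2)


def categorize_receptors(
    points: pd.DataFrame, config: InteractionConfig | None = None
) -> pd.DataFrame:
    """Category table over every receptor present in ``points``."""
    cats = [
        categorize_receptor(group, config)
        for _, group in points.groupby("or_name", sort=True)
    ]
    return pd.DataFrame(
        {
            "or_name": [c.or_name for c in cats],
            "category": [c.category for c in cats],
            "median_tau": [c.median_tau for c in cats],
            "n_valid": [c.n_valid for c in cats],
            "n_rtp2_active_ligands": [c.n_rtp2_active_ligands for c in cats],
        }
    )


def _within_group_dispersion(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean within-group pairwise Euclidean distance, averaged over groups.

    Groups with fewer than two points carry no pairwise distance and are
    skipped. Lower values mean tighter within-group clustering.
    """
    diff = coords[:, None, :] - coords[None, :, :]
    return _dispersion_from_matrix(np.sqrt((diff**2).sum(-1)), labels)


def _dispersion_from_matrix(dist: np.ndarray, labels: np.ndarray) -> float:
    means = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            continue
        sub = dist[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), 1)
        means.append(sub[iu].mean())
    if not means:
        raise ValueError("no group has >= 2 points")
    return float(np.mean(means))


def dependence_analysis(
    points: pd.DataFrame,
    grouping: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Permutation test of whether interaction points cluster by group.

    Groups valid points by receptor (``by_or``) or odorant (``by_odorant``)
    and measures the mean within-group pairwise distance in (tau, sigma)
    space. The p-value is the permutation probability (group labels shuffled)
    of a dispersion at least as small as observed, with the +1 correction.
    """
    if grouping not in ("by_or", "by_odorant"):
        raise ValueError(f"grouping must be by_or or by_odorant, got {grouping!r}")
    col = "or_name" if grouping == "by_or" else "odorant"
    valid = points[points["valid"]]
    labels = valid[col].to_numpy()
    coords = valid[["tau_rtp1s", "sigma"]].to_numpy(float)
    n_groups = len(np.unique(labels))
    if n_groups < 2 or len(valid) < 4:
        raise ValueError("dependence analysis needs >= 2 groups and >= 4 points")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    obs = _dispersion_from_matrix(dist, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _dispersion_from_matrix(dist, perm) <= obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return {
        "grouping": grouping,
        "statistic": obs,
        "p": p,
        "n_points": int(len(valid)),
        "n_groups": int(n_groups),
        "n_perm": n_perm,
    }


def compare_dependence(
    points: pd.DataFrame, n_perm: int = 999, seed: int | None = None
) -> dict:
    """Which factor — receptor type or odorant type — drives the interaction.

    Runs the permutation dispersion test under both groupings and reports
    which clusters more tightly (smaller statistic).
    """
    by_or = dependence_analysis(points, "by_or", n_perm, seed)
    by_od = dependence_analysis(points, "by_odorant", n_perm, seed)
    tighter = "by_or" if by_or["statistic"] < by_od["statistic"] else "by_odorant"
    return {
        "by_or": by_or,
        "by_odorant": by_od,
        "tighter_grouping": tighter,
        "interpretation": (
            "interaction mode depends more on receptor type"
            if tighter == "by_or"
            else "interaction mode depends more on odorant type"
        ),
    }
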