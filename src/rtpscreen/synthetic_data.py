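"""Seeded generator for synthetic dual-luciferase screens with ground truth.

The generator emulates the structure of a chaperone co-expression screen:
each receptor archetype carries Hill dose-response parameters for the
OR-only, RTP1S-only and RTP2-only transfection conditions, and the
co-transfection response is a convex combination of the two single-chaperone
responses,

    psi_mix(c) = phi * psi_RTP1S(c) + (1 - phi) * psi_RTP2(c),

the simplest model of two chaperones competing for a shared binding site on
the receptor (equal plasmid doses; phi encodes relative binding affinity).
Because a convex combination never exceeds the larger of its parts,
psi_mix <= max(psi1, psi2) < psi1 + psi2 whenever both singles respond, so
every generated interaction point is hypo-additive (sigma < 1) by
construction.

Category-1 archetypes give RTP2 negligible efficacy (its top is at the
OR-only level); Category-2 archetypes give both chaperones comparable tops.
Luminescence noise is multiplicative lognormal on both channels, reflecting
positive, heteroscedastic plate-reader counts. All randomness flows from a
single integer seed; the same seed reproduces the tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .interaction import classify_addition
from .plate_model import RTP_CONDITIONS, VECTOR_NAME, VEHICLE_NAME

#: default concentration series, µM (0 = vehicle baseline)
DEFAULT_CONCENTRATIONS_UM = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0)

DEFAULT_ODORANTS = ("octanal", "eugenol", "acetophenone", "nonanedioic_acid")


@dataclass
class HillParams:
    """True dose-response parameters of one transfection condition."""

    top: float
    ec50_uM: float
    hill_n: float = 1.0
    bottom: float = 0.0

    def psi(self, conc_uM) -> np.ndarray:
        """True response level at the given concentrations (µM)."""
        c = np.asarray(conc_uM, dtype=float)
        with np.errstate(divide="ignore"):
            frac = np.where(
                c > 0,
                c**self.hill_n / (self.ec50_uM**self.hill_n + c**self.hill_n),
                0.0,
            )
        return self.bottom + (self.top - self.bottom) * frac


@dataclass
class ReceptorArchetype:
    or_name: str
    category: str  # "category1" | "category2"
    params: dict[str, HillParams]  # keys: none, RTP1S, RTP2
    mix_weight: float  # phi: relative RTP1S occupancy under co-transfection
    #: optional relative inflation of the mixture response (Category-2
    #: receptors may show a less obvious suppression); > 0 can break the
    #: hypo-addition guarantee and is off by default
    mix_boost: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mix_weight <= 1.0:
            raise ValueError("mix_weight must lie in [0, 1]")
        missing = {"none", "RTP1S", "RTP2"} - set(self.params)
        if missing:
            raise ValueError(f"archetype {self.or_name} missing conditions {missing}")
        for cond, p in self.params.items():
            if p.top < p.bottom or p.bottom < 0:
                raise ValueError(
                    f"archetype {self.or_name}/{cond}: need top >= bottom >= 0"
                )

    def psi(self, condition: str, conc_uM) -> np.ndarray:
        """True response for any condition, including the mixture."""
        if condition == "both":
            p1 = self.params["RTP1S"].psi(conc_uM)
            p2 = self.params["RTP2"].psi(conc_uM)
            return (1.0 + self.mix_boost) * (
                self.mix_weight * p1 + (1.0 - self.mix_weight) * p2
            )
        return self.params[condition].psi(conc_uM)


@dataclass
class NoiseModel:
    """Multiplicative lognormal noise on both luciferase channels."""

    firefly_cv: float = 0.1
    renilla_mean: float = 5e5
    renilla_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.firefly_cv < 0 or self.renilla_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")


@dataclass
class GroundTruth:
    """Generator truth keyed identically to the pipeline outputs."""

    archetypes: list[ReceptorArchetype]
    responses: pd.DataFrame = field(repr=False)  # per (or, odorant, conc)
    categories: pd.DataFrame = field(repr=False)  # per or
    thresholds: pd.DataFrame = field(repr=False)  # per (or, condition, odorant)
    config: dict = field(default_factory=dict)


def default_archetypes(n_cat1: int = 4, n_cat2: int = 2) -> list[ReceptorArchetype]:
    """Desk-scale receptor panel: RTP1S-dominated and dual-enhanced types.

    Category-1 receptors respond strongly with RTP1S (top 0.7-1.0) and
    barely above the OR-only level with RTP2; their mixing weight is high
    (RTP1S wins the shared site). Category-2 receptors respond with both
    chaperones and mix near-evenly. EC50s spread over 3-30 µM as in typical
    odorant panels.
    """
    archetypes = []
    for i in range(n_cat1):
        archetypes.append(
            ReceptorArchetype(
                or_name=f"ORc1-{i + 1}",
                category="category1",
                params={
                    "none": HillParams(top=0.03 + 0.01 * (i % 2), ec50_uM=30.0),
                    "RTP1S": HillParams(
                        top=0.75 + 0.08 * i, ec50_uM=[5.0, 10.0, 20.0, 8.0][i % 4],
                        hill_n=1.0 + 0.2 * (i % 3),
                    ),
                    "RTP2": HillParams(
                        top=0.05 + 0.01 * i, ec50_uM=[8.0, 15.0, 25.0, 12.0][i % 4]
                    ),
                },
                mix_weight=0.82 + 0.03 * (i % 3),
            )
        )
    for j in range(n_cat2):
        archetypes.append(
            ReceptorArchetype(
                or_name=f"ORc2-{j + 1}",
                category="category2",
                params={
                    "none": HillParams(top=0.04, ec50_uM=25.0),
                    "RTP1S": HillParams(
                        top=0.85 - 0.05 * j, ec50_uM=[6.0, 18.0][j % 2],
                        hill_n=1.1,
                    ),
                    "RTP2": HillParams(
                        top=0.62 - 0.04 * j, ec50_uM=[9.0, 22.0][j % 2]
                    ),
                },
                mix_weight=0.55 + 0.03 * j,
            )
        )
    return archetypes


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise; cv = 0 gives exactly 1."""
    if cv == 0:
        return np.ones(size)
    s = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(s**2) / 2.0, sigma=s, size=size)


def _assign_wells(n: int) -> tuple[list[str], list[str]]:
    """Sequential 96-well plate/well ids for n wells."""
    rows, cols = "ABCDEFGH", range(1, 13)
    plate_ids, well_ids = [], []
    for i in range(n):
        plate, slot = divmod(i, 96)
        r, c = divmod(slot, 12)
        plate_ids.append(f"P{plate + 1:03d}")
        well_ids.append(f"{rows[r]}{c + 1:02d}")
    return plate_ids, well_ids


def generate_screen(
    archetypes: list[ReceptorArchetype] | None = None,
    odorants: tuple[str, ...] = DEFAULT_ODORANTS,
    concentrations_uM: tuple[float, ...] = DEFAULT_CONCENTRATIONS_UM,
    n_replicates: int = 3,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    gain: float = 2e5,
    constitutive: float = 0.02,
    n_vector_wells: int = 3,
    eps: float = 1e-3,
    tolerance: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one synthetic screen: measurement table, layout, ground truth.

    Every receptor x condition x odorant x positive concentration cell gets
    ``n_replicates`` wells, plus vehicle (0 µM) baseline wells per receptor x
    condition and empty-vector (pCI) control wells. Firefly counts are
    ``gain * (constitutive + psi) * noise``; Renilla counts are lognormal
    about ``noise.renilla_mean``. ``seed`` is mandatory for reproducibility.
    """
    if seed is None:
        raise ValueError("generate_screen requires an explicit seed")
    if 0.0 not in concentrations_uM:
        raise ValueError("concentration series must include the 0 µM baseline")
    archetypes = archetypes if archetypes is not None else default_archetypes()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    layout_rows = []
    true_psi = []
    for arch in archetypes:
        for cond in RTP_CONDITIONS:
            # vehicle baseline wells
            for _ in range(n_replicates):
                layout_rows.append((arch.or_name, cond, VEHICLE_NAME, 0.0))
                true_psi.append(float(arch.psi(cond, 0.0)))
            for odorant in odorants:
                for conc in sorted(c for c in concentrations_uM if c > 0):
                    psi = float(arch.psi(cond, conc))
                    for _ in range(n_replicates):
                        layout_rows.append((arch.or_name, cond, odorant, conc))
                        true_psi.append(psi)
    for _ in range(n_vector_wells):
        layout_rows.append((VECTOR_NAME, "none", VEHICLE_NAME, 0.0))
        true_psi.append(0.0)

    n = len(layout_rows)
    plate_ids, well_ids = _assign_wells(n)
    psi_arr = np.asarray(true_psi)
    firefly = gain * (constitutive + psi_arr) * _lognormal_factor(
        rng, noise.firefly_cv, n
    )
    renilla = noise.renilla_mean * _lognormal_factor(rng, noise.renilla_cv, n)

    layout = pd.DataFrame(layout_rows, columns=["or_name", "rtp_condition", "odorant", "concentration_uM"])
    layout.insert(0, "well_id", well_ids)
    layout.insert(0, "plate_id", plate_ids)
    measurements = pd.DataFrame(
        {
            "plate_id": plate_ids,
            "well_id": well_ids,
            "firefly": firefly,
            "renilla": renilla,
        }
    )

    truth = _ground_truth(
        archetypes, odorants, concentrations_uM, eps=eps, tolerance=tolerance
    )
    truth.config = {
        "odorants": list(odorants),
        "concentrations_uM": list(concentrations_uM),
        "n_replicates": n_replicates,
        "noise": asdict(noise),
        "seed": seed,
        "gain": gain,
        "constitutive": constitutive,
    }
    return measurements, layout, truth


def _ground_truth(
    archetypes, odorants, concentrations_uM, eps: float, tolerance: float
) -> GroundTruth:
    resp_rows, thr_rows = [], []
    for arch in archetypes:
        for odorant in odorants:
            for conc in sorted(c for c in concentrations_uM if c > 0):
                p1 = float(arch.psi("RTP1S", conc))
                p2 = float(arch.psi("RTP2", conc))
                pm = float(arch.psi("both", conc))
                total = p1 + p2
                if total > 0:
                    tau = p1 / total
                    sigma = pm / total
                    cls = classify_addition(sigma, tolerance)
                else:
                    tau = sigma = np.nan
                    cls = None
                resp_rows.append(
                    {
                        "or_name": arch.or_name,
                        "odorant": odorant,
                        "concentration": conc * 1e-6,
                        "psi_none": float(arch.psi("none", conc)),
                        "psi_rtp1s": p1,
                        "psi_rtp2": p2,
                        "psi_mix": pm,
                        "tau_rtp1s": tau,
                        "sigma": sigma,
                        "addition_class": cls,
                    }
                )
        for cond in RTP_CONDITIONS:
            base = float(arch.psi(cond, 0.0))
            for odorant in odorants:
                thr = None
                for conc in sorted(c for c in concentrations_uM if c > 0):
                    if float(arch.psi(cond, conc)) > base:
                        thr = conc
                        break
                thr_rows.append(
                    {
                        "or_name": arch.or_name,
                        "rtp_condition": cond,
                        "odorant": odorant,
                        "threshold_uM": thr,
                    }
                )
    categories = pd.DataFrame(
        {
            "or_name": [a.or_name for a in archetypes],
            "category": [a.category for a in archetypes],
        }
    )
    return GroundTruth(
        archetypes=list(archetypes),
        responses=pd.DataFrame(resp_rows),
        categories=categories,
        thresholds=pd.DataFrame(thr_rows),
    )


def ground_truth_report(gt: GroundTruth) -> pd.DataFrame:
    """Truth table keyed like the pipeline's interaction-point table."""
    return gt.responses.copy()


DEFAULT_SURFACE_FOLDS = {"none": 1.1, "RTP1S": 3.0, "RTP2": 1.2, "both": 2.0}

#: default true colocalization fractions per (condition, compartment),
#: emulating RTP1S routing receptors through the Golgi to the surface while
#: RTP2 retains them in the Golgi (and dampens RTP1S when co-expressed)
DEFAULT_COLOC_P = {
    ("OR_alone", "ER"): 0.80,
    ("OR_alone", "Golgi"): 0.15,
    ("OR_alone", "surface"): 0.05,
    ("OR+RTP1S", "ER"): 0.35,
    ("OR+RTP1S", "Golgi"): 0.45,
    ("OR+RTP1S", "surface"): 0.55,
    ("OR+RTP2", "ER"): 0.40,
    ("OR+RTP2", "Golgi"): 0.65,
    ("OR+RTP2", "surface"): 0.10,
    ("OR+both", "ER"): 0.35,
    ("OR+both", "Golgi"): 0.60,
    ("OR+both", "surface"): 0.30,
}


def generate_surface_assay(
    archetypes: list[ReceptorArchetype] | None = None,
    fold_effects: dict[str, float] | None = None,
    cv: float = 0.1,
    n_replicates: int = 3,
    base_luminescence: float = 1e4,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic chemiluminescent surface-expression table.

    Programmed fold effects over the vector control default to the ordering
    RTP1S > both > RTP2 ≈ OR-only. Emits ``n_replicates`` rows per receptor x
    condition plus matching pCI vector-control rows.
    """
    if seed is None:
        raise ValueError("generate_surface_assay requires an explicit seed")
    archetypes = archetypes if archetypes is not None else default_archetypes()
    folds = fold_effects or DEFAULT_SURFACE_FOLDS
    rng = np.random.default_rng(seed)
    rows = []
    for arch in archetypes:
        for cond in RTP_CONDITIONS:
            for rep in range(n_replicates):
                rows.append((arch.or_name, cond, rep + 1, folds[cond]))
    for rep in range(n_replicates):
        rows.append((VECTOR_NAME, "none", rep + 1, 1.0))
    df = pd.DataFrame(rows, columns=["or_name", "rtp_condition", "replicate", "fold"])
    df["luminescence"] = (
        base_luminescence * df["fold"].to_numpy() * _lognormal_factor(rng, cv, len(df))
    )
    return df.drop(columns="fold")


def generate_colocalization_sessions(
    p_true: dict[tuple[str, str], float],
    n_sessions: int = 3,
    counted: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binomial counting sessions: positive_count ~ Bin(counted, p_true).

    ``p_true`` maps (condition, compartment) to the true positive fraction.
    """
    if seed is None:
        raise ValueError("generate_colocalization_sessions requires an explicit seed")
    rng = np.random.default_rng(seed)
    rows = []
    for (condition, compartment), p in sorted(p_true.items()):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_true for {(condition, compartment)} outside [0, 1]")
        draws = rng.binomial(counted, p, size=n_sessions)
        for sess, k in enumerate(draws, start=1):
            rows.append(
                {
                    "condition": condition,
                    "compartment": compartment,
                    "session": sess,
                    "counted": counted,
                    "positive_count": int(k),
                }
            )
    return pd.DataFrame(rows)
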