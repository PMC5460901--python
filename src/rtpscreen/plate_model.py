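"""Ingestion and normalization of dual-luciferase plate data.

The screening readout is a dual reporter: a CRE-driven firefly luciferase
measures receptor activation through the cAMP pathway, while a constitutive
*Renilla* luciferase controls for cell viability and transfection efficiency.
Each well yields a ratio ``luc/RL``; ratios are then min-max normalized within
a *scope* (one plate, or one batch of plates analyzed together) so that the
lowest well maps to 0 and the highest to 1::

    activity = (r - r_min) / (r_max - r_min),   r = firefly / renilla

Replicate wells (same receptor, chaperone condition, odorant and
concentration) are summarized as mean +/- SEM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: transfection conditions: OR alone (empty vector), each chaperone alone, both
RTP_CONDITIONS = ("none", "RTP1S", "RTP2", "both")

#: placeholder receptor name for empty-vector control wells
VECTOR_NAME = "pCI"

#: placeholder odorant name for 0-concentration (no-odorant) wells
VEHICLE_NAME = "vehicle"

MEASUREMENT_COLUMNS = ("plate_id", "well_id", "firefly", "renilla")
LAYOUT_COLUMNS = (
    "plate_id",
    "well_id",
    "or_name",
    "rtp_condition",
    "odorant",
    "concentration_uM",
)


class PlateDataError(ValueError):
    """Raised for malformed or inconsistent plate tables."""


@dataclass
class MeasurementSet:
    """Joined per-well measurements plus layout annotations.

    ``wells`` carries one row per usable well with columns: plate_id, well_id,
    firefly, renilla, or_name, rtp_condition, odorant, concentration (molar).
    ``dropped`` records wells removed for non-positive *Renilla* signal.
    """

    wells: pd.DataFrame
    normalization_scope: str = "per_batch"
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.normalization_scope not in ("per_batch", "per_plate"):
            raise PlateDataError(
                f"unknown normalization scope {self.normalization_scope!r}"
            )
        if len(self.wells) == 0:
            raise PlateDataError("MeasurementSet is empty")

    def __len__(self) -> int:
        return len(self.wells)

    def scope_keys(self) -> list[str]:
        """Grouping columns defining one normalization scope."""
        return ["plate_id"] if self.normalization_scope == "per_plate" else []


def luc_rl_ratio(firefly, renilla):
    """Firefly/Renilla luminescence ratio for a well (or arrays of wells).

    Raises :class:`PlateDataError` if any renilla reading is <= 0.
    """
    renilla_arr = np.asarray(renilla, dtype=float)
    if np.any(renilla_arr <= 0):
        raise PlateDataError("renilla luminescence must be > 0")
    ratio = np.asarray(firefly, dtype=float) / renilla_arr
    return float(ratio) if ratio.ndim == 0 else ratio


def read_measurements(
    measurement_table: str | Path | pd.DataFrame,
    layout_table: str | Path | pd.DataFrame,
    normalization_scope: str = "per_batch",
) -> MeasurementSet:
    """Join a raw measurement table to its plate layout.

    Both inputs are tidy delimited tables (TSV/CSV, one well per row) or
    already-loaded data frames. Layout concentrations are given in µM and
    converted to molar. Wells with renilla <= 0 are dropped with a warning;
    a well missing from the layout, or duplicated in it, is a hard error.
    """
    meas = _load_table(measurement_table, MEASUREMENT_COLUMNS, "measurement")
    layout = _load_table(layout_table, LAYOUT_COLUMNS, "layout")

    key = ["plate_id", "well_id"]
    dup = layout.duplicated(subset=key)
    if dup.any():
        bad = layout.loc[dup, key].iloc[0]
        raise PlateDataError(
            f"duplicate layout entry for well {bad.well_id!r} on plate "
            f"{bad.plate_id!r}"
        )

    joined = meas.merge(layout, on=key, how="left", indicator=True)
    missing = joined["_merge"] == "left_only"
    if missing.any():
        bad = joined.loc[missing, key].iloc[0]
        raise PlateDataError(
            f"well {bad.well_id!r} on plate {bad.plate_id!r} has no layout entry"
        )
    joined = joined.drop(columns="_merge")

    bad_condition = ~joined["rtp_condition"].isin(RTP_CONDITIONS)
    if bad_condition.any():
        raise PlateDataError(
            "unknown rtp_condition values: "
            f"{sorted(joined.loc[bad_condition, 'rtp_condition'].unique())}"
        )
    if (joined["concentration_uM"] < 0).any():
        raise PlateDataError("negative concentration in layout")
    zero_mismatch = (joined["concentration_uM"] == 0) != (
        joined["odorant"] == VEHICLE_NAME
    )
    if zero_mismatch.any():
        bad = joined.loc[zero_mismatch].iloc[0]
        raise PlateDataError(
            f"well {bad.well_id!r}: concentration 0 must pair with odorant "
            f"{VEHICLE_NAME!r} and vice versa"
        )

    joined["concentration"] = joined["concentration_uM"] * 1e-6  # molar
    joined = joined.drop(columns="concentration_uM")

    usable = joined["renilla"] > 0
    dropped = joined.loc[~usable].copy()
    if len(dropped):
        logger.warning(
            "dropping %d well(s) with renilla <= 0: %s",
            len(dropped),
            list(dropped["well_id"]),
        )
    return MeasurementSet(
        wells=joined.loc[usable].reset_index(drop=True),
        normalization_scope=normalization_scope,
        dropped=dropped.reset_index(drop=True),
    )


def normalize_activities(ms: MeasurementSet) -> pd.DataFrame:
    """Min-max normalize luc/RL ratios within each normalization scope.

    Returns the well table with two added columns: ``ratio`` (luc/RL) and
    ``activity`` (normalized to [0, 1] within scope). The first-encountered
    extremum wells define the 0 and 1 anchors; a scope whose ratios are all
    identical is degenerate and raises.
    """
    wells = ms.wells.copy()
    wells["ratio"] = luc_rl_ratio(wells["firefly"].to_numpy(), wells["renilla"].to_numpy())

    def _norm(ratios: pd.Series) -> pd.Series:
        lo, hi = ratios.min(), ratios.max()
        if hi <= lo:
            raise PlateDataError(
                "degenerate normalization scope: all luc/RL ratios identical"
            )
        return (ratios - lo) / (hi - lo)

    keys = ms.scope_keys()
    if keys:
        wells["activity"] = wells.groupby(keys, group_keys=False)["ratio"].transform(_norm)
    else:
        wells["activity"] = _norm(wells["ratio"])
    return wells


def summarize_replicates(normalized: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate wells to mean +/- SEM per condition.

    Groups by (or_name, rtp_condition, odorant, concentration). SEM uses the
    sample standard deviation (n-1 denominator); singleton groups get SEM 0
    and ``singleton = True``.
    """
    keys = ["or_name", "rtp_condition", "odorant", "concentration"]
    grouped = normalized.groupby(keys, sort=True)["activity"]
    # identical replicates have SEM exactly 0 (pandas std leaves ~1e-17 noise)
    out = grouped.agg(
        mean="mean",
        sd=lambda s: 0.0 if s.nunique() == 1 else s.std(ddof=1),
        n_replicates="count",
    )
    out = out.reset_index()
    singleton = out["n_replicates"] == 1
    out["sem"] = np.where(
        singleton, 0.0, out["sd"] / np.sqrt(out["n_replicates"])
    )
    out["singleton"] = singleton
    if singleton.any():
        logger.warning("%d singleton replicate group(s); SEM set to 0", singleton.sum())
    return out.drop(columns="sd")


def replicate_values(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-group replicate activity vectors, keyed like ``summarize_replicates``."""
    keys = ["or_name", "rtp_condition", "odorant", "concentration"]
    return (
        normalized.groupby(keys, sort=True)["activity"]
        .apply(lambda s: np.asarray(s, dtype=float))
        .reset_index()
        .rename(columns={"activity": "values"})
    )


def grid_to_tidy(grid: pd.DataFrame, plate_id: str, value_name: str) -> pd.DataFrame:
    """Convert a 96-well grid export (rows A-H x columns 1-12) to tidy rows."""
    long = grid.stack().reset_index()
    long.columns = ["row", "col", value_name]
    long["well_id"] = long["row"].astype(str) + long["col"].astype(str)
    long["plate_id"] = plate_id
    return long[["plate_id", "well_id", value_name]]


def _load_table(
    source: str | Path | pd.DataFrame, required: tuple[str, ...], label: str
) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if not path.exists():
            raise PlateDataError(f"{label} table not found: {path}")
        df = pd.read_csv(path, sep=None, engine="python")
    missing = set(required) - set(df.columns)
    if missing:
        raise PlateDataError(f"{label} table missing columns: {sorted(missing)}")
    return df
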