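"""Plate-reader data model and normalization chain.

Fluorescent-reporter screens of split inteins read out as microplate
fluorescence (mCherry, GFP, mTagBFP) together with culture density
(OD600).  The raw exports are normalized in a fixed chain:

1. :func:`blank_correct` — subtract the growth-medium background
   (fluorescence and absorbance) measured in blank wells;
2. :func:`fluo_per_od` — divide fluorescence by cell density to obtain
   the per-cell signal Fluo./OD600;
3. :func:`control_subtract` — subtract the Fluo./OD600 of cells carrying
   empty backbone plasmids (the negative control), then aggregate
   biological replicates to mean / sd / n.

Kinetic runs additionally use :func:`baseline_subtract` which removes
either each well's minimum or its t = 0 reading.

The canonical in-memory container (*SignalTable*) is a tidy
:class:`pandas.DataFrame` with columns ``plate_id, well, sample_id,
channel, time_s, value`` plus the layout columns ``role`` and
``replicate_group``.  Negative values produced by subtraction are kept
as-is (downstream classifiers floor them); clamping here would bias the
medians used by the orthogonality criterion.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    FormatError,
    InputError,
    LayoutError,
    PairingError,
)

#: Closed set of measurement channels.
CHANNELS = frozenset({"mCherry", "GFP", "mTagBFP", "OD600"})

#: Channels that are fluorescence (everything but cell density).
FLUOR_CHANNELS = frozenset(CHANNELS - {"OD600"})

#: Valid sample roles in a layout.
ROLES = frozenset({"test", "blank_medium", "negative_control", "standard"})

#: Columns every plate table must provide.
REQUIRED_COLUMNS = ("plate_id", "well", "sample_id", "channel", "time_s", "value")

#: OD600 below this (after blank correction) flags a well as non-growing.
DEFAULT_OD_FLOOR = 0.01


def read_layout(path: str | Path) -> pd.DataFrame:
    """Read a sample layout from TSV or JSON.

    TSV needs columns ``sample_id, role, replicate_group``; extra columns
    are carried along as metadata.  JSON is a list of objects with the
    same keys plus an optional ``metadata`` mapping that is flattened
    into columns.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        rows = []
        for rec in records:
            row = {k: v for k, v in rec.items() if k != "metadata"}
            row.update(rec.get("metadata", {}))
            rows.append(row)
        layout = pd.DataFrame(rows)
    else:
        layout = pd.read_csv(path, sep="\t")
    return validate_layout(layout)


def validate_layout(layout: pd.DataFrame) -> pd.DataFrame:
    for col in ("sample_id", "role", "replicate_group"):
        if col not in layout.columns:
            raise FormatError(f"layout is missing required column {col!r}")
    bad_roles = set(layout["role"]) - ROLES
    if bad_roles:
        raise LayoutError(f"unknown sample roles: {sorted(bad_roles)}")
    if layout["sample_id"].duplicated().any():
        dups = layout.loc[layout["sample_id"].duplicated(), "sample_id"].tolist()
        raise LayoutError(f"duplicate sample_id entries in layout: {dups}")
    return layout


def read_plate_table(path: str | Path, layout: pd.DataFrame) -> pd.DataFrame:
    """Read a long-format plate-reader CSV and join it to the layout.

    Row count is preserved: every reading in the file appears exactly
    once in the result, annotated with its layout ``role`` and
    ``replicate_group``.
    """
    table = pd.read_csv(path)
    return join_layout(table, layout)


def join_layout(table: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw readings table and attach layout annotations."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"plate table is missing required column {col!r}")
    layout = validate_layout(layout)

    unknown = set(table["channel"]) - CHANNELS
    if unknown:
        raise FormatError(
            f"unknown channel(s) {sorted(unknown)}; expected one of {sorted(CHANNELS)}"
        )
    if not np.isfinite(table["value"]).all():
        raise FormatError("plate table contains non-finite values")
    key = ["plate_id", "well", "channel", "time_s"]
    if table.duplicated(subset=key).any():
        raise FormatError(f"duplicate readings for the same {key}")

    missing = set(table["sample_id"]) - set(layout["sample_id"])
    if missing:
        raise LayoutError(f"sample(s) without a layout entry: {sorted(missing)}")

    n_before = len(table)
    joined = table.merge(
        layout[["sample_id", "role", "replicate_group"]], on="sample_id", how="left"
    )
    assert len(joined) == n_before
    return joined


def blank_correct(table: pd.DataFrame, per_time: bool = True) -> pd.DataFrame:
    """Subtract the medium background measured in blank wells.

    For every (plate, channel) — and, by default, every time point — the
    arithmetic mean of the ``blank_medium`` wells is subtracted from all
    other wells.  Blank wells are removed from the output.  Negative
    results are retained.

    Set ``per_time=False`` to subtract a single per-plate/channel blank
    (e.g. a pre-read blank) across all time points of a kinetic run.
    """
    if "role" not in table.columns:
        raise FormatError("table has no 'role' column; join a layout first")
    blanks = table[table["role"] == "blank_medium"]
    rest = table[table["role"] != "blank_medium"].copy()
    if rest.empty:
        return rest

    group_cols = ["plate_id", "channel"] + (["time_s"] if per_time else [])
    needed = rest[group_cols].drop_duplicates()
    blank_means = (
        blanks.groupby(group_cols)["value"].mean().rename("blank_mean").reset_index()
    )
    merged = needed.merge(blank_means, on=group_cols, how="left")
    if merged["blank_mean"].isna().any():
        absent = merged.loc[merged["blank_mean"].isna(), group_cols]
        raise ConfigurationError(
            "no blank_medium well for plate/channel group(s):\n"
            + absent.to_string(index=False)
        )
    rest = rest.merge(blank_means, on=group_cols, how="left")
    rest["value"] = rest["value"] - rest["blank_mean"]
    return rest.drop(columns="blank_mean")


def fluo_per_od(
    table: pd.DataFrame, od_floor: float = DEFAULT_OD_FLOOR
) -> pd.DataFrame:
    """Compute Fluo./OD600 per well and time point.

    Every fluorescence reading is divided by the OD600 reading of the
    same (plate, well, time).  Wells whose OD600 is below ``od_floor``
    are flagged (``low_od`` column) but not dropped, so non-growing
    cultures remain visible downstream.
    """
    fluo = table[table["channel"].isin(FLUOR_CHANNELS)].copy()
    od = table[table["channel"] == "OD600"]
    if fluo.empty:
        raise InputError("table contains no fluorescence readings")

    key = ["plate_id", "well", "time_s"]
    od_vals = od[key + ["value"]].rename(columns={"value": "od600"})
    merged = fluo.merge(od_vals, on=key, how="left")
    if merged["od600"].isna().any():
        absent = merged.loc[merged["od600"].isna(), key].drop_duplicates()
        raise PairingError(
            "fluorescence reading(s) without an OD600 partner:\n"
            + absent.to_string(index=False)
        )
    merged["ratio"] = merged["value"] / merged["od600"]
    merged["low_od"] = merged["od600"] < od_floor
    return merged


def control_subtract(
    signals: pd.DataFrame,
    control_group: str,
    value_col: str = "ratio",
) -> pd.DataFrame:
    """Subtract the negative-control signal and aggregate replicates.

    The mean ``value_col`` of the ``control_group`` replicates is
    subtracted from every other replicate (per channel), after which
    replicates are aggregated per ``replicate_group`` into
    ``sample_id, channel, mean, sd, n``.  With a single replicate the sd
    is reported as missing (NaN), never as zero.
    """
    if control_group not in set(signals["replicate_group"]):
        raise ConfigurationError(f"control group {control_group!r} not present")

    ctrl = signals[signals["replicate_group"] == control_group]
    rest = signals[signals["replicate_group"] != control_group].copy()

    ctrl_mean = ctrl.groupby("channel")[value_col].mean().rename("ctrl_mean")
    rest = rest.merge(ctrl_mean, on="channel", how="left")
    if rest["ctrl_mean"].isna().any():
        chans = rest.loc[rest["ctrl_mean"].isna(), "channel"].unique().tolist()
        raise ConfigurationError(f"control group has no readings for channel(s) {chans}")
    rest["corrected"] = rest[value_col] - rest["ctrl_mean"]

    agg = (
        rest.groupby(["replicate_group", "channel"])["corrected"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
        .rename(columns={"replicate_group": "sample_id"})
    )
    agg.loc[agg["n"] < 2, "sd"] = np.nan
    agg["n"] = agg["n"].astype(int)
    return agg


def baseline_subtract(
    table: pd.DataFrame,
    mode: str = "min",
    group_cols: tuple[str, ...] = ("plate_id", "well", "channel"),
    value_col: str = "value",
) -> pd.DataFrame:
    """Subtract each well's kinetic baseline.

    ``mode="min"`` subtracts the lowest value observed in the well's
    series (the result's minimum is exactly 0); ``mode="t0"`` subtracts
    the reading at the earliest time point (the result at t0 is 0).
    """
    if mode not in ("min", "t0"):
        raise InputError(f"unknown baseline mode {mode!r}; use 'min' or 't0'")
    if table.empty:
        raise InputError("empty series")
    out = table.copy()
    grouping = [c for c in group_cols if c in out.columns]
    if not grouping:
        raise InputError("no grouping columns present to identify wells")

    if mode == "min":
        base = out.groupby(grouping)[value_col].transform("min")
    else:
        if "time_s" not in out.columns:
            raise InputError("t0 mode requires a time_s column")
        first = (
            out.sort_values("time_s")
            .groupby(grouping, as_index=False)
            .first()[grouping + [value_col]]
            .rename(columns={value_col: "_t0"})
        )
        out = out.merge(first, on=grouping, how="left")
        base = out.pop("_t0")
    out[value_col] = out[value_col] - base.to_numpy()
    return out


def baseline_subtract_series(values, mode: str = "min"):
    """Baseline-subtract a single 1-D series (convenience wrapper)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("empty series")
    if mode == "min":
        return arr - arr.min()
    if mode == "t0":
        return arr - arr[0]
    raise InputError(f"unknown baseline mode {mode!r}")


def write_normalized(signals: pd.DataFrame, path: str | Path) -> None:
    """Write aggregated NormalizedSignal rows as tidy CSV."""
    signals.to_csv(path, index=False)
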