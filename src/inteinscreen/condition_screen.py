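"""Reaction-condition screening: pick one condition that serves every intein.

An in vitro trans-splicing screen varies buffer pH (8.0 / 9.0), NaCl
(100 / 300 / 500 mM) and incubation temperature (4 / 21 / 30 / 37 /
42 C) — 30 conditions per intein — and records an end-point reporter
signal per (intein, condition).  Because inteins differ hugely in
absolute signal, each intein's signals are first rescaled to its own
maximum; a condition's score is then an aggregate of those rescaled
values across inteins.

The default aggregate is ``min`` (maximize the worst intein), matching
the goal of one common condition usable for *any* combination of
inteins; ``median`` and ``mean`` are available.  DTT (2 mM) is a fixed
protocol constant, not a screened axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import FormatError, InputError, ShapeError

PH_LEVELS = (8.0, 9.0)
NACL_LEVELS_MM = (100, 300, 500)
TEMPERATURE_LEVELS_C = (4, 21, 30, 37, 42)
DTT_MM = 2.0

AGGREGATES = ("min", "median", "mean")


class Condition(NamedTuple):
    pH: float
    NaCl_mM: int
    temperature_C: int


def all_conditions() -> list[Condition]:
    """The full factorial grid (30 conditions)."""
    return [
        Condition(ph, na, t)
        for ph in PH_LEVELS
        for na in NACL_LEVELS_MM
        for t in TEMPERATURE_LEVELS_C
    ]


@dataclass
class ScreenResult:
    ranking: list[Condition]
    scores: pd.Series  # indexed by Condition, in ranking order
    selected: Condition
    aggregate: str
    excluded_inteins: list[str]


def score_conditions(grid: pd.DataFrame, aggregate: str = "min") -> ScreenResult:
    """Rank conditions by their aggregated per-intein rescaled signal.

    ``grid`` needs columns ``intein, pH, NaCl_mM, temperature_C, value``.
    Each intein's values are divided by its own maximum, so scores live
    in [0, 1] and are invariant to per-intein signal magnitude.  Inteins
    with no positive signal anywhere are excluded with a warning.  Ties
    in the aggregate break by median score, then by lexicographic
    condition tuple; ``selected`` is the top of the ranking.
    """
    if aggregate not in AGGREGATES:
        raise InputError(f"aggregate must be one of {AGGREGATES}, got {aggregate!r}")
    for col in ("intein", "pH", "NaCl_mM", "temperature_C", "value"):
        if col not in grid.columns:
            raise FormatError(f"condition grid is missing column {col!r}")

    grid = grid.copy()
    maxima = grid.groupby("intein")["value"].max()
    dead = maxima[maxima <= 0].index.tolist()
    if dead:
        warnings.warn(
            f"intein(s) with no positive signal excluded from the screen: {dead}",
            stacklevel=2,
        )
        grid = grid[~grid["intein"].isin(dead)]
    if grid.empty:
        raise InputError("no intein with a positive signal; nothing to score")

    grid["scaled"] = grid["value"] / grid["intein"].map(maxima)
    pivot = grid.pivot_table(
        index=["pH", "NaCl_mM", "temperature_C"],
        columns="intein",
        values="scaled",
        aggfunc="mean",
    )
    if pivot.isna().any().any():
        holes = pivot.isna().stack()
        holes = holes[holes].index.tolist()
        raise ShapeError(f"missing (condition, intein) cell(s): {holes}")

    agg_fn = {"min": np.min, "median": np.median, "mean": np.mean}[aggregate]
    score = pivot.apply(agg_fn, axis=1)
    tiebreak = pivot.median(axis=1)

    rows = [
        (Condition(*idx), s, tb) for idx, s, tb in zip(score.index, score, tiebreak)
    ]
    # descending score, descending median, ascending condition tuple
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    ranking = [r[0] for r in rows]
    index = pd.MultiIndex.from_tuples(ranking, names=["pH", "NaCl_mM", "temperature_C"])
    scores = pd.Series([r[1] for r in rows], index=index)
    return ScreenResult(ranking, scores, ranking[0], aggregate, dead)
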