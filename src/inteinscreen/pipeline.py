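"""End-to-end glue: raw plate exports -> normalized signals -> cross matrix."""

from __future__ import annotations

import pandas as pd

from . import plate_data
from .orthogonality import CrossMatrix


def normalized_signals_from_plates(
    readings: pd.DataFrame,
    layout: pd.DataFrame,
    control_group: str = "neg_ctrl",
    per_time: bool = True,
) -> pd.DataFrame:
    """Run the full normalization chain on raw readings.

    Blank-corrects fluorescence and OD600, forms Fluo./OD600, subtracts
    the negative control, and aggregates replicates to mean/sd/n per
    replicate group and channel.
    """
    table = plate_data.join_layout(readings, layout)
    corrected = plate_data.blank_correct(table, per_time=per_time)
    ratios = plate_data.fluo_per_od(corrected)
    return plate_data.control_subtract(ratios, control_group)


def cross_matrix_from_plates(
    readings: pd.DataFrame,
    layout: pd.DataFrame,
    pairing: dict,
    control_group: str = "neg_ctrl",
    channel: str = "mCherry",
) -> CrossMatrix:
    """Normalize plate readings and assemble the N x C cross-reactivity matrix."""
    signals = normalized_signals_from_plates(readings, layout, control_group)
    signals = signals[signals["channel"] == channel]
    return CrossMatrix.from_signals(signals, pairing)
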