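"""Splicing efficiency from Western-blot band-intensity tables.

A cis- or trans-splicing reaction resolves on a blot into the spliced
reporter, unreacted precursor(s) and N-/C-cleavage by-products.  Two
antibody channels are imaged — one against the reporter's N-terminal
epitope, one against the C-terminal His6 tag — on (typically) two
membranes, giving n = 4 quantifications per sample.

Per channel x membrane the efficiency is

    spliced / sum(intensity of every species that antibody can see)

and the reported estimate is the mean +/- sd over the four values.  The
set of species visible to each antibody is an explicit
:data:`EpitopeMap`; whether cleavage by-products enter the denominator
is therefore a configuration choice (they do by default).

Band-to-species assignment is an input: this module starts from
intensity tables, not images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FormatError, InputError

CHANNELS = frozenset({"anti_mCherry_N", "anti_His_C"})

SPECIES = frozenset(
    {"precursor", "spliced", "n_cleavage", "c_cleavage", "n_precursor", "c_precursor", "other"}
)

#: Which species each antibody detects.  The N-terminal antibody sees
#: everything carrying the reporter's N-half; the anti-His antibody sees
#: everything carrying the C-terminal tag.  Both see the spliced product.
DEFAULT_EPITOPE_MAP: dict[str, frozenset[str]] = {
    "anti_mCherry_N": frozenset({"precursor", "spliced", "n_cleavage", "n_precursor"}),
    "anti_His_C": frozenset({"precursor", "spliced", "c_cleavage", "c_precursor"}),
}


@dataclass
class EfficiencyEstimate:
    """Splicing-efficiency estimate aggregated over channel x membrane.

    ``mean`` is None when any channel x membrane had zero total signal
    (the not-detected outcome); ``n`` counts the band-signal
    quantifications that entered the estimate.
    """

    sample_id: str
    mean: float | None
    sd: float | None
    n: int
    detected: bool = True


def _validate_epitope_map(emap: dict) -> dict:
    for ch, species in emap.items():
        if ch not in CHANNELS:
            raise FormatError(f"unknown antibody channel {ch!r}")
        if not species:
            raise FormatError(f"epitope map for {ch!r} is empty")
        if "spliced" not in species:
            raise FormatError(f"spliced product must be visible in channel {ch!r}")
        bad = set(species) - SPECIES
        if bad:
            raise FormatError(f"unknown species {sorted(bad)} in channel {ch!r}")
    return emap


def _validate_bands(bands: pd.DataFrame) -> pd.DataFrame:
    for col in ("lane_id", "membrane_id", "channel", "species", "intensity"):
        if col not in bands.columns:
            raise FormatError(f"band table is missing column {col!r}")
    bad_ch = set(bands["channel"]) - CHANNELS
    if bad_ch:
        raise FormatError(f"unknown channel(s) {sorted(bad_ch)}")
    bad_sp = set(bands["species"]) - SPECIES
    if bad_sp:
        raise FormatError(f"unknown species {sorted(bad_sp)}")
    if (bands["intensity"] < 0).any():
        raise FormatError("band intensities must be >= 0")
    key = ["lane_id", "membrane_id", "channel", "species"]
    if bands.duplicated(subset=key).any():
        raise FormatError(f"duplicate band records for the same {key}")
    return bands


def splicing_efficiency(
    bands: pd.DataFrame,
    emap: dict | None = None,
    sample_id: str = "",
) -> EfficiencyEstimate:
    """Estimate splicing efficiency from one sample's band records.

    Efficiency is computed independently for every channel x membrane
    (spliced over the summed epitope-visible intensities) and averaged;
    ``n`` is the number of such quantifications (4 for two antibodies on
    two membranes).  If any quantification has zero total signal the
    whole estimate is reported as not detected.
    """
    emap = _validate_epitope_map(emap or DEFAULT_EPITOPE_MAP)
    bands = _validate_bands(bands)

    effs = []
    groups = bands.groupby(["channel", "membrane_id"], sort=True)
    for (channel, _membrane), sub in groups:
        visible = sub[sub["species"].isin(emap[channel])]
        if "spliced" not in set(visible["species"]):
            raise InputError(
                f"no spliced-band record in channel {channel!r}; add one "
                "(zero intensity is allowed)"
            )
        total = visible["intensity"].sum()
        spliced = visible.loc[visible["species"] == "spliced", "intensity"].sum()
        if total <= 0:
            return EfficiencyEstimate(sample_id, None, None, len(groups), detected=False)
        effs.append(spliced / total)

    arr = np.asarray(effs)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return EfficiencyEstimate(sample_id, float(arr.mean()), sd, arr.size)


def spliced_fraction_timecourse(
    bands: pd.DataFrame,
    emap: dict | None = None,
    time_col: str = "time_s",
) -> pd.DataFrame:
    """Splicing efficiency at each sampled time point (no smoothing).

    ``bands`` must carry a time column; each time point is quantified
    independently with :func:`splicing_efficiency`.  Requires at least
    two time points.
    """
    if time_col not in bands.columns:
        raise FormatError(f"band table is missing time column {time_col!r}")
    times = sorted(bands[time_col].unique())
    if len(times) < 2:
        raise InputError(f"timecourse needs >= 2 time points, got {len(times)}")
    rows = []
    for t in times:
        est = splicing_efficiency(bands[bands[time_col] == t], emap)
        rows.append(
            {time_col: t, "mean": est.mean, "sd": est.sd, "n": est.n, "detected": est.detected}
        )
    return pd.DataFrame(rows)
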