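"""Activity calling and kinetic classification of splicing reactions.

Three threshold rules, all strict, decide activity:

* cis in vivo — background-subtracted Fluo./OD600 above 2000 a.u.;
* in vitro   — end-point fluorescence above 4000 a.u. AND spliced
  product above 10% of the cohort maximum (the most efficient intein);
* kinetics   — a reaction is *fast* when the signal at 1 h (linearly
  interpolated) exceeds 75% of the observed plateau.

The plateau used for classification is the observed series maximum, not
a fitted asymptote; :func:`fit_first_order` separately fits a delayed
first-order model A(1 - exp(-k (t - d)+)) — the delay d absorbs the lag
between splicing and detection caused by fluorophore maturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import FitError, InputError, UndefinedReferenceError

CIS_THRESHOLD_AU = 2000.0
INVITRO_FLUO_THRESHOLD_AU = 4000.0
INVITRO_FRAC_THRESHOLD = 0.10
FAST_FRACTION = 0.75
FAST_CUTOFF_S = 3600.0


@dataclass
class ActivityCall:
    sample_id: str
    context: str  # cis_in_vivo | trans_in_vivo | in_vitro
    signal: float
    active: bool
    spliced_fraction_of_max: float | None = None


@dataclass
class KineticProfile:
    """A single well's splicing time course."""

    sample_id: str
    times: np.ndarray
    values: np.ndarray
    fast: bool | None = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise InputError("times and values differ in length")
        if self.times.size == 0:
            raise InputError("empty kinetic series")
        order = np.argsort(self.times)
        self.times = self.times[order]
        self.values = self.values[order]

    @property
    def plateau(self) -> float:
        """Observed maximum of the series."""
        return float(self.values.max())

    def value_at(self, t: float) -> float:
        """Linear interpolation between sampled time points."""
        return float(np.interp(t, self.times, self.values))

    def frac_at(self, t: float) -> float:
        p = self.plateau
        if p <= 0:
            raise InputError("plateau is not positive; fraction undefined")
        return self.value_at(t) / p


def call_cis_active(
    sample_id: str, mean_signal: float, threshold: float = CIS_THRESHOLD_AU
) -> ActivityCall:
    """cis-splicing call: active iff the signal is strictly above threshold."""
    if not np.isfinite(mean_signal):
        raise InputError(f"signal for {sample_id!r} is not finite")
    return ActivityCall(sample_id, "cis_in_vivo", mean_signal, mean_signal > threshold)


def call_invitro_active(
    sample_id: str,
    signal: float,
    spliced_rel_max: float,
    fluo_threshold: float = INVITRO_FLUO_THRESHOLD_AU,
    frac_threshold: float = INVITRO_FRAC_THRESHOLD,
) -> ActivityCall:
    """In vitro call: fluorescence AND spliced-fraction rules, both strict."""
    active = (signal > fluo_threshold) and (spliced_rel_max > frac_threshold)
    return ActivityCall(sample_id, "in_vitro", signal, active, spliced_rel_max)


def call_invitro_cohort(
    signals: pd.DataFrame,
    fluo_threshold: float = INVITRO_FLUO_THRESHOLD_AU,
    frac_threshold: float = INVITRO_FRAC_THRESHOLD,
) -> list[ActivityCall]:
    """Call a whole in vitro cohort.

    ``signals`` needs columns ``sample_id, signal, spliced``; each
    sample's spliced level is referenced to the cohort maximum before
    the 10%-of-max rule is applied.
    """
    max_spliced = signals["spliced"].max()
    if max_spliced <= 0:
        raise UndefinedReferenceError("cohort maximum spliced level is 0")
    return [
        call_invitro_active(
            row["sample_id"],
            row["signal"],
            row["spliced"] / max_spliced,
            fluo_threshold,
            frac_threshold,
        )
        for _, row in signals.iterrows()
    ]


def classify_fast(
    profile: KineticProfile,
    frac: float = FAST_FRACTION,
    t_cut: float = FAST_CUTOFF_S,
) -> KineticProfile:
    """Mark a profile fast iff its value at ``t_cut`` exceeds ``frac`` x plateau.

    The series must cover ``t_cut``.  An all-zero (or non-positive)
    series is not classifiable and leaves ``fast`` as None.  The call is
    invariant to rescaling the whole series by a positive constant.
    """
    if profile.times.max() < t_cut:
        raise InputError(
            f"series ends at {profile.times.max():.0f} s, before the {t_cut:.0f} s cutoff"
        )
    if profile.plateau <= 0:
        profile.fast = None
        return profile
    profile.fast = profile.value_at(t_cut) > frac * profile.plateau
    return profile


@dataclass
class FirstOrderFit:
    rate_per_s: float
    plateau: float
    delay_s: float
    residual_norm: float


def fit_first_order(
    profile: KineticProfile, delay: float | None = None
) -> FirstOrderFit:
    """Least-squares fit of A(1 - exp(-k (t - d)+)) to a time course.

    If ``delay`` is given, d is held fixed at that value; otherwise it
    is fitted (bounded at >= 0).  Needs at least 4 time points and a
    non-constant series.
    """
    t, y = profile.times, profile.values
    if t.size < 4:
        raise InputError(f"first-order fit needs >= 4 time points, got {t.size}")
    if np.ptp(y) == 0:
        raise FitError("constant series: rate is unidentifiable")

    a0 = max(y.max(), 1e-12)
    # crude initial rate from the time of half-rise
    above = np.nonzero(y >= 0.5 * a0)[0]
    t_half = t[above[0]] if above.size else t[-1]
    k0 = np.log(2) / max(t_half, (t[1] - t[0]) if t.size > 1 else 1.0)

    if delay is None:

        def model(tt, a, k, d):
            return a * (1.0 - np.exp(-k * np.clip(tt - d, 0.0, None)))

        p0 = (a0, k0, 0.0)
        bounds = ([0.0, 1e-12, 0.0], [np.inf, np.inf, float(t.max())])
    else:

        def model(tt, a, k):
            return a * (1.0 - np.exp(-k * np.clip(tt - delay, 0.0, None)))

        p0 = (a0, k0)
        bounds = ([0.0, 1e-12], [np.inf, np.inf])

    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"first-order fit did not converge: {exc}") from exc

    resid = y - model(t, *popt)
    d = float(popt[2]) if delay is None else float(delay)
    return FirstOrderFit(float(popt[1]), float(popt[0]), d, float(np.linalg.norm(resid)))
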