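"""Synthetic datasets with ground truth for recovery testing.

Every analysis in this package was designed against plate-reader and
blot exports whose raw values are not redistributable, so this module
generates structurally matched stand-ins: cognate-pair fluorescence
with replicate noise (n = 3 biological replicates), sparse low-level
non-cognate cross-talk with optional planted violators, medium blanks
and negative-control background, OD600 variation, first-order splicing
kinetics with a reporter-maturation delay, and dual-channel band
intensity tables.  Each generator returns the dataset together with a
:class:`SyntheticTruth` so recovery can be asserted against known
parameters.

Noise model: fluorescence and band intensities get multiplicative
lognormal noise (positive signals, roughly constant CV); OD600 gets
additive Gaussian noise.  Non-cognate relative levels are drawn from an
exponential with mean 0.01 by default, giving the sparse cross-talk
structure real orthogonality matrices show.  All draws come from
``numpy.random.default_rng(seed)`` in a fixed order, so identical
configs produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .condition_screen import Condition, all_conditions
from .exceptions import ConfigurationError
from .orthogonality import CrossMatrix, OrthoConfig, SplitPair, classify_all

HOUR_S = 3600.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study.

    The defaults emulate the study conditions of the screens this
    package analyzes: 16 parent inteins contributing 24 split pairs,
    three biological replicates, replicate CV of 10%, sparse exponential
    cross-talk (mean 0.01 relative to cognate), and kinetics with a
    ~20 min maturation delay sampled every 5 min 24 s for 20 h.
    """

    seed: int
    # cross-reactivity matrix
    n_inteins: int = 16
    split_variants: tuple[tuple[str, tuple[str, ...]], ...] | None = None
    cognate_mean: float = 20000.0  # a.u. Fluo./OD600 of a cognate pair
    cognate_cv: float = 0.10  # multiplicative replicate CV on fluorescence
    crosstalk_mean: float = 0.01  # exponential mean of non-cognate relative level
    planted_violators: tuple[tuple[str, float], ...] = ()
    replicate_n: int = 3
    # plate background
    blank_mean: float = 100.0  # medium fluorescence, a.u.
    od_blank: float = 0.04  # medium absorbance
    od_mean: float = 0.5  # cell density of grown cultures
    od_cv: float = 0.05
    control_ratio: float = 300.0  # negative-control Fluo./OD600
    # kinetics
    rate_per_s: float = 1.4 / HOUR_S
    delay_s: float = 1200.0
    plateau: float = 1.0
    kinetic_noise_sd: float = 0.0
    t_max_s: float = 20 * HOUR_S
    dt_s: float = 324.0  # 5 min 24 s sampling interval
    # densitometry
    true_efficiency: float = 0.9
    band_noise_cv: float = 0.05
    band_total: float = 1000.0

    def __post_init__(self):
        if self.replicate_n < 1:
            raise ConfigurationError("replicate_n must be >= 1")
        for name in ("cognate_cv", "crosstalk_mean", "od_cv", "band_noise_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.cognate_mean <= self.blank_mean:
            raise ConfigurationError(
                "degenerate config: cognate_mean must exceed blank_mean "
                f"({self.cognate_mean} <= {self.blank_mean})"
            )
        if not (0 <= self.true_efficiency <= 1):
            raise ConfigurationError("true_efficiency must lie in [0, 1]")
        if self.plateau < 0:
            raise ConfigurationError("plateau must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth paired with a generated dataset."""

    config: GeneratorConfig
    pairs: list[SplitPair] | None = None
    rel_matrix: np.ndarray | None = None  # true relative levels, diagonal 1
    pairing: dict | None = None  # sample_id -> (row pair, col pair)
    orthogonal_pairs: list[SplitPair] | None = None
    violators: list[SplitPair] = field(default_factory=list)
    active_labels: pd.Series | None = None
    rates: pd.DataFrame | None = None
    efficiency: float | None = None
    selected_condition: Condition | None = None

    def to_json(self, path: str | Path) -> None:
        out = {"config": dataclasses.asdict(self.config)}
        if self.pairs is not None:
            out["pairs"] = [p.label for p in self.pairs]
        if self.rel_matrix is not None:
            out["rel_matrix"] = np.round(self.rel_matrix, 9).tolist()
        if self.orthogonal_pairs is not None:
            out["orthogonal_pairs"] = [p.label for p in self.orthogonal_pairs]
        if self.violators:
            out["violators"] = [p.label for p in self.violators]
        if self.efficiency is not None:
            out["efficiency"] = self.efficiency
        if self.selected_condition is not None:
            out["selected_condition"] = list(self.selected_condition)
        Path(path).write_text(json.dumps(out, indent=2, sort_keys=True))


# ----------------------------------------------------------------- helpers
def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def default_pairs(cfg: GeneratorConfig) -> list[SplitPair]:
    """Split-pair roster: n_inteins parents, 24 pairs under the defaults.

    With 16 parents the first eight contribute two split variants
    (S2 and S3) and the rest one (S2), matching a 24-pair screen.
    """
    if cfg.split_variants is not None:
        return [
            SplitPair(intein, site)
            for intein, sites in cfg.split_variants
            for site in sites
        ]
    n_two = min(max(0, 24 - cfg.n_inteins), cfg.n_inteins)
    pairs = []
    for i in range(cfg.n_inteins):
        name = f"Int{i + 1:02d}"
        sites = ("S2", "S3") if i < n_two else ("S2",)
        pairs.extend(SplitPair(name, s) for s in sites)
    return pairs


def _pair_label(p: SplitPair) -> str:
    return p.label


def gen_cross_matrix_truth(cfg: GeneratorConfig) -> SyntheticTruth:
    """Draw the true relative cross-talk matrix (no measurement noise).

    Off-diagonal relative levels are exponential(crosstalk_mean); a
    planted violator ``(pair_label, level)`` overwrites that pair's
    whole row and column with ``level``.  The true orthogonal set is
    obtained by classifying the noiseless matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs = default_pairs(cfg)
    k = len(pairs)
    rel = rng.exponential(cfg.crosstalk_mean, size=(k, k))
    np.fill_diagonal(rel, 1.0)

    labels = {p.label: i for i, p in enumerate(pairs)}
    violators = []
    for label, level in cfg.planted_violators:
        if label not in labels:
            raise ConfigurationError(f"planted violator {label!r} is not in the roster")
        i = labels[label]
        mask = np.arange(k) != i
        rel[i, mask] = level
        rel[mask, i] = level
        violators.append(pairs[i])

    truth_matrix = CrossMatrix(pairs, cfg.cognate_mean * rel)
    calls = classify_all(truth_matrix, OrthoConfig())
    ortho = [c.pair for c in calls if c.orthogonal]
    return SyntheticTruth(
        cfg, pairs=pairs, rel_matrix=rel, orthogonal_pairs=ortho, violators=violators
    )


def gen_cross_matrix(cfg: GeneratorConfig) -> tuple[CrossMatrix, SyntheticTruth]:
    """Noisy cross matrix at the signal level (replicate means, no plate layer).

    Each cell is the mean of ``replicate_n`` lognormal-noised draws
    around ``cognate_mean * rel``; use this for Monte-Carlo studies of
    the classifier where the plate-normalization layer is not under
    test (:func:`gen_cross_matrix_readings` exercises the full chain).
    """
    truth = gen_cross_matrix_truth(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    k = len(truth.pairs)
    noise = _lognormal_factor(rng, cfg.cognate_cv, (k, k, cfg.replicate_n))
    cells = cfg.cognate_mean * truth.rel_matrix[:, :, None] * noise
    return CrossMatrix(truth.pairs, cells.mean(axis=2)), truth


def gen_cross_matrix_readings(
    cfg: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Emit raw plate readings whose processed matrix recovers the truth.

    Wells are laid out on virtual 96-well plates, each carrying 30
    combinations x replicate_n test wells plus 3 medium blanks and 3
    negative-control wells, read in mCherry and OD600.  Running the
    normalization chain (blank correction, Fluo./OD600, negative-control
    subtraction) and building the cross matrix recovers
    ``cognate_mean * rel`` up to replicate noise.
    """
    truth = gen_cross_matrix_truth(cfg)
    rng = np.random.default_rng(cfg.seed + 1)  # independent of the truth draw
    pairs, rel = truth.pairs, truth.rel_matrix
    k = len(pairs)

    combos = [(i, j) for i in range(k) for j in range(k)]
    pairing = {
        f"{pairs[i].label}|{pairs[j].label}": (pairs[i], pairs[j]) for i, j in combos
    }
    truth.pairing = pairing

    well_names = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    per_plate = 90 // cfg.replicate_n  # combos per plate, 3 blank + 3 ctrl wells spare
    readings, layout_rows = [], {}

    def add_well(plate, well, sample_id, role, group, fluo, od):
        readings.append((plate, well, sample_id, "mCherry", 0.0, fluo))
        readings.append((plate, well, sample_id, "OD600", 0.0, od))
        layout_rows[sample_id] = (sample_id, role, group)

    for chunk_idx in range(0, len(combos), per_plate):
        plate = f"P{chunk_idx // per_plate + 1:02d}"
        chunk = combos[chunk_idx : chunk_idx + per_plate]
        widx = 0
        for i, j in chunk:
            sid = f"{pairs[i].label}|{pairs[j].label}"
            signal = cfg.cognate_mean * rel[i, j]
            for _ in range(cfg.replicate_n):
                od_cells = max(
                    cfg.od_mean * (1 + rng.normal(0, cfg.od_cv)), 0.05 * cfg.od_mean
                )
                noise = _lognormal_factor(rng, cfg.cognate_cv, None)
                fluo = cfg.blank_mean + od_cells * (cfg.control_ratio + signal) * noise
                od = cfg.od_blank + od_cells + rng.normal(0, 0.002)
                add_well(plate, well_names[widx], sid, "test", sid, fluo, od)
                widx += 1
        for _ in range(3):
            fluo = cfg.blank_mean * _lognormal_factor(rng, 0.05, None)
            od = cfg.od_blank + rng.normal(0, 0.001)
            add_well(plate, well_names[widx], "blank", "blank_medium", "blank", fluo, od)
            widx += 1
        for _ in range(3):
            od_cells = max(
                cfg.od_mean * (1 + rng.normal(0, cfg.od_cv)), 0.05 * cfg.od_mean
            )
            noise = _lognormal_factor(rng, cfg.cognate_cv, None)
            fluo = cfg.blank_mean + od_cells * cfg.control_ratio * noise
            od = cfg.od_blank + od_cells + rng.normal(0, 0.002)
            add_well(
                plate, well_names[widx], "neg_ctrl", "negative_control", "neg_ctrl", fluo, od
            )
            widx += 1

    table = pd.DataFrame(
        readings, columns=["plate_id", "well", "sample_id", "channel", "time_s", "value"]
    )
    layout = pd.DataFrame(
        layout_rows.values(), columns=["sample_id", "role", "replicate_group"]
    )
    return table, layout, truth


def gen_kinetic_traces(
    cfg: GeneratorConfig,
    rates_per_s: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Delayed first-order traces A(1 - exp(-k (t - d)+)) + Gaussian noise.

    ``rates_per_s`` maps sample_id to rate; by default one trace with
    the config rate is produced.  Sampling follows the config's interval
    and span.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    rates = rates_per_s or {"trace1": cfg.rate_per_s}
    times = np.arange(0.0, cfg.t_max_s + cfg.dt_s / 2, cfg.dt_s)
    rows = []
    for sid, k in sorted(rates.items()):
        clean = cfg.plateau * (1 - np.exp(-k * np.clip(times - cfg.delay_s, 0, None)))
        noisy = clean + rng.normal(0, cfg.kinetic_noise_sd, size=times.size)
        rows.append(pd.DataFrame({"sample_id": sid, "time_s": times, "value": noisy}))
    truth = SyntheticTruth(
        cfg,
        rates=pd.DataFrame(
            {
                "sample_id": sorted(rates),
                "rate_per_s": [rates[s] for s in sorted(rates)],
                "delay_s": cfg.delay_s,
                "plateau": cfg.plateau,
            }
        ),
    )
    return pd.concat(rows, ignore_index=True), truth


def gen_band_table(
    cfg: GeneratorConfig, sample_id: str = "S1"
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Dual-antibody, two-membrane band table at the configured efficiency.

    Each of the four channel x membrane quantifications carries
    independent multiplicative lognormal noise, so the per-quantification
    efficiencies scatter around the truth.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    e, total = cfg.true_efficiency, cfg.band_total
    rows = []
    for membrane in ("M1", "M2"):
        for channel in ("anti_mCherry_N", "anti_His_C"):
            spliced = e * total * _lognormal_factor(rng, cfg.band_noise_cv, None)
            precursor = (1 - e) * total * _lognormal_factor(rng, cfg.band_noise_cv, None)
            rows.append((sample_id, membrane, channel, "spliced", spliced))
            rows.append((sample_id, membrane, channel, "precursor", precursor))
    bands = pd.DataFrame(
        rows, columns=["lane_id", "membrane_id", "channel", "species", "intensity"]
    )
    return bands, SyntheticTruth(cfg, efficiency=e)


def gen_activity_cohort(
    cfg: GeneratorConfig,
    n_total: int = 34,
    n_active: int = 22,
    threshold: float = 2000.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Cis-splicing cohort with a planted number of above-threshold cultures.

    Mirrors the structure of a 34-culture screen with 22 actives: active
    signals land in [2x, 15x] threshold, inactive ones below half of it.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    active = np.zeros(n_total, dtype=bool)
    active[rng.permutation(n_total)[:n_active]] = True
    signal = np.where(
        active,
        threshold * rng.uniform(2.0, 15.0, n_total),
        threshold * rng.uniform(0.0, 0.5, n_total),
    )
    df = pd.DataFrame(
        {"sample_id": [f"culture{i + 1:02d}" for i in range(n_total)], "signal": signal}
    )
    truth = SyntheticTruth(cfg, active_labels=pd.Series(active, index=df["sample_id"]))
    return df, truth


def gen_invitro_cohort(
    cfg: GeneratorConfig,
    n_total: int = 24,
    n_active: int = 12,
    fluo_threshold: float = 4000.0,
    frac_threshold: float = 0.10,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """In vitro cohort passing/failing the conjunction rule by construction.

    Actives clear both the fluorescence and the fraction-of-max rule;
    planted inactives fail either the fluorescence rule (half) or the
    spliced-fraction rule (half).
    """
    rng = np.random.default_rng(cfg.seed + 5)
    active = np.zeros(n_total, dtype=bool)
    active[rng.permutation(n_total)[:n_active]] = True

    scale = cfg.band_total  # arbitrary densitometry units for spliced levels
    signal = np.empty(n_total)
    spliced = np.empty(n_total)
    low_fluo_toggle = True
    for idx in range(n_total):
        if active[idx]:
            signal[idx] = rng.uniform(2.0, 8.0) * fluo_threshold
            spliced[idx] = rng.uniform(0.3, 1.0) * scale
        elif low_fluo_toggle:
            signal[idx] = rng.uniform(0.1, 0.8) * fluo_threshold
            spliced[idx] = rng.uniform(0.0, 0.05) * scale
            low_fluo_toggle = False
        else:
            signal[idx] = rng.uniform(2.0, 5.0) * fluo_threshold
            spliced[idx] = rng.uniform(0.0, frac_threshold * 0.8) * scale
            low_fluo_toggle = True
    spliced[np.argmax(active)] = scale  # pin the cohort maximum to an active pair

    df = pd.DataFrame(
        {
            "sample_id": [f"pair{i + 1:02d}" for i in range(n_total)],
            "signal": signal,
            "spliced": spliced,
        }
    )
    truth = SyntheticTruth(cfg, active_labels=pd.Series(active, index=df["sample_id"]))
    return df, truth


def gen_condition_grid(
    cfg: GeneratorConfig,
    n_inteins: int = 10,
    planted: Condition = Condition(9.0, 100, 21),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Condition-screen grid whose max-min optimum is the planted condition.

    Each synthetic intein peaks at its own (rotating) personal optimum,
    scores 0.85 of its maximum at the planted condition, and 0.1-0.7
    elsewhere — so the planted condition is the unique best worst-case
    choice while no intein is actually maximal there.
    """
    rng = np.random.default_rng(cfg.seed + 6)
    conditions = all_conditions()
    others = [c for c in conditions if c != planted]
    rows = []
    for i in range(n_inteins):
        personal = others[i % len(others)]
        max_i = cfg.cognate_mean * _lognormal_factor(rng, 0.3, None)
        for c in conditions:
            if c == personal:
                v = max_i
            elif c == planted:
                v = 0.85 * max_i
            else:
                v = rng.uniform(0.1, 0.7) * max_i
            rows.append((f"vInt{i + 1:02d}", c.pH, c.NaCl_mM, c.temperature_C, v))
    grid = pd.DataFrame(rows, columns=["intein", "pH", "NaCl_mM", "temperature_C", "value"])
    return grid, SyntheticTruth(cfg, selected_condition=planted)


# ------------------------------------------------------------- file output
def write_cross_matrix_dataset(cfg: GeneratorConfig, out_dir: str | Path) -> SyntheticTruth:
    """Write plate.csv / layout.tsv / truth.json; byte-identical per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, layout, truth = gen_cross_matrix_readings(cfg)
    table.to_csv(out / "plate.csv", index=False, float_format="%.6f")
    layout.to_csv(out / "layout.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
    return truth


def write_kinetics_dataset(cfg: GeneratorConfig, out_dir: str | Path) -> SyntheticTruth:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces, truth = gen_kinetic_traces(cfg)
    traces.to_csv(out / "kinetics.csv", index=False, float_format="%.8f")
    truth.to_json(out / "truth.json")
    return truth


def write_band_dataset(cfg: GeneratorConfig, out_dir: str | Path) -> SyntheticTruth:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bands, truth = gen_band_table(cfg)
    bands.to_csv(out / "bands.csv", index=False, float_format="%.6f")
    truth.to_json(out / "truth.json")
    return truth
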