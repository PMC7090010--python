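"""Planning and yield simulation of intein-mediated modular protein assembly.

Large repetitive proteins (the working example is chains of SasG5^3 E^2
units — three G5 and two E domains each) are hard to clone and express
as single genes; instead, units fused to orthogonal split-intein halves
are spliced together in vitro.  Two schemes are supported:

one-pot
    All n units react simultaneously; every junction needs its own
    orthogonal intein, so n units consume n - 1 distinct inteins and n
    distinct unit designs.

solid-phase (recursive)
    The chain grows on a resin, one unit per cycle, with only two
    orthogonal inteins alternating along the junctions.  Unit designs
    saturate at four (tagged start, two alternating internals, tagged
    end); n units need n - 1 cycles.

Incomplete splicing produces a ladder of truncated by-products;
:func:`simulate_yield` computes the exact species distribution from
per-junction success probabilities (and can cross-check it by seeded
stochastic simulation).  Failed solid-phase junctions are modelled as
permanently truncating the resin-bound chain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .exceptions import (
    CapacityError,
    InputError,
    MissingSequenceError,
    OrthogonalityError,
    ParameterError,
)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

TAGS = ("none", "H6", "Strep")

#: Domain counts of one SasG5^3 E^2 building unit.
SASG_UNIT_G5 = 3
SASG_UNIT_E = 2


@dataclass(frozen=True)
class InteinSpec:
    """A split intein usable at an assembly junction.

    ``junction_pref`` holds the six preferred extein residues flanking
    the splice junction (-3..-1 upstream, +1..+3 downstream).
    """

    name: str
    junction_pref: str
    orthogonal_group: str = ""

    def __post_init__(self):
        if len(self.junction_pref) != 6:
            raise InputError(
                f"junction_pref of {self.name!r} must be 6 residues "
                f"(-3..+3), got {len(self.junction_pref)}"
            )
        bad = set(self.junction_pref.upper()) - AA_ALPHABET
        if bad:
            raise InputError(f"invalid amino acids {sorted(bad)} in junction_pref")


@dataclass
class AssemblyUnit:
    """One building block: extein core plus optional intein halves and tag.

    ``n_side`` names the intein whose C-half this unit carries (it
    accepts the upstream splice); ``c_side`` names the intein whose
    N-half it carries.  Terminal units replace one side with a
    purification tag.
    """

    unit_id: str
    g5_count: int = SASG_UNIT_G5
    e_count: int = SASG_UNIT_E
    sequence: str | None = None
    n_side: str | None = None
    c_side: str | None = None
    tag: str = "none"

    def __post_init__(self):
        if self.tag not in TAGS:
            raise InputError(f"unknown tag {self.tag!r}; use one of {TAGS}")

    @property
    def design_key(self) -> tuple:
        """Two units with the same key are the same physical construct."""
        return (self.n_side, self.c_side, self.tag, self.g5_count, self.e_count, self.sequence)


@dataclass
class AssemblyPlan:
    scheme: str  # one_pot | solid_phase
    units: list[AssemblyUnit]
    inteins_used: list[InteinSpec]
    cycles: int | None = None  # solid_phase only

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def unit_types(self) -> int:
        """Number of distinct unit designs the plan requires."""
        return len({u.design_key for u in self.units})

    @property
    def junction_inteins(self) -> list[str]:
        """Intein name at each junction i (between unit i and i+1)."""
        return [u.c_side for u in self.units[:-1]]


@dataclass
class LadderSpecies:
    units_incorporated: int
    abundance: float
    mass_kDa: float | None = None
    label: str = ""


@dataclass
class LadderPrediction:
    """Predicted species distribution from incomplete splicing."""

    species: list[LadderSpecies]

    def __post_init__(self):
        total = sum(s.abundance for s in self.species)
        assert abs(total - 1.0) < 1e-9, f"abundances sum to {total}"

    @property
    def full_length(self) -> LadderSpecies:
        return max(self.species, key=lambda s: s.units_incorporated)

    def by_length(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for s in self.species:
            out[s.units_incorporated] = out.get(s.units_incorporated, 0.0) + s.abundance
        return out


def plan_one_pot(
    n_units: int,
    library: list[InteinSpec],
    start_tag: str = "H6",
    end_tag: str = "Strep",
) -> AssemblyPlan:
    """Plan a one-pot assembly: one distinct orthogonal intein per junction.

    n units need n - 1 library members and n distinct unit designs; the
    start unit carries ``start_tag`` (resin side), the end unit
    ``end_tag``.
    """
    if n_units < 2:
        raise InputError(f"an assembly needs >= 2 units, got {n_units}")
    names = [i.name for i in library]
    if len(set(names)) != len(names):
        raise OrthogonalityError(f"library contains duplicate intein names: {names}")
    needed = n_units - 1
    if len(library) < needed:
        raise CapacityError(
            f"one-pot assembly of {n_units} units requires {needed} orthogonal "
            f"inteins; library holds {len(library)}"
        )
    inteins = library[:needed]
    units = []
    for i in range(n_units):
        units.append(
            AssemblyUnit(
                unit_id=f"U{i + 1}",
                n_side=inteins[i - 1].name if i > 0 else None,
                c_side=inteins[i].name if i < n_units - 1 else None,
                tag=start_tag if i == 0 else (end_tag if i == n_units - 1 else "none"),
            )
        )
    return AssemblyPlan("one_pot", units, inteins)


def plan_solid_phase(
    n_units: int,
    pair: tuple[InteinSpec, InteinSpec],
    start_tag: str = "H6",
    end_tag: str = "Strep",
) -> AssemblyPlan:
    """Plan a recursive solid-phase assembly with two alternating inteins.

    Junction inteins alternate A, B, A, B, ...; unit designs saturate at
    four for n >= 4 and the build takes n - 1 extension cycles.
    """
    if n_units < 2:
        raise InputError(f"an assembly needs >= 2 units, got {n_units}")
    a, b = pair
    if a.name == b.name:
        raise OrthogonalityError(
            f"solid-phase assembly needs two distinct orthogonal inteins, got "
            f"{a.name!r} twice"
        )
    junctions = [a if j % 2 == 0 else b for j in range(n_units - 1)]
    units = []
    for i in range(n_units):
        units.append(
            AssemblyUnit(
                unit_id=f"U{i + 1}",
                n_side=junctions[i - 1].name if i > 0 else None,
                c_side=junctions[i].name if i < n_units - 1 else None,
                tag=start_tag if i == 0 else (end_tag if i == n_units - 1 else "none"),
            )
        )
    return AssemblyPlan("solid_phase", units, [a, b], cycles=n_units - 1)


@dataclass
class Composition:
    g5_total: int
    e_total: int
    mass_kDa: float | None


def _chain_mass_kda(units: list[AssemblyUnit]) -> float:
    """Average-isotopic mass of the spliced extein chain, in kDa.

    The inteins excise themselves, so only the concatenated unit
    sequences (one polypeptide, one terminal water) remain.
    """
    seq = "".join(u.sequence for u in units)
    return ProteinAnalysis(seq).molecular_weight() / 1000.0


def product_composition(
    plan_or_units: AssemblyPlan | list[AssemblyUnit], require_mass: bool = False
) -> Composition:
    """Total repeat composition (and optionally mass) of the spliced product.

    Six uniform SasG5^3 E^2 units give (18, 12); mass needs every unit to
    carry its amino-acid sequence and is reported to 0.1 kDa.
    """
    units = (
        plan_or_units.units
        if isinstance(plan_or_units, AssemblyPlan)
        else list(plan_or_units)
    )
    g5 = sum(u.g5_count for u in units)
    e = sum(u.e_count for u in units)
    have_seqs = all(u.sequence for u in units)
    if require_mass and not have_seqs:
        missing = [u.unit_id for u in units if not u.sequence]
        raise MissingSequenceError(
            f"mass requested but unit(s) {missing} carry no sequence"
        )
    mass = round(_chain_mass_kda(units), 1) if have_seqs else None
    return Composition(g5, e, mass)


@dataclass
class JunctionReport:
    junction_index: int
    intein: str
    realized: str
    preferred: str
    match: bool


def check_junction_compatibility(
    plan: AssemblyPlan, inteins: dict[str, InteinSpec] | None = None
) -> list[JunctionReport]:
    """Compare realized -3..+3 junction residues with each intein's preference.

    Splicing efficiency depends strongly on the junction sequence, so
    units are normally designed with the preferred residues built in;
    this reports an exact-match flag per junction, no scoring.
    """
    lookup = inteins or {i.name: i for i in plan.inteins_used}
    reports = []
    for j in range(plan.n_units - 1):
        up, down = plan.units[j], plan.units[j + 1]
        if not (up.sequence and down.sequence):
            raise MissingSequenceError(
                f"junction {j}: unit sequences required for compatibility check"
            )
        realized = up.sequence[-3:] + down.sequence[:3]
        spec = lookup[up.c_side]
        reports.append(
            JunctionReport(j, spec.name, realized, spec.junction_pref, realized == spec.junction_pref)
        )
    return reports


def _junction_probs(plan: AssemblyPlan, p) -> np.ndarray:
    n_j = plan.n_units - 1
    if isinstance(p, dict):
        probs = np.array([p[name] for name in plan.junction_inteins], dtype=float)
    elif np.isscalar(p):
        probs = np.full(n_j, float(p))
    else:
        probs = np.asarray(p, dtype=float)
        if probs.size != n_j:
            raise ParameterError(f"need {n_j} junction probabilities, got {probs.size}")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ParameterError(f"splicing probabilities must lie in [0, 1]: {probs}")
    return probs


def _segment_mass(plan: AssemblyPlan, start: int, end: int) -> float | None:
    units = plan.units[start : end + 1]
    if all(u.sequence for u in units):
        return round(_chain_mass_kda(units), 1)
    return None


def simulate_yield(
    plan: AssemblyPlan,
    p,
    mode: str = "deterministic",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> LadderPrediction:
    """Species ladder from independent per-junction splicing successes.

    ``p`` is a scalar probability, a per-junction array, or a mapping
    intein name -> probability.

    solid_phase: the chain truncates permanently at its first failed
    cycle, so a species of j < n units has abundance
    (prod_{i<j} p_i)(1 - p_j) and the full-length product prod_i p_i.

    one_pot: all junctions fire independently; species are grouped by
    how many junctions spliced (the ladder rung s + 1 units tall for s
    successes), with abundance the exact probability of that outcome
    class — the Poisson-binomial distribution over junction successes.
    For the per-molecule view of the same reaction see
    :func:`one_pot_fragment_distribution`.

    ``mode="stochastic"`` estimates the same distribution from
    ``n_draws`` seeded Bernoulli simulations.
    """
    probs = _junction_probs(plan, p)
    if mode == "deterministic":
        if plan.scheme == "solid_phase":
            return _solid_phase_ladder(plan, probs)
        return _one_pot_success_ladder(plan, probs)
    if mode == "stochastic":
        rng = np.random.default_rng(seed)
        return _stochastic_ladder(plan, probs, n_draws, rng)
    raise InputError(f"unknown mode {mode!r}")


def _solid_phase_ladder(plan: AssemblyPlan, probs: np.ndarray) -> LadderPrediction:
    n = plan.n_units
    species = []
    prefix = 1.0
    for j, pj in enumerate(probs):  # failure at cycle j+1 -> j+1 units on resin
        ab = prefix * (1.0 - pj)
        if ab > 0:
            species.append(
                LadderSpecies(j + 1, ab, _segment_mass(plan, 0, j), f"truncated@cycle{j + 1}")
            )
        prefix *= pj
    if prefix > 0:
        species.append(LadderSpecies(n, prefix, _segment_mass(plan, 0, n - 1), "full_length"))
    return LadderPrediction(species)


def _poisson_binomial(probs: np.ndarray) -> np.ndarray:
    """Exact pmf of the number of successes among independent Bernoullis."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def _one_pot_success_ladder(plan: AssemblyPlan, probs: np.ndarray) -> LadderPrediction:
    n = plan.n_units
    pmf = _poisson_binomial(probs)
    species = []
    for s, ab in enumerate(pmf):
        if ab <= 0:
            continue
        mass = _segment_mass(plan, 0, n - 1) if s == n - 1 else None
        label = "full_length" if s == n - 1 else f"{s}_junctions_spliced"
        species.append(LadderSpecies(s + 1, float(ab), mass, label))
    return LadderPrediction(species)


def one_pot_fragment_distribution(plan: AssemblyPlan, p) -> LadderPrediction:
    """Per-molecule one-pot ladder: expected molar fractions of fragments.

    Every maximal spliced run is a product molecule; the abundance of
    run U_i..U_j is its expected count divided by the expected total
    number of product molecules.  This is the quantity a stained gel
    lane approximates (band intensity further scales with mass).
    """
    probs = _junction_probs(plan, p)
    n = plan.n_units
    fail = 1.0 - probs
    expected: list[tuple[int, int, float]] = []
    total = 0.0
    for i in range(n):
        for j in range(i, n):
            # maximal run i..j: junction i-1 failed (or chain start),
            # junctions i..j-1 spliced, junction j failed (or chain end)
            w = 1.0
            if i > 0:
                w *= fail[i - 1]
            w *= np.prod(probs[i:j])
            if j < n - 1:
                w *= fail[j]
            if w > 0:
                expected.append((i, j, float(w)))
                total += w
    species = [
        LadderSpecies(j - i + 1, w / total, _segment_mass(plan, i, j), f"U{i + 1}-U{j + 1}")
        for i, j, w in expected
    ]
    return LadderPrediction(species)


def one_pot_success_distribution_by_enumeration(plan: AssemblyPlan, p) -> dict[int, float]:
    """Brute-force P(s junctions spliced) over all 2^(n-1) outcomes
    (small n; reference for the Poisson-binomial closed form)."""
    probs = _junction_probs(plan, p)
    out: dict[int, float] = {}
    for pattern in itertools.product([True, False], repeat=plan.n_units - 1):
        w = float(np.prod([pj if ok else 1 - pj for pj, ok in zip(probs, pattern)]))
        s = sum(pattern)
        out[s] = out.get(s, 0.0) + w
    return out


def one_pot_fragments_by_enumeration(plan: AssemblyPlan, p) -> dict[int, float]:
    """Brute-force molar fragment-length distribution over all 2^(n-1)
    junction outcomes (small n; reference for the closed form)."""
    probs = _junction_probs(plan, p)
    n = plan.n_units
    counts: dict[int, float] = {}
    for pattern in itertools.product([True, False], repeat=n - 1):
        w = float(
            np.prod([pj if ok else 1 - pj for pj, ok in zip(probs, pattern)])
        )
        length = 1
        frags = []
        for ok in pattern:
            if ok:
                length += 1
            else:
                frags.append(length)
                length = 1
        frags.append(length)
        for L in frags:
            counts[L] = counts.get(L, 0.0) + w
    total = sum(counts.values())
    return {L: c / total for L, c in counts.items()}


def _stochastic_ladder(
    plan: AssemblyPlan, probs: np.ndarray, n_draws: int, rng: np.random.Generator
) -> LadderPrediction:
    n = plan.n_units
    outcomes = rng.random((n_draws, n - 1)) < probs  # independent junction successes
    if plan.scheme == "solid_phase":
        # first failed junction truncates the chain permanently
        failed = ~outcomes
        first_fail = np.where(failed.any(axis=1), failed.argmax(axis=1), n - 1)
        lengths = np.where(failed.any(axis=1), first_fail + 1, n)
    else:
        lengths = outcomes.sum(axis=1) + 1  # successes + 1 = ladder rung height
    species = []
    for L, c in zip(*np.unique(lengths, return_counts=True)):
        L = int(L)
        full = L == n
        mass = _segment_mass(plan, 0, L - 1) if (plan.scheme == "solid_phase" or full) else None
        label = "full_length" if full else f"{L}_units"
        species.append(LadderSpecies(L, c / n_draws, mass, label))
    return LadderPrediction(species)
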