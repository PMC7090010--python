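"""Cross-reactivity matrices and the two-threshold orthogonality criterion.

A split intein is characterized by its parent intein and the site at
which it was bisected (S1 near the N-terminus, S2 at the canonical
endonuclease insertion site, S3 near the C-terminus).  Screening all
N-half x C-half combinations of k split pairs gives a k x k matrix of
reconstituted-reporter signals; the diagonal holds the cognate pairs.

For each pair the 2(k-1) non-cognate signals in its row and column are
divided by its cognate signal.  The pair is *orthogonal* when all of
those relative values are below 0.2 AND their median is below 0.05
(both strict).  A mutually orthogonal set is one in which every member
passes the criterion when the matrix is restricted to the set.

Two selection procedures are provided: a deterministic greedy pruning
(:func:`prune_mutually_orthogonal`, remove-the-worst-until-clean, then
one split variant per parent intein) and a guaranteed-maximum search
(:func:`max_orthogonal_subset` with ``mode="exact"``).  The max rule is
hereditary (restricting a matrix can only lower each member's maximum
relative value), so the exact search prunes on it; the median rule is
not hereditary and is re-checked on every candidate subset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    AmbiguityError,
    ShapeError,
    SubsetSizeError,
    UndefinedNormalizationError,
)

SPLIT_SITES = ("S1", "S2", "S3")

#: Largest matrix accepted by the exact subset search.
EXACT_MODE_MAX_K = 25


@dataclass(frozen=True, order=True)
class SplitPair:
    """Identity of a split-intein pair: parent intein + split site."""

    intein: str
    split_site: str

    def __post_init__(self):
        if self.split_site not in SPLIT_SITES:
            raise ShapeError(
                f"split_site must be one of {SPLIT_SITES}, got {self.split_site!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.intein}:{self.split_site}"

    @classmethod
    def from_label(cls, label: str) -> "SplitPair":
        intein, _, site = label.rpartition(":")
        return cls(intein, site)


@dataclass(frozen=True)
class OrthoConfig:
    """Thresholds and policy of the orthogonality criterion.

    max_threshold
        Every cognate-normalized non-cognate value must fall below this
        (default 0.2).
    median_threshold
        The median of those values must fall below this (default 0.05).
    noncognate_policy
        ``"all"`` keeps every off-diagonal cell in the pair's row and
        column (2(k-1) values for a k x k matrix).  ``"exclude_same_intein"``
        drops cells whose partner shares the parent intein — variants of
        one intein split at different sites often share sequence and
        cross-react by construction.
    """

    max_threshold: float = 0.2
    median_threshold: float = 0.05
    noncognate_policy: str = "all"

    def __post_init__(self):
        if not (0 < self.median_threshold <= self.max_threshold < 1):
            raise ValueError(
                "need 0 < median_threshold <= max_threshold < 1, got "
                f"{self.median_threshold} / {self.max_threshold}"
            )
        if self.noncognate_policy not in ("all", "exclude_same_intein"):
            raise ValueError(f"unknown policy {self.noncognate_policy!r}")


@dataclass
class OrthoCall:
    """Orthogonality verdict for one split pair within a matrix."""

    pair: SplitPair
    relative_values: np.ndarray
    max_rel: float
    median_rel: float
    orthogonal: bool


class CrossMatrix:
    """Square N-half x C-half signal grid keyed by split-pair identity.

    ``values[i, j]`` is the (replicate-mean) signal of N-half *i* with
    C-half *j*; rows and columns share one ordered pair list, so the
    diagonal holds the cognate signals.  Optional per-cell replicate
    values can be attached for uncertainty propagation.
    """

    def __init__(
        self,
        pairs: list[SplitPair],
        values: np.ndarray,
        replicates: np.ndarray | None = None,
    ):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ShapeError(f"matrix must be square, got shape {values.shape}")
        if values.shape[0] != len(pairs):
            raise ShapeError(
                f"{len(pairs)} pairs but value grid of shape {values.shape}"
            )
        if len(set(pairs)) != len(pairs):
            raise ShapeError("duplicate SplitPair identities")
        self.pairs = list(pairs)
        self.values = values
        self.replicates = replicates
        self._index = {p: i for i, p in enumerate(self.pairs)}

    @property
    def k(self) -> int:
        return len(self.pairs)

    def index_of(self, pair: SplitPair) -> int:
        return self._index[pair]

    def cognate(self, pair: SplitPair) -> float:
        i = self._index[pair]
        return self.values[i, i]

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_signals(cls, signals: pd.DataFrame, pairing: dict) -> "CrossMatrix":
        """Assemble a matrix from NormalizedSignal rows.

        ``pairing`` maps each sample_id to a ``(row SplitPair, col
        SplitPair)`` tuple.  All k^2 combinations must be present exactly
        once; a 24-pair screen therefore consumes 576 signals.
        """
        pairs = sorted({rp for rp, _ in pairing.values()} | {cp for _, cp in pairing.values()})
        idx = {p: i for i, p in enumerate(pairs)}
        k = len(pairs)
        values = np.full((k, k), np.nan)
        for _, row in signals.iterrows():
            sid = row["sample_id"]
            if sid not in pairing:
                continue
            rp, cp = pairing[sid]
            i, j = idx[rp], idx[cp]
            if not np.isnan(values[i, j]):
                raise AmbiguityError(f"duplicate signal for cell {rp.label} x {cp.label}")
            values[i, j] = row["mean"]
        if np.isnan(values).any():
            missing = [
                f"{pairs[i].label} x {pairs[j].label}"
                for i, j in zip(*np.nonzero(np.isnan(values)))
            ]
            raise ShapeError(f"missing matrix cell(s): {missing}")
        return cls(pairs, values)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CrossMatrix":
        """Read a CSV grid whose header row/column hold 'intein:site' labels."""
        df = pd.read_csv(path, index_col=0)
        row_pairs = [SplitPair.from_label(s) for s in df.index]
        col_pairs = [SplitPair.from_label(s) for s in df.columns]
        if row_pairs != col_pairs:
            raise ShapeError("row and column labels differ (matrix must be square)")
        return cls(row_pairs, df.to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def to_frame(self) -> pd.DataFrame:
        labels = [p.label for p in self.pairs]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def restrict(self, pairs: list[SplitPair]) -> "CrossMatrix":
        """Return the sub-matrix over the given pairs (original order)."""
        keep = [p for p in self.pairs if p in set(pairs)]
        idx = [self._index[p] for p in keep]
        return CrossMatrix(keep, self.values[np.ix_(idx, idx)])


def _relative_values(
    m: CrossMatrix, i: int, cfg: OrthoConfig, subset: np.ndarray | None = None
) -> np.ndarray:
    """Cognate-normalized non-cognate values of pair i, optionally within a subset."""
    cog = m.values[i, i]
    if cog <= 0:
        raise UndefinedNormalizationError(
            f"cognate signal of {m.pairs[i].label} is {cog}; cannot normalize"
        )
    if subset is None:
        others = [j for j in range(m.k) if j != i]
    else:
        others = [j for j in subset if j != i]
    if cfg.noncognate_policy == "exclude_same_intein":
        others = [j for j in others if m.pairs[j].intein != m.pairs[i].intein]
    if not others:
        return np.empty(0)
    row = m.values[i, others]
    col = m.values[others, i]
    # Negative blank/control-subtracted signals mean "no signal": floor at 0.
    vals = np.clip(np.concatenate([row, col]), 0.0, None)
    return vals / cog


def noncognate_values(
    pair: SplitPair, m: CrossMatrix, cfg: OrthoConfig | None = None
) -> np.ndarray:
    """Relative (cognate-normalized) non-cognate values for one pair.

    Under policy ``"all"`` a k x k matrix yields 2(k-1) values — 46 for
    the 24-pair in vivo screen.
    """
    cfg = cfg or OrthoConfig()
    return _relative_values(m, m.index_of(pair), cfg)


def classify_orthogonal(
    pair: SplitPair, m: CrossMatrix, cfg: OrthoConfig | None = None
) -> OrthoCall:
    """Apply the two-threshold criterion to one pair.

    A pair with no non-cognate partners (singleton matrix, or all
    partners excluded by policy) is vacuously orthogonal with max and
    median reported as 0.
    """
    cfg = cfg or OrthoConfig()
    rel = noncognate_values(pair, m, cfg)
    return _call_from_values(pair, rel, cfg)


def _call_from_values(pair: SplitPair, rel: np.ndarray, cfg: OrthoConfig) -> OrthoCall:
    if rel.size == 0:
        return OrthoCall(pair, rel, 0.0, 0.0, True)
    max_rel = float(rel.max())
    median_rel = float(np.median(rel))
    ok = (max_rel < cfg.max_threshold) and (median_rel < cfg.median_threshold)
    return OrthoCall(pair, rel, max_rel, median_rel, ok)


def classify_all(m: CrossMatrix, cfg: OrthoConfig | None = None) -> list[OrthoCall]:
    cfg = cfg or OrthoConfig()
    return [classify_orthogonal(p, m, cfg) for p in m.pairs]


def calls_to_frame(calls: list[OrthoCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair": [c.pair.label for c in calls],
            "max_rel": [c.max_rel for c in calls],
            "median_rel": [c.median_rel for c in calls],
            "orthogonal": [c.orthogonal for c in calls],
        }
    )


def _subset_calls(
    m: CrossMatrix, subset: list[int], cfg: OrthoConfig
) -> list[OrthoCall]:
    sub = np.asarray(subset)
    return [
        _call_from_values(m.pairs[i], _relative_values(m, i, cfg, sub), cfg)
        for i in subset
    ]


def _subset_feasible(m: CrossMatrix, subset: list[int], cfg: OrthoConfig) -> bool:
    return all(c.orthogonal for c in _subset_calls(m, subset, cfg))


@dataclass
class PruneResult:
    """Outcome of greedy pruning: surviving pairs, and one variant per intein."""

    pairs: list[SplitPair]
    inteins: list[str]
    selected_variants: list[SplitPair]
    removed: list[SplitPair] = field(default_factory=list)


def prune_mutually_orthogonal(
    m: CrossMatrix, cfg: OrthoConfig | None = None
) -> PruneResult:
    """Greedy pruning to a mutually orthogonal set.

    Repeatedly classifies every remaining pair within the reduced matrix
    and removes the worst offender until every survivor passes.  "Worst"
    is the failing pair in max-rule conflict with the most remaining
    partners, then the largest (max_rel, median_rel), ties broken by
    lexicographic pair identity: a single promiscuous pair inflates the
    max of everything it touches, so conflict degree — not the raw max —
    identifies it.  Parent inteins represented by several surviving
    split variants are then collapsed to the variant with the highest
    cognate signal (ties again lexicographic), giving the intein-level
    orthogonal set.
    """
    cfg = cfg or OrthoConfig()
    conflict = _conflict_graph(m, cfg)
    active = list(range(m.k))
    removed: list[SplitPair] = []
    while True:
        calls = _subset_calls(m, active, cfg)
        failing = [(c, i) for c, i in zip(calls, active) if not c.orthogonal]
        if not failing:
            break
        act = np.asarray(active)
        worst = max(
            failing,
            key=lambda ci: (
                int(conflict[ci[1], act].sum()),
                ci[0].max_rel,
                ci[0].median_rel,
                _neg_key(ci[0].pair),
            ),
        )
        active.remove(worst[1])
        removed.append(worst[0].pair)

    surviving = [m.pairs[i] for i in active]
    best_variant: dict[str, SplitPair] = {}
    for p in sorted(surviving):
        cur = best_variant.get(p.intein)
        if cur is None or m.cognate(p) > m.cognate(cur):
            best_variant[p.intein] = p
    inteins = sorted(best_variant)
    selected = [best_variant[i] for i in inteins]
    return PruneResult(surviving, inteins, selected, removed)


class _NegKey:
    """Inverts sort order of a SplitPair so max() picks the lexicographic min on ties."""

    __slots__ = ("p",)

    def __init__(self, p: SplitPair):
        self.p = p

    def __lt__(self, other):  # self "less" when pair is lexicographically larger
        return self.p > other.p

    def __eq__(self, other):
        return self.p == other.p


def _neg_key(p: SplitPair) -> _NegKey:
    return _NegKey(p)


def _conflict_graph(m: CrossMatrix, cfg: OrthoConfig) -> np.ndarray:
    """Boolean adjacency: i ~ j if either orientation of their shared cells
    violates the max rule for either member.  Any subset containing a
    conflicting pair of members can never satisfy the criterion."""
    k = m.k
    cog = np.diag(m.values)
    if np.any(cog <= 0):
        bad = [m.pairs[i].label for i in np.nonzero(cog <= 0)[0]]
        raise UndefinedNormalizationError(f"non-positive cognate signal(s): {bad}")
    vals = np.clip(m.values, 0.0, None)
    rel_by_row = vals / cog[:, None]  # cell (i,j) normalized to pair i
    rel_by_col = vals / cog[None, :]  # cell (i,j) normalized to pair j
    t = cfg.max_threshold
    conflict = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            if (
                cfg.noncognate_policy == "exclude_same_intein"
                and m.pairs[i].intein == m.pairs[j].intein
            ):
                continue
            if (
                rel_by_row[i, j] >= t
                or rel_by_col[i, j] >= t
                or rel_by_row[j, i] >= t
                or rel_by_col[j, i] >= t
            ):
                conflict[i, j] = conflict[j, i] = True
    return conflict


def max_orthogonal_subset(
    m: CrossMatrix, cfg: OrthoConfig | None = None, mode: str = "exact"
) -> list[SplitPair]:
    """Largest subset whose every member classifies orthogonal within it.

    ``mode="greedy"`` returns the pair-level result of
    :func:`prune_mutually_orthogonal`.  ``mode="exact"`` (k <= 25) runs a
    branch-and-bound that enumerates max-rule-compatible subsets
    (conflict-graph independent sets) and keeps the largest that also
    satisfies the median rule; the exact answer is never smaller than
    the greedy one.  Ties between equal-size subsets resolve to the
    lexicographically first pair list.
    """
    cfg = cfg or OrthoConfig()
    if mode == "greedy":
        return prune_mutually_orthogonal(m, cfg).pairs
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    if m.k > EXACT_MODE_MAX_K:
        raise SubsetSizeError(
            f"exact mode supports k <= {EXACT_MODE_MAX_K} (got {m.k}); use greedy"
        )

    order = sorted(range(m.k), key=lambda i: m.pairs[i])
    conflict = _conflict_graph(m, cfg)
    best: list[int] = []

    def search(current: list[int], candidates: list[int]) -> None:
        nonlocal best
        if len(current) > len(best) and _subset_feasible(m, current, cfg):
            best = list(current)
        for pos, v in enumerate(candidates):
            rest = candidates[pos + 1 :]
            if len(current) + 1 + len(rest) <= len(best):
                break  # even taking everything left cannot beat best
            nxt = [u for u in rest if not conflict[v, u]]
            current.append(v)
            search(current, nxt)
            current.pop()

    search([], order)
    return sorted(m.pairs[i] for i in best)


def max_orthogonal_subset_bruteforce(
    m: CrossMatrix, cfg: OrthoConfig | None = None
) -> list[SplitPair]:
    """Exhaustive reference over all 2^k subsets (k <= ~12; test oracle)."""
    cfg = cfg or OrthoConfig()
    best: list[int] = []
    idx = range(m.k)
    for r in range(m.k, len(best), -1):
        for combo in itertools.combinations(idx, r):
            if _subset_feasible(m, list(combo), cfg):
                return sorted(m.pairs[i] for i in combo)
    return []
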