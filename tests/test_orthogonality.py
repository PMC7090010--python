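"""Cross-reactivity matrices, the two-threshold criterion, subset selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_matrix
from inteinscreen import orthogonality as og
from inteinscreen.exceptions import (
    AmbiguityError,
    ShapeError,
    SubsetSizeError,
    UndefinedNormalizationError,
)
from inteinscreen.orthogonality import (
    CrossMatrix,
    OrthoConfig,
    SplitPair,
    classify_all,
    classify_orthogonal,
    max_orthogonal_subset,
    max_orthogonal_subset_bruteforce,
    noncognate_values,
    prune_mutually_orthogonal,
)


def random_matrix(rng, k, scale=0.08):
    rel = rng.exponential(scale, size=(k, k))
    return make_matrix(rel)


class TestMatrixConstruction:
    def test_from_signals_square(self):
        pairs = [SplitPair(f"I{i}", "S2") for i in range(3)]
        pairing, rows = {}, []
        for i, rp in enumerate(pairs):
            for j, cp in enumerate(pairs):
                sid = f"{rp.label}|{cp.label}"
                pairing[sid] = (rp, cp)
                rows.append({"sample_id": sid, "mean": 1000.0 if i == j else 5.0})
        m = CrossMatrix.from_signals(pd.DataFrame(rows), pairing)
        assert m.k == 3
        assert np.allclose(np.diag(m.values), 1000.0)

    def test_missing_cell_named(self):
        pairs = [SplitPair("A", "S2"), SplitPair("B", "S2")]
        pairing = {
            f"{r.label}|{c.label}": (r, c) for r in pairs for c in pairs
        }
        rows = [{"sample_id": sid, "mean": 1.0} for sid in list(pairing)[:3]]
        with pytest.raises(ShapeError, match="missing"):
            CrossMatrix.from_signals(pd.DataFrame(rows), pairing)

    def test_duplicate_cell_rejected(self):
        p = SplitPair("A", "S2")
        pairing = {"s1": (p, p), "s2": (p, p)}
        rows = [{"sample_id": "s1", "mean": 1.0}, {"sample_id": "s2", "mean": 2.0}]
        with pytest.raises(AmbiguityError):
            CrossMatrix.from_signals(pd.DataFrame(rows), pairing)

    def test_non_square_rejected(self):
        with pytest.raises(ShapeError):
            CrossMatrix([SplitPair("A", "S2")], np.ones((1, 2)))

    def test_csv_roundtrip(self, tmp_path):
        m = make_matrix(np.full((3, 3), 0.02))
        path = tmp_path / "m.csv"
        m.to_csv(path)
        back = CrossMatrix.from_csv(path)
        assert back.pairs == m.pairs
        assert np.allclose(back.values, m.values)


class TestNoncognateValues:
    def test_count_is_2k_minus_2(self):
        m = make_matrix(np.zeros((24, 24)))
        assert len(noncognate_values(m.pairs[0], m)) == 46

    def test_planted_crosstalk_appears(self):
        rel = np.zeros((3, 3))
        rel[0, 2] = 0.1
        m = make_matrix(rel)
        vals = noncognate_values(m.pairs[0], m)
        assert 0.1 in np.round(vals, 12)

    def test_cognate_excluded_and_zero_offdiag(self):
        m = make_matrix(np.zeros((2, 2)))
        vals = noncognate_values(m.pairs[0], m)
        assert vals.tolist() == [0.0, 0.0]
        assert 1.0 not in vals

    def test_exclude_same_intein_policy(self):
        pairs = [SplitPair("A", "S1"), SplitPair("A", "S2"), SplitPair("B", "S2")]
        rel = np.full((3, 3), 0.3)
        np.fill_diagonal(rel, 1.0)
        m = CrossMatrix(pairs, 1000 * rel)
        cfg = OrthoConfig(noncognate_policy="exclude_same_intein")
        assert len(noncognate_values(pairs[0], m, cfg)) == 2  # only vs B:S2
        assert len(noncognate_values(pairs[0], m)) == 4

    def test_nonpositive_cognate_errors(self):
        m = make_matrix(np.zeros((2, 2)))
        m.values[0, 0] = 0.0
        with pytest.raises(UndefinedNormalizationError):
            noncognate_values(m.pairs[0], m)

    def test_negative_signals_floored_before_ratio(self):
        rel = np.zeros((2, 2))
        rel[0, 1] = -0.5  # negative after control subtraction
        m = make_matrix(rel)
        assert noncognate_values(m.pairs[0], m).min() == 0.0


class TestClassification:
    def test_all_zero_is_orthogonal(self, clean_matrix_4):
        assert all(c.orthogonal for c in classify_all(clean_matrix_4))

    def test_max_rule_violation(self):
        rel = np.zeros((4, 4))
        rel[0, 1] = 0.25
        m = make_matrix(rel)
        call = classify_orthogonal(m.pairs[0], m)
        assert not call.orthogonal and call.max_rel == pytest.approx(0.25)

    def test_median_rule_violation_despite_low_max(self):
        # 46 values all 0.06: max < 0.2 but median 0.06 >= 0.05
        rel = np.full((24, 24), 0.06)
        m = make_matrix(rel)
        call = classify_orthogonal(m.pairs[0], m)
        assert call.max_rel == pytest.approx(0.06)
        assert call.median_rel == pytest.approx(0.06)
        assert not call.orthogonal

    @pytest.mark.parametrize(
        "level, expected",
        [(0.199, True), (0.2, False), (0.049, True), (0.05, False)],
    )
    def test_strict_inequalities_at_boundaries(self, level, expected):
        if level in (0.199, 0.2):
            rel = np.zeros((4, 4))
            rel[0, 1] = level  # single value; median ~ 0... ensure median small
            m = make_matrix(rel)
        else:
            rel = np.full((4, 4), level)  # all values at the median threshold
            m = make_matrix(rel)
        assert classify_orthogonal(m.pairs[0], m).orthogonal is expected

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 6)
        scaled = CrossMatrix(m.pairs, m.values * 37.5)
        for p in m.pairs:
            assert (
                classify_orthogonal(p, m).orthogonal
                == classify_orthogonal(p, scaled).orthogonal
            )

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000))
    def test_threshold_monotonicity(self, seed):
        """Raising either threshold never shrinks the orthogonal set."""
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 8)
        tight = {c.pair for c in classify_all(m, OrthoConfig(0.15, 0.04)) if c.orthogonal}
        loose = {c.pair for c in classify_all(m, OrthoConfig(0.3, 0.08)) if c.orthogonal}
        assert tight <= loose

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000))
    def test_max_rule_monotone_under_restriction(self, seed):
        """Removing members can only lower each survivor's max relative value."""
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 8)
        sub = m.restrict(m.pairs[:5])
        for p in sub.pairs:
            assert (
                classify_orthogonal(p, sub).max_rel
                <= classify_orthogonal(p, m).max_rel + 1e-12
            )


class TestSubsetSelection:
    def test_prune_keeps_clean_matrix(self, clean_matrix_4):
        res = prune_mutually_orthogonal(clean_matrix_4)
        assert res.pairs == clean_matrix_4.pairs
        assert res.removed == []

    def test_prune_removes_single_violator(self):
        rel = np.zeros((4, 4))
        rel[2, :] = 0.5
        rel[:, 2] = 0.5
        m = make_matrix(rel)
        res = prune_mutually_orthogonal(m)
        assert [p.label for p in res.removed] == ["I03:S2"]
        assert len(res.pairs) == 3

    def test_prune_collapses_variants_by_cognate_signal(self):
        pairs = [SplitPair("A", "S1"), SplitPair("A", "S2"), SplitPair("B", "S2")]
        values = np.diag([500.0, 900.0, 700.0])
        m = CrossMatrix(pairs, values)
        res = prune_mutually_orthogonal(m)
        assert res.inteins == ["A", "B"]
        assert SplitPair("A", "S2") in res.selected_variants  # higher cognate wins

    def test_exact_equals_bruteforce_many_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(4, 11))
            m = random_matrix(rng, k, scale=float(rng.uniform(0.02, 0.15)))
            exact = max_orthogonal_subset(m, mode="exact")
            brute = max_orthogonal_subset_bruteforce(m)
            assert len(exact) == len(brute)
            assert og._subset_feasible(m, [m.index_of(p) for p in exact], OrthoConfig())

    def test_exact_never_smaller_than_greedy(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            m = random_matrix(rng, 8, scale=0.1)
            exact = max_orthogonal_subset(m, mode="exact")
            greedy = max_orthogonal_subset(m, mode="greedy")
            assert len(exact) >= len(greedy)

    def test_exact_size_limit(self):
        m = make_matrix(np.zeros((26, 26)))
        with pytest.raises(SubsetSizeError):
            max_orthogonal_subset(m, mode="exact")

    def test_clique_crosstalk_structure(self):
        # 3 pairs cross-talking 0.3 with each other, 3 clean pairs:
        # at most one clique member can join the clean set.
        rel = np.zeros((6, 6))
        for i in range(3):
            for j in range(3):
                if i != j:
                    rel[i, j] = 0.3
        m = make_matrix(rel)
        exact = max_orthogonal_subset(m, mode="exact")
        assert len(exact) == 4
        clique = {m.pairs[0], m.pairs[1], m.pairs[2]}
        assert len(clique & set(exact)) == 1
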