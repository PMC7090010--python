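"""Assembly planning, product composition, junction checks, yield ladders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inteinscreen import assembly_planner as ap
from inteinscreen.exceptions import (
    CapacityError,
    InputError,
    MissingSequenceError,
    OrthogonalityError,
    ParameterError,
)


class TestPlanning:
    def test_one_pot_six_units(self, intein_library):
        plan = ap.plan_one_pot(6, intein_library)
        assert plan.unit_types == 6
        assert len(plan.inteins_used) == 5
        assert plan.units[0].tag == "H6" and plan.units[-1].tag == "Strep"
        assert len(set(plan.junction_inteins)) == 5  # all junctions distinct

    def test_one_pot_minimal_chain(self, intein_library):
        plan = ap.plan_one_pot(2, intein_library[:1])
        assert plan.unit_types == 2 and len(plan.inteins_used) == 1

    def test_one_pot_capacity_error_names_requirement(self, intein_library):
        with pytest.raises(CapacityError, match="5"):
            ap.plan_one_pot(6, intein_library[:4])

    @pytest.mark.parametrize(
        "n, types, cycles", [(2, 2, 1), (3, 3, 2), (4, 4, 3), (6, 4, 5), (10, 4, 9)]
    )
    def test_solid_phase_unit_types_saturate_at_four(self, intein_library, n, types, cycles):
        plan = ap.plan_solid_phase(n, (intein_library[0], intein_library[2]))
        assert plan.unit_types == types
        assert plan.cycles == cycles
        assert len(plan.inteins_used) == 2

    def test_solid_phase_junctions_alternate(self, intein_library):
        plan = ap.plan_solid_phase(6, (intein_library[0], intein_library[2]))
        assert plan.junction_inteins == ["gp41-1", "NrdJ-1"] * 2 + ["gp41-1"]

    def test_solid_phase_identical_inteins_rejected(self, intein_library):
        with pytest.raises(OrthogonalityError):
            ap.plan_solid_phase(4, (intein_library[0], intein_library[0]))

    def test_single_unit_assembly_rejected(self, intein_library):
        with pytest.raises(InputError):
            ap.plan_one_pot(1, intein_library)


class TestComposition:
    @pytest.mark.parametrize("n, g5, e", [(1, 3, 2), (6, 18, 12), (10, 30, 20)])
    def test_uniform_sasg_units(self, intein_library, n, g5, e):
        if n == 1:
            comp = ap.product_composition([ap.AssemblyUnit("U1")])
        else:
            lib = [ap.InteinSpec(f"i{j}", "GSGSGS") for j in range(n - 1)]
            comp = ap.product_composition(ap.plan_one_pot(n, lib))
        assert (comp.g5_total, comp.e_total) == (g5, e)

    def test_additivity_under_concatenation(self):
        a = [ap.AssemblyUnit("A", g5_count=3, e_count=2)]
        b = [ap.AssemblyUnit("B", g5_count=5, e_count=1)]
        ca, cb, cab = (ap.product_composition(u) for u in (a, b, a + b))
        assert cab.g5_total == ca.g5_total + cb.g5_total
        assert cab.e_total == ca.e_total + cb.e_total

    def test_mass_from_sequences(self, intein_library):
        plan = ap.plan_one_pot(2, intein_library)
        for u in plan.units:
            u.sequence = "MKLVINGKTLKGEITVEA"  # 18-mer test extein
        comp = ap.product_composition(plan, require_mass=True)
        # two 18-mers spliced: one chain of 36 residues, one terminal water
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        expected = ProteinAnalysis("MKLVINGKTLKGEITVEA" * 2).molecular_weight() / 1000
        assert comp.mass_kDa == pytest.approx(expected, abs=0.05)

    def test_mass_requires_sequences(self, intein_library):
        plan = ap.plan_one_pot(2, intein_library)
        with pytest.raises(MissingSequenceError):
            ap.product_composition(plan, require_mass=True)


class TestJunctions:
    def _planned(self, intein_library, mutate=None):
        plan = ap.plan_solid_phase(3, (intein_library[0], intein_library[2]))
        prefs = {i.name: i.junction_pref for i in intein_library}
        # design each unit so junctions carry the preferred -3..+3 residues
        seqs = []
        for i, u in enumerate(plan.units):
            seq = "GGSGGSGG"
            if u.n_side:
                seq = prefs[u.n_side][3:] + seq
            if u.c_side:
                seq = seq + prefs[u.c_side][:3]
            seqs.append(seq)
        if mutate is not None:
            j, pos, aa = mutate
            s = list(seqs[j])
            s[pos] = aa
            seqs[j] = "".join(s)
        for u, s in zip(plan.units, seqs):
            u.sequence = s
        return plan

    def test_designed_junctions_all_match(self, intein_library):
        reports = ap.check_junction_compatibility(self._planned(intein_library))
        assert all(r.match for r in reports)

    def test_single_substitution_flags_exactly_that_junction(self, intein_library):
        plan = self._planned(intein_library, mutate=(0, -1, "W"))  # -1 residue of junction 0
        reports = ap.check_junction_compatibility(plan)
        assert [r.match for r in reports] == [False, True]
        assert reports[0].realized[2] == "W"

    def test_random_junctions_match_hamming_oracle(self, intein_library):
        rng = np.random.default_rng(12)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        flagged = oracle = 0
        for _ in range(100):
            plan = ap.plan_solid_phase(4, (intein_library[0], intein_library[2]))
            for u in plan.units:
                u.sequence = "".join(rng.choice(aas, size=8))
            reports = ap.check_junction_compatibility(plan)
            flagged += sum(not r.match for r in reports)
            oracle += sum(
                r.realized != r.preferred for r in reports
            )  # direct string comparison
        assert flagged == oracle > 0


class TestYieldSimulation:
    def test_perfect_splicing_gives_full_length_only(self, intein_library):
        for plan in (
            ap.plan_one_pot(5, intein_library),
            ap.plan_solid_phase(5, (intein_library[0], intein_library[2])),
        ):
            ladder = ap.simulate_yield(plan, 1.0)
            assert len(ladder.species) == 1
            assert ladder.full_length.abundance == pytest.approx(1.0)

    def test_solid_phase_closed_form(self, intein_library):
        plan = ap.plan_solid_phase(6, (intein_library[0], intein_library[2]))
        ladder = ap.simulate_yield(plan, 0.8)
        assert ladder.full_length.abundance == pytest.approx(0.8**5)
        by_len = ladder.by_length()
        for j in range(1, 6):  # truncation after cycle j
            assert by_len[j] == pytest.approx(0.8 ** (j - 1) * 0.2)

    def test_one_pot_matches_enumeration(self, intein_library):
        plan = ap.plan_one_pot(3, intein_library)
        det = ap.simulate_yield(plan, 0.5).by_length()
        assert det == pytest.approx({1: 0.25, 2: 0.5, 3: 0.25})
        enum = ap.one_pot_success_distribution_by_enumeration(plan, 0.5)
        assert {s + 1: v for s, v in enum.items()} == pytest.approx(det)

    def test_one_pot_heterogeneous_probs_vs_enumeration(self, intein_library):
        plan = ap.plan_one_pot(5, intein_library)
        p = [0.9, 0.5, 0.7, 0.95]
        det = ap.simulate_yield(plan, p).by_length()
        enum = ap.one_pot_success_distribution_by_enumeration(plan, p)
        assert det == pytest.approx({s + 1: v for s, v in enum.items()})

    def test_fragment_distribution_vs_enumeration(self, intein_library):
        plan = ap.plan_one_pot(6, intein_library)
        p = [0.8, 0.4, 0.9, 0.6, 0.75]
        frag = ap.one_pot_fragment_distribution(plan, p).by_length()
        enum = ap.one_pot_fragments_by_enumeration(plan, p)
        assert frag == pytest.approx(enum)

    @settings(derandomize=True, max_examples=30)
    @given(
        p=st.floats(min_value=0.0, max_value=1.0),
        n=st.integers(min_value=2, max_value=12),
        scheme=st.sampled_from(["one_pot", "solid_phase"]),
    )
    def test_abundances_sum_to_one(self, p, n, scheme):
        lib = [ap.InteinSpec(f"i{j}", "GSGSGS") for j in range(max(n - 1, 2))]
        plan = (
            ap.plan_one_pot(n, lib)
            if scheme == "one_pot"
            else ap.plan_solid_phase(n, (lib[0], lib[1]))
        )
        ladder = ap.simulate_yield(plan, p)  # internal assert enforces sum == 1
        assert abs(sum(s.abundance for s in ladder.species) - 1.0) < 1e-9

    def test_stochastic_matches_deterministic_within_3se(self, intein_library):
        for plan in (
            ap.plan_one_pot(5, intein_library),
            ap.plan_solid_phase(5, (intein_library[0], intein_library[2])),
        ):
            n_draws = 100_000
            det = ap.simulate_yield(plan, 0.7).by_length()
            sto = ap.simulate_yield(plan, 0.7, mode="stochastic", n_draws=n_draws, seed=5)
            for L, p_det in det.items():
                se = np.sqrt(p_det * (1 - p_det) / n_draws)
                assert abs(sto.by_length().get(L, 0.0) - p_det) < 3 * se + 1e-12

    def test_invalid_probability_rejected(self, intein_library):
        plan = ap.plan_one_pot(3, intein_library)
        with pytest.raises(ParameterError):
            ap.simulate_yield(plan, 1.2)

    def test_per_intein_probability_map(self, intein_library):
        plan = ap.plan_solid_phase(4, (intein_library[0], intein_library[2]))
        ladder = ap.simulate_yield(plan, {"gp41-1": 1.0, "NrdJ-1": 0.5})
        # junctions A,B,A -> full length = 1 * 0.5 * 1
        assert ladder.full_length.abundance == pytest.approx(0.5)
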