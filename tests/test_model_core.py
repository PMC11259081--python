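import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circgenome.model_core import (BoundSegment, Parameters, Strand,
                                   SystemState, TemplateComplex,
                                   canonical_rotation,
                                   make_default_parameters, total_mass,
                                   validate_parameters)

RNA = st.text(alphabet="AGCU", min_size=1, max_size=20)


class TestParameters:
    def test_defaults_match_published_values(self):
        p = make_default_parameters()
        assert p.P_AT == 0.5
        assert p.P_BB == 5e-6
        assert p.P_EL == 1e-7
        assert p.P_FP == 0.001
        assert p.P_MN == 0.002
        assert p.P_MNP == 0.01
        assert p.P_ND == 0.05
        assert p.P_NDE == 0.001
        assert p.P_NF == 0.005
        assert p.P_NFR == 0.9
        assert p.P_RL == 1e-7
        assert p.P_SP == 0.5
        assert p.P_TL == 0.01
        assert p.P_TLR == 0.9
        assert p.N == 30
        assert p.T_NPB == 100_000
        assert p.T_REP == 10 and p.T_NR == 10
        assert p.F_DA == 5 and p.F_LT == 0.5
        assert p.CS_REP == "GAGUCUCU"
        assert p.CS_NR == "UGAUGCAG"
        assert p.CS_CT == "ACGAACUG"

    def test_defaults_raise_no_warnings(self):
        assert validate_parameters(make_default_parameters()) == []

    def test_ordering_violation_warns_not_raises(self):
        p = make_default_parameters().replace(P_TL=1e-9)
        warnings = validate_parameters(p)
        assert any("P_TL >> P_RL" in w for w in warnings)

    def test_switched_off_ribozyme_only_warns(self):
        # interventions set P_TLR = 0 mid-run; that must stay legal
        warnings = validate_parameters(
            make_default_parameters().replace(P_TLR=0.0))
        assert any("P_TLR >> P_TL" in w for w in warnings)

    @pytest.mark.parametrize("field,value", [
        ("P_AT", 1.5), ("P_SP", -0.1), ("F_DA", 0.5), ("F_LT", 2.0),
        ("N", 0), ("T_NPB", -1), ("T_REP", -2),
    ])
    def test_range_violations_rejected_with_field_named(self, field, value):
        p = make_default_parameters().replace(**{field: value})
        with pytest.raises(ValueError, match=field):
            validate_parameters(p)

    def test_yaml_round_trip_is_bit_exact(self):
        p = make_default_parameters().replace(P_BB=3.14e-6, F_LT=0.123456789)
        q = Parameters.from_yaml(p.to_yaml())
        assert q == p

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="P_XX"):
            Parameters.from_dict({"P_XX": 1.0})


class TestStrand:
    def test_circular_sequences_are_canonicalized(self):
        a = Strand("GAGUCUCU", circular=True)
        b = Strand("UCUGAGUC", circular=True)
        assert a.seq == b.seq

    @given(RNA.filter(lambda s: len(s) >= 3), st.integers(0, 19))
    @settings(max_examples=60, deadline=None)
    def test_any_two_rotations_compare_equal(self, seq, k):
        k = k % len(seq)
        rot = seq[k:] + seq[:k]
        assert Strand(seq, True).seq == Strand(rot, True).seq

    def test_minimum_ring_size_enforced(self):
        with pytest.raises(ValueError):
            Strand("AU", circular=True)
        Strand("AUG", circular=True)  # smallest legal ring

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            Strand("AGCT")  # DNA letter

    def test_canonical_rotation_is_smallest(self):
        assert canonical_rotation("UGA") == "AUG"
        assert canonical_rotation("GAGUCUCU") == min(
            "GAGUCUCU"[i:] + "GAGUCUCU"[:i] for i in range(8))


class TestComplexGeometry:
    def test_overlapping_segments_rejected(self):
        t = Strand("GAGUCUCU")
        with pytest.raises(ValueError):
            TemplateComplex(t, [BoundSegment(0, "AAA"),
                                BoundSegment(2, "GG")])

    def test_segment_outside_linear_template_rejected(self):
        with pytest.raises(ValueError):
            TemplateComplex(Strand("GAGU"), [BoundSegment(2, "AAA")])

    @given(st.integers(4, 18), st.data())
    @settings(max_examples=80, deadline=None)
    def test_empty_runs_match_bruteforce(self, L, data):
        circ = data.draw(st.booleans())
        occ = data.draw(st.lists(st.booleans(), min_size=L, max_size=L))
        if circ and L < 3:
            occ = occ + [False] * (3 - L)
            L = 3
        t = Strand("A" * L, circ and L >= 3)
        segs = [BoundSegment(i, "U") for i, o in enumerate(occ[:L]) if o]
        cx = TemplateComplex(t, segs)
        runs = cx.empty_runs()
        # brute force: positions covered by returned runs == empty positions
        covered = sorted({(s + k) % L for s, g in runs for k in range(g)})
        empty = [i for i in range(L) if not occ[i]]
        assert covered == empty
        # runs are maximal: no two runs are adjacent
        n_flank, n_interior = cx.site_classes()
        assert n_flank + n_interior == len(empty)
        assert n_flank >= 0 and n_interior >= 0


class TestMass:
    def test_fresh_state_mass_equals_endowment(self, rng):
        p = make_default_parameters().replace(N=5, T_NPB=1000)
        s = SystemState(p, rng)
        assert total_mass(s) == 1000

    def test_zero_endowment(self, rng):
        p = make_default_parameters().replace(N=2, T_NPB=0)
        assert total_mass(SystemState(p, rng)) == 0

    def test_hand_counted_inventory(self, rng):
        p = make_default_parameters().replace(N=2, T_NPB=0)
        s = SystemState(p, rng)
        s.precursors[0] = 82
        s.nucleotides[1, 0] = 10
        s.free_strands.append(s.make_strand("GAGUCUCU", False, 0))
        assert total_mass(s) == 82 + 10 + 8 == 100

    def test_complex_mass_counts_template_and_substrates(self, rng):
        p = make_default_parameters().replace(N=2, T_NPB=0)
        s = SystemState(p, rng)
        t = s.make_strand("GAGUCUCU", False, 0)
        t.alive = False
        s.complexes.append(TemplateComplex(t, [BoundSegment(0, "AGA")]))
        assert total_mass(s) == 11

    def test_room_view_reflects_state(self, rng):
        p = make_default_parameters().replace(N=3, T_NPB=90)
        s = SystemState(p, rng)
        s.nucleotides[4, 2] = 3
        room = s.room(1, 1)
        assert room.free_nucleotides["C"] == 3
        assert room.precursor_count == int(s.precursors[4])
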