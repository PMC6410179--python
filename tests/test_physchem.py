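"""Descriptor formulas: derived values, invariants, Biopython cross-check."""

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import DIWV
from hypothesis import given, settings
from hypothesis import strategies as st

from famchar import physchem as pc
from famchar.physchem import summarize_profiles, validate_against_table

AA = "ACDEFGHIKLMNPQRSTVWY"
seqs = st.text(alphabet=AA, min_size=1, max_size=60)
seqs2 = st.text(alphabet=AA, min_size=2, max_size=60)


class TestMolecularWeight:
    def test_single_glycine_is_residue_plus_water(self):
        assert pc.molecular_weight("G") == pytest.approx(75.07, abs=0.005)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pc.molecular_weight("")

    @settings(derandomize=True, max_examples=50)
    @given(seqs)
    def test_alanine_additivity(self, s):
        delta = pc.molecular_weight("A" + s) - pc.molecular_weight(s)
        assert delta == pytest.approx(pc.AVERAGE_RESIDUE_MASS["A"], abs=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(st.permutations(list("MKVLATWC")))
    def test_permutation_invariant(self, perm):
        assert pc.molecular_weight("".join(perm)) == pytest.approx(
            pc.molecular_weight("MKVLATWC")
        )


class TestGravy:
    def test_table_lookups(self):
        assert pc.gravy("AAAA") == pytest.approx(1.8)
        assert pc.gravy("RRRR") == pytest.approx(-4.5)

    @settings(derandomize=True, max_examples=30)
    @given(st.permutations(list("MKVLATWC")))
    def test_permutation_invariant(self, perm):
        assert pc.gravy("".join(perm)) == pytest.approx(pc.gravy("MKVLATWC"))


class TestTheoreticalPi:
    def test_basic_above_7_acidic_below_7(self):
        assert pc.theoretical_pi("KKKK") > 7 > pc.theoretical_pi("DDDD")

    @settings(derandomize=True, max_examples=25)
    @given(seqs)
    def test_is_a_charge_root(self, s):
        pi = pc.theoretical_pi(s)
        assert abs(pc.net_charge(s, pi)) < 1e-4

    @settings(derandomize=True, max_examples=25)
    @given(seqs)
    def test_acidic_to_basic_substitution_raises_pi(self, s):
        acidic, basic = "D" + s, "K" + s
        assert pc.theoretical_pi(basic) > pc.theoretical_pi(acidic)


class TestInstabilityIndex:
    def test_dipeptide_closed_form(self):
        # any 2-mer: II = 10/2 x its single DIWV entry
        assert pc.instability_index("MK") == pytest.approx(5.0 * DIWV["M"]["K"])
        assert pc.instability_index("WC") == pytest.approx(5.0 * DIWV["W"]["C"])

    def test_length_below_two_rejected(self):
        with pytest.raises(ValueError):
            pc.instability_index("M")

    def test_homo_dipeptide_repeat_converges_to_ten_times_weight(self):
        # closed form: II((XY)^k) -> 10 x mean of DIWV[X][Y], DIWV[Y][X]
        limit = 10.0 * (DIWV["W"]["C"] + DIWV["C"]["W"]) / 2.0
        ks = [5, 50, 500]
        errors = [abs(pc.instability_index("WC" * k) - limit) for k in ks]
        # error is O(1/k): 10 x DIWV[C][W] / (2k)
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] == pytest.approx(10 * DIWV["C"]["W"] / (2 * 500), abs=1e-6)

    def test_depends_on_dipeptide_order(self):
        # find an asymmetric DIWV entry; the index must feel the swap
        x, y = next(
            (x, y) for x in AA for y in AA if abs(DIWV[x][y] - DIWV[y][x]) > 1
        )
        assert pc.instability_index(x + y) != pytest.approx(pc.instability_index(y + x))


class TestAliphaticIndex:
    def test_boundary_compositions(self):
        assert pc.aliphatic_index("GGGG") == 0.0
        assert pc.aliphatic_index("AAAA") == pytest.approx(100.0)
        assert pc.aliphatic_index("IIII") == pytest.approx(390.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.permutations(list("AVILGGKK")))
    def test_permutation_invariant(self, perm):
        assert pc.aliphatic_index("".join(perm)) == pytest.approx(
            pc.aliphatic_index("AVILGGKK")
        )


@settings(derandomize=True, max_examples=25)
@given(st.text(alphabet=AA, min_size=40, max_size=200))
def test_descriptors_match_biopython(s):
    """Independent cross-check of all shared descriptors against ProtParam.

    Protein-length sequences only: Biopython stops its pI search at a coarse
    charge tolerance, which for very short peptides (flat charge curves)
    wanders ~0.2 pH units away from the true root this package bisects to.
    """
    pa = ProteinAnalysis(s)
    assert pc.gravy(s) == pytest.approx(pa.gravy(), abs=1e-9)
    assert pc.instability_index(s) == pytest.approx(pa.instability_index(), abs=1e-6)
    assert pc.theoretical_pi(s) == pytest.approx(pa.isoelectric_point(), abs=0.01)
    # mass tables differ in the 3rd decimal per residue between sources
    assert pc.molecular_weight(s) == pytest.approx(pa.molecular_weight(), rel=2e-4)


class TestSummary:
    def test_single_profile_means_equal_profile(self):
        from famchar.core_io import ProteinRecord

        p = pc.profile(ProteinRecord("x", "MKVLAT"))
        s = summarize_profiles([p], {"x": "DHN"})
        assert s.n_proteins == 1
        assert s.mean_pi == round(p.pi, 2)
        assert s.mean_mw_kda == round(p.mw / 1000, 1)
        assert s.min_pi == s.max_pi == ("x", round(p.pi, 2))

    def test_unknown_group_label_rejected(self):
        from famchar.core_io import ProteinRecord

        p = pc.profile(ProteinRecord("x", "MKVLAT"))
        with pytest.raises(ValueError, match="unknown group"):
            summarize_profiles([p], {"x": "LEA9"})

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_profiles([], {})


class TestValidationHarness:
    def test_all_cells_match_for_computed_profiles(self):
        from famchar.core_io import ProteinRecord

        recs = [ProteinRecord("a", "MKVLATWC"), ProteinRecord("b", "GGDDKKRR")]
        profiles = pc.profile_all(recs)
        table = {
            p.id: {"mw": round(p.mw, 2), "gravy": round(p.gravy, 3), "pi": round(p.pi, 2)}
            for p in profiles
        }
        frac, mismatches = validate_against_table(profiles, table)
        assert frac == 1.0 and mismatches == []

    def test_perturbed_cell_is_flagged(self):
        from famchar.core_io import ProteinRecord

        profiles = pc.profile_all([ProteinRecord("a", "MKVLATWC")])
        table = {"a": {"mw": round(profiles[0].mw, 2) + 0.5, "gravy": round(profiles[0].gravy, 3)}}
        frac, mismatches = validate_against_table(profiles, table)
        assert frac == 0.5
        assert mismatches[0][0] == "a" and mismatches[0][1] == "mw"
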