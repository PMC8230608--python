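"""Mass arithmetic: monosaccharides, glycans, peptides, the ¹⁸O marker."""

import pytest
from hypothesis import given, strategies as st
from pyteomics import mass as pmass

from glycoshift.masses import (
    MONOSACCHARIDES,
    GlycanComposition,
    ModifiedPeptide,
    deamidation_18o_shift,
    deamidation_shift,
    glycan_mass,
    glycopeptide_mass,
    monosaccharide_mass,
    peptide_mass,
    water_mass,
)

# CODATA/IUPAC constants used for independent bookkeeping in this file
M_H = 1.00782503207
M_N = 14.0030740048
M_O18 = 17.999161


@pytest.mark.parametrize(
    "code, form, scale, expected",
    [
        ("Hex", "free", "average", 180.16),
        ("Neu5Ac", "free", "average", 309.27),
        ("HexNAc", "free", "average", 221.21),
        ("Hex", "residue", "average", 162.14),
        ("dHex", "free", "average", 164.16),
    ],
)
def test_monosaccharide_masses(code, form, scale, expected):
    assert monosaccharide_mass(code, form, scale) == pytest.approx(expected, abs=0.005)


def test_monosaccharide_rounded_trio():
    rounded = {c: round(monosaccharide_mass(c, "free", "average")) for c in ("Hex", "HexNAc", "Neu5Ac")}
    assert rounded == {"Hex": 180, "HexNAc": 221, "Neu5Ac": 309}


def test_unknown_code_named_in_error():
    with pytest.raises(ValueError, match="Pent"):
        monosaccharide_mass("Pent")


def test_residue_is_free_minus_water():
    for scale in ("mono", "average"):
        for m in MONOSACCHARIDES.values():
            assert m.mass("residue", scale) == pytest.approx(
                m.mass("free", scale) - water_mass(scale), abs=1e-9
            )


def test_average_at_least_monoisotopic():
    for m in MONOSACCHARIDES.values():
        assert m.free_average >= m.free_mono


def test_water_constants():
    assert water_mass("mono") == pytest.approx(18.0106, abs=5e-4)
    assert water_mass("average") == pytest.approx(18.0153, abs=5e-4)


class TestGlycanComposition:
    def test_empty_residue_sum_is_zero(self):
        assert glycan_mass(GlycanComposition(), "residue_sum", "average") == 0.0
        assert GlycanComposition().free_mass() == 0.0

    def test_man5_free_mass_against_elemental_formula(self):
        # Man5 = Hex5HexNAc2; free glycan formula assembled atom by atom:
        # 5x C6H10O5 + 2x C8H13NO5 + H2O = C46H78N2O36
        man5 = GlycanComposition.from_string("Hex5HexNAc2")
        oracle = pmass.calculate_mass(formula="C46H78N2O36", average=True)
        assert glycan_mass(man5, "free", "average") == pytest.approx(oracle, abs=1e-6)
        assert glycan_mass(man5, "free", "average") == pytest.approx(1235.1, abs=0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            GlycanComposition(n_hex=-1)

    def test_string_round_trip(self):
        for text in ("", "Hex5HexNAc2", "Hex5HexNAc4dHex1Neu5Ac2"):
            assert str(GlycanComposition.from_string(text)) == text

    @given(
        a=st.lists(st.integers(0, 6), min_size=4, max_size=4),
        b=st.lists(st.integers(0, 6), min_size=4, max_size=4),
    )
    def test_mass_additivity(self, a, b):
        pep = "ANGTSEK"
        ca, cb = GlycanComposition(*a), GlycanComposition(*b)
        assert glycopeptide_mass(pep, ca + cb) == pytest.approx(
            glycopeptide_mass(pep, ca) + cb.residue_sum("average"), abs=1e-9
        )

    def test_adding_one_hex_adds_hex_residue(self):
        base = GlycanComposition.from_string("Hex5HexNAc2")
        grown = base.add({"Hex": 1})
        delta = grown.free_mass("average") - base.free_mass("average")
        assert delta == pytest.approx(monosaccharide_mass("Hex", "residue", "average"), abs=1e-9)


class TestPeptideMass:
    def test_polyglycine_monoisotopic(self):
        # 7 x Gly residue (57.02146) + water (18.010565)
        expected = 7 * 57.02146372057 + 18.0105646837
        assert peptide_mass("GGGGGGG", "mono") == pytest.approx(expected, abs=1e-5)

    def test_cysteine_carries_fixed_carbamidomethyl(self):
        bare = pmass.calculate_mass(sequence="ACDEFGK")
        assert peptide_mass("ACDEFGK", "mono") == pytest.approx(bare + 57.02146, abs=1e-4)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            peptide_mass("")

    def test_unknown_residue_errors(self):
        with pytest.raises(ValueError, match="B"):
            peptide_mass("GGBGGGG")

    def test_variable_mod_deltas(self):
        plain = peptide_mass(ModifiedPeptide("NMSTGGK"), "mono")
        ox = peptide_mass(ModifiedPeptide("NMSTGGK", ((2, "oxidation"),)), "mono")
        dea = peptide_mass(ModifiedPeptide("NMSTGGK", ((1, "deamidation_18O"),)), "mono")
        assert ox - plain == pytest.approx(15.9949146, abs=1e-5)
        assert dea - plain == pytest.approx(2.98826, abs=1e-5)

    def test_mod_on_wrong_residue_rejected(self):
        with pytest.raises(ValueError):
            ModifiedPeptide("GGGGGGG", ((1, "oxidation"),))  # G is not M

    def test_min_length_enforced(self):
        with pytest.raises(ValueError):
            ModifiedPeptide("GGG")


class TestDeamidationMarker:
    def test_rounded_shifts(self):
        assert deamidation_18o_shift(rounded=True) == 3
        assert deamidation_shift(rounded=True, labeled=False) == 1

    def test_monoisotopic_value_by_elemental_bookkeeping(self):
        # Asn -> Asp(18O): side-chain NH2 leaves, 18OH arrives
        expected = M_O18 - M_N - M_H
        assert deamidation_18o_shift("mono") == pytest.approx(expected, abs=1e-6)
        assert deamidation_18o_shift("mono") == pytest.approx(2.98826, abs=1e-5)


class TestGlycopeptideMass:
    def test_empty_composition_is_identity(self):
        assert glycopeptide_mass("ANGTSEK", GlycanComposition()) == pytest.approx(
            peptide_mass("ANGTSEK", "average"), abs=1e-12
        )

    def test_two_hex_difference(self):
        base = GlycanComposition.from_string("Hex5HexNAc2")
        grown = base.add({"Hex": 2})
        diff = glycopeptide_mass("ANGTSEK", grown) - glycopeptide_mass("ANGTSEK", base)
        assert diff == pytest.approx(324.3, abs=0.05)

    def test_no_asparagine_rejected(self):
        with pytest.raises(ValueError, match="asparagine"):
            glycopeptide_mass("GGGGGGK", GlycanComposition(n_hex=5))
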