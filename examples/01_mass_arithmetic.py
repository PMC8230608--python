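"""Monosaccharide, glycan and glycosite-marker mass arithmetic.

Builds a high-mannose glycan on a small tryptic peptide and prints the
mass increments that drive the SEC elution-shift method.
"""

from glycoshift import (
    GlycanComposition,
    deamidation_18o_shift,
    deamidation_shift,
    glycopeptide_mass,
    monosaccharide_mass,
    peptide_mass,
)

print("Free average monosaccharide masses (Da):")
for code in ("Hex", "HexNAc", "dHex", "Neu5Ac"):
    print(f"  {code:7s} {monosaccharide_mass(code, 'free', 'average'):7.2f}"
          f"  (residue {monosaccharide_mass(code, 'residue', 'average'):7.2f})")

pep = "LLNGSTFK"  # one N-G-S sequon
man5 = GlycanComposition.from_string("Hex5HexNAc2")
man7 = man5.add({"Hex": 2})
print(f"\nPeptide {pep}: {peptide_mass(pep, 'average'):.2f} Da (average)")
print(f"  + Man5 glycan -> {glycopeptide_mass(pep, man5):.2f} Da")
print(f"  + Man7 glycan -> {glycopeptide_mass(pep, man7):.2f} Da")
print(f"  a 2-hexose glycan change moves the intact glycopeptide by "
      f"{glycopeptide_mass(pep, man7) - glycopeptide_mass(pep, man5):.2f} Da")

print(f"\nGlycosite marker left by PNGase F in heavy water:")
print(f"  Asn -> Asp(18O): +{deamidation_18o_shift('mono'):.5f} Da "
      f"(nominal +{deamidation_18o_shift(rounded=True)} Da)")
print(f"  spontaneous deamidation: nominal "
      f"+{deamidation_shift(rounded=True, labeled=False)} Da — distinguishable")
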