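"""Mass arithmetic for glycopeptides carrying the ¹⁸O deamidation marker.

N-glycosidase F (PNGase F) releases N-glycans and converts the glycosylated
asparagine to aspartate.  Performed in H₂¹⁸O, the new carboxylate oxygen is
¹⁸O, so a former glycosite is marked by a +3 Da shift (nominal) instead of
the +1 Da of spontaneous deamidation.  This module provides the elemental
bookkeeping behind that marker, plus monosaccharide, glycan-composition,
peptide and intact-glycopeptide masses on both the monoisotopic and the
average scale.

Conventions
-----------
* Monosaccharide *free* masses are the masses of the free sugars
  (Hex = C6H12O6 etc.); *residue* masses are free masses minus one water.
  Every glycosidic bond — including the Asn–GlcNAc linkage — condenses out
  one water, so an intact glycopeptide mass is simply the peptide mass plus
  the plain sum of residue masses.  No water is double counted.
* Elemental masses come from the tables shipped with :mod:`pyteomics`
  (CODATA monoisotopic masses, IUPAC standard atomic weights for the
  average scale).
* Cysteines are assumed carbamidomethylated (the standard fixed
  modification of a reductive-alkylation workflow).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields

from pyteomics import mass as _pmass

__all__ = [
    "MONOSACCHARIDES",
    "Monosaccharide",
    "GlycanComposition",
    "ModifiedPeptide",
    "monosaccharide_mass",
    "glycan_mass",
    "peptide_mass",
    "deamidation_shift",
    "deamidation_18o_shift",
    "glycopeptide_mass",
    "water_mass",
]

_SCALES = ("mono", "average")

#: Masses of water on both scales (Da).
WATER = {
    "mono": _pmass.calculate_mass(formula="H2O"),
    "average": _pmass.calculate_mass(formula="H2O", average=True),
}

# isotope-resolved atomic masses used for the deamidation marker
_M_H = _pmass.nist_mass["H"][1][0]
_M_N14 = _pmass.nist_mass["N"][14][0]
_M_O16 = _pmass.nist_mass["O"][16][0]
_M_O18 = _pmass.nist_mass["O"][18][0]
_M_H_AVG = _pmass.calculate_mass(formula="H", average=True)
_M_N_AVG = _pmass.calculate_mass(formula="N", average=True)
_M_O_AVG = _pmass.calculate_mass(formula="O", average=True)


def _check_scale(scale: str) -> None:
    if scale not in _SCALES:
        raise ValueError(f"unknown mass scale {scale!r}; expected one of {_SCALES}")


def water_mass(scale: str = "mono") -> float:
    """Mass of one water molecule (Da)."""
    _check_scale(scale)
    return WATER[scale]


@dataclass(frozen=True)
class Monosaccharide:
    """One row of the monosaccharide mass table."""

    code: str
    formula: str
    free_mono: float
    free_average: float

    @property
    def residue_mono(self) -> float:
        return self.free_mono - WATER["mono"]

    @property
    def residue_average(self) -> float:
        return self.free_average - WATER["average"]

    def mass(self, form: str = "free", scale: str = "average") -> float:
        _check_scale(scale)
        if form not in ("free", "residue"):
            raise ValueError(f"unknown mass form {form!r}; expected 'free' or 'residue'")
        if form == "free":
            return self.free_mono if scale == "mono" else self.free_average
        return self.residue_mono if scale == "mono" else self.residue_average


def _build_table() -> dict[str, Monosaccharide]:
    formulas = {
        "Hex": "C6H12O6",      # glucose / galactose / mannose
        "HexNAc": "C8H15NO6",  # GlcNAc / GalNAc
        "dHex": "C6H12O5",     # fucose
        "Neu5Ac": "C11H19NO9",  # N-acetylneuraminic acid
    }
    table = {}
    for code, formula in formulas.items():
        table[code] = Monosaccharide(
            code=code,
            formula=formula,
            free_mono=_pmass.calculate_mass(formula=formula),
            free_average=_pmass.calculate_mass(formula=formula, average=True),
        )
    return table


#: Monosaccharide classes distinguishable by mass class in a glycan composition.
MONOSACCHARIDES: dict[str, Monosaccharide] = _build_table()


def monosaccharide_mass(code: str, form: str = "free", scale: str = "average") -> float:
    """Mass of one monosaccharide (Da).

    ``form='free'`` gives the free sugar, ``form='residue'`` the glycan
    residue (free minus one water).
    """
    try:
        entry = MONOSACCHARIDES[code]
    except KeyError:
        raise ValueError(
            f"unknown monosaccharide code {code!r}; known codes: "
            f"{sorted(MONOSACCHARIDES)}"
        ) from None
    return entry.mass(form=form, scale=scale)


_CODE_TO_ATTR = {"Hex": "n_hex", "HexNAc": "n_hexnac", "dHex": "n_dhex", "Neu5Ac": "n_neu5ac"}
_ATTR_TO_CODE = {v: k for k, v in _CODE_TO_ATTR.items()}
_COMP_RE = re.compile(r"(HexNAc|Hex|dHex|Neu5Ac)(\d+)")


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of monosaccharide classes making up one N-glycan.

    The empty composition is valid (a deglycosylated or never-glycosylated
    peptide).  Compositions are immutable; arithmetic helpers return new
    instances.
    """

    n_hex: int = 0
    n_hexnac: int = 0
    n_dhex: int = 0
    n_neu5ac: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"monosaccharide count {f.name}={v!r} must be a non-negative integer")

    # -- constructors -------------------------------------------------
    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "GlycanComposition":
        unknown = set(counts) - set(_CODE_TO_ATTR)
        if unknown:
            raise ValueError(f"unknown monosaccharide codes {sorted(unknown)}")
        return cls(**{_CODE_TO_ATTR[c]: n for c, n in counts.items()})

    @classmethod
    def from_string(cls, text: str) -> "GlycanComposition":
        """Parse a composition string such as ``"Hex5HexNAc2"`` ("" is empty)."""
        text = text.strip()
        if not text:
            return cls()
        counts: dict[str, int] = {}
        pos = 0
        for m in _COMP_RE.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse glycan composition {text!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2))
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse glycan composition {text!r}")
        return cls.from_counts(counts)

    # -- views --------------------------------------------------------
    def counts(self) -> dict[str, int]:
        return {code: getattr(self, attr) for code, attr in _CODE_TO_ATTR.items()}

    def total(self) -> int:
        return sum(self.counts().values())

    def __str__(self) -> str:
        return "".join(f"{code}{n}" for code, n in self.counts().items() if n)

    # -- arithmetic ---------------------------------------------------
    def add(self, delta: dict[str, int], clip: bool = False) -> "GlycanComposition":
        """Return a new composition with signed per-code ``delta`` applied.

        With ``clip=True`` counts that would go negative are clipped to 0.
        """
        counts = self.counts()
        for code, d in delta.items():
            if code not in counts:
                raise ValueError(f"unknown monosaccharide code {code!r}")
            counts[code] += d
        if clip:
            counts = {c: max(0, n) for c, n in counts.items()}
        return GlycanComposition.from_counts(counts)

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return self.add(other.counts())

    def residue_sum(self, scale: str = "average") -> float:
        """Sum of residue masses (Da): the mass the glycan adds to a peptide."""
        return sum(
            n * monosaccharide_mass(code, "residue", scale)
            for code, n in self.counts().items()
        )

    def free_mass(self, scale: str = "average") -> float:
        """Mass of the released glycan (residue sum plus one water)."""
        if self.total() == 0:
            return 0.0
        return self.residue_sum(scale) + WATER[scale]


def glycan_mass(comp: GlycanComposition, form: str = "residue_sum", scale: str = "average") -> float:
    """Mass of a glycan composition (Da).

    ``form='residue_sum'`` is the mass added to a peptide on attachment;
    ``form='free'`` is the mass of the released glycan.
    """
    _check_scale(scale)
    if form == "residue_sum":
        return comp.residue_sum(scale)
    if form == "free":
        return comp.free_mass(scale)
    raise ValueError(f"unknown mass form {form!r}; expected 'residue_sum' or 'free'")


_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")
MIN_PEPTIDE_LENGTH = 7

#: variable modification name -> residues it may sit on
MOD_TARGETS = {
    "oxidation": "M",
    "deamidation": "NQ",
    "deamidation_18O": "N",
}

_CAM_DELTA = {
    "mono": _pmass.calculate_mass(formula="C2H3NO"),
    "average": _pmass.calculate_mass(formula="C2H3NO", average=True),
}


def deamidation_shift(scale: str = "mono", rounded: bool = False, labeled: bool = True) -> float:
    """Mass shift of Asn -> Asp deamidation (Da).

    With ``labeled=True`` the incoming oxygen is ¹⁸O (PNGase F digestion in
    heavy water): the nominal shift is +3 Da instead of the +1 Da of plain
    deamidation.  On the average scale the label oxygen keeps its exact
    isotope mass (a label is not an isotope mixture); only N and H use
    standard atomic weights.
    """
    _check_scale(scale)
    if scale == "mono":
        o = _M_O18 if labeled else _M_O16
        delta = o - _M_N14 - _M_H
    else:
        o = _M_O18 if labeled else _M_O_AVG
        delta = o - _M_N_AVG - _M_H_AVG
    return round(delta) if rounded else delta


def deamidation_18o_shift(scale: str = "mono", rounded: bool = False) -> float:
    """Mass shift of the ¹⁸O glycosite marker (Asn -> Asp(¹⁸O))."""
    return deamidation_shift(scale=scale, rounded=rounded, labeled=True)


def _mod_delta(name: str, scale: str) -> float:
    if name == "oxidation":
        return _M_O16 if scale == "mono" else _M_O_AVG
    if name == "deamidation":
        return deamidation_shift(scale, labeled=False)
    if name == "deamidation_18O":
        return deamidation_shift(scale, labeled=True)
    raise ValueError(f"unknown modification {name!r}; known: {sorted(MOD_TARGETS)}")


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with its modification state.

    Carbamidomethylation of every cysteine is fixed (applied implicitly);
    ``variable_mods`` is a tuple of ``(position, name)`` with 1-based
    positions and names among :data:`MOD_TARGETS`.
    """

    sequence: str
    variable_mods: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence, min_length=MIN_PEPTIDE_LENGTH)
        object.__setattr__(self, "variable_mods", tuple(self.variable_mods))
        for pos, name in self.variable_mods:
            if name not in MOD_TARGETS:
                raise ValueError(f"unknown modification {name!r}")
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside peptide of length {len(self.sequence)}")
            residue = self.sequence[pos - 1]
            if residue not in MOD_TARGETS[name]:
                raise ValueError(
                    f"modification {name!r} cannot sit on residue {residue!r} at position {pos}"
                )


def _validate_sequence(seq: str, min_length: int = 1) -> None:
    if not seq:
        raise ValueError("empty peptide sequence")
    bad = set(seq) - _VALID_AA
    if bad:
        raise ValueError(f"unknown amino-acid letter(s) {sorted(bad)} in sequence {seq!r}")
    if len(seq) < min_length:
        raise ValueError(f"peptide {seq!r} shorter than minimum length {min_length}")


def peptide_mass(pep: "ModifiedPeptide | str", scale: str = "mono") -> float:
    """Neutral mass of a (modified) peptide (Da).

    Plain strings are accepted as unmodified peptides (cysteines still get
    the fixed carbamidomethyl).
    """
    _check_scale(scale)
    if isinstance(pep, str):
        _validate_sequence(pep)
        seq, mods = pep, ()
    else:
        seq, mods = pep.sequence, pep.variable_mods
    m = _pmass.calculate_mass(sequence=seq, average=(scale == "average"))
    m += seq.count("C") * _CAM_DELTA[scale]
    for _pos, name in mods:
        m += _mod_delta(name, scale)
    return m


def glycopeptide_mass(pep: "ModifiedPeptide | str", comp: GlycanComposition, scale: str = "average") -> float:
    """Neutral mass of an intact glycopeptide (Da).

    The glycan contributes its residue-mass sum: attachment to the sequon
    asparagine condenses out one water, which is already encoded in the
    residue masses.
    """
    seq = pep if isinstance(pep, str) else pep.sequence
    if "N" not in seq:
        raise ValueError(f"peptide {seq!r} has no asparagine to carry an N-glycan")
    return peptide_mass(pep, scale) + comp.residue_sum(scale)
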