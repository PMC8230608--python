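"""Ground-truthed synthetic two-condition glycoproteomics fixtures.

The generator emulates the full experimental chain feeding the analysis:
a small proteome digested with trypsin, N-glycosites on N-X-(S/T) sequons
(X != P), per-condition glycan compositions drawn from a high-mannose-
weighted pool (the lectin-enrichment step binds mannose), SEC fraction
assignment of each intact glycopeptide through the deterministic
calibration model, and per-fraction site/peptide tables in the exact
dialect :mod:`glycoshift.io_tables` reads — plus decoy and contaminant
rows, a localization-probability mixture, detection dropout, a synthetic
known-glycosite catalogue and a small synthetic GO cellular-component
ontology with gene annotations.

A treatment effect perturbs the glycan composition of a configurable
fraction of sites, biased toward mass gain (mirroring treatments that
drive higher-mass glycan structures).  Everything derives from a single
seed: identical config => byte-identical fixture.  The emitted truth table
records, per glycopeptide, both conditions' compositions, masses,
expected fractions and the expected differential flag, all recomputable
from composition + calibration alone.

What the simulator does *not* model: spectra, intensities, retention
times, peak tailing, shared peptides (sequences are kept unique so the
ground truth is per-peptide unambiguous) and realistic database sequences.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .masses import GlycanComposition, glycopeptide_mass
from .sec import SECCalibration, fraction_for_mass
from .shifts import DEFAULT_MIN_SHIFT

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimPeptide",
    "SimProtein",
    "TruthRecord",
    "FixtureResult",
    "find_sequons",
    "parse_effect",
    "generate_proteome",
    "assign_glycans",
    "build_truth",
    "emit_fixture",
    "DEFAULT_GLYCAN_POOL",
    "DEFAULT_EFFECTS",
    "SINGLE_MONO_EFFECTS",
]

#: control-condition glycan pool (composition, weight): high-mannose
#: dominated, ConA-compatible, with a tail of hybrid/complex structures.
DEFAULT_GLYCAN_POOL: tuple[tuple[str, float], ...] = (
    ("Hex5HexNAc2", 0.25),   # Man5
    ("Hex6HexNAc2", 0.20),   # Man6
    ("Hex7HexNAc2", 0.15),   # Man7
    ("Hex8HexNAc2", 0.10),   # Man8
    ("Hex9HexNAc2", 0.10),   # Man9
    ("Hex5HexNAc3", 0.08),
    ("Hex6HexNAc3", 0.05),
    ("Hex5HexNAc4Neu5Ac1", 0.04),
    ("Hex5HexNAc4dHex1", 0.03),
)

#: treatment effect pool (signed composition delta, weight): >= 2
#: monosaccharides each, biased toward mass gain.
DEFAULT_EFFECTS: tuple[tuple[str, float], ...] = (
    ("+2Hex", 0.45),
    ("+3Hex", 0.20),
    ("+1Hex+1HexNAc", 0.20),
    ("-2Hex", 0.15),
)

#: single-monosaccharide effects, at the resolution limit of the method.
SINGLE_MONO_EFFECTS: tuple[tuple[str, float], ...] = (
    ("+1Hex", 0.4),
    ("+1HexNAc", 0.3),
    ("+1Neu5Ac", 0.3),
)

# residues used for peptide bodies: tryptic-interior letters, no K/R
# (cleavage sites), no N (sequons are injected explicitly so each
# glycopeptide has exactly one, keeping the ground truth unambiguous).
_BODY_POOL = "ACDEFGHILMQSTVWY"
_SEQUON_X_POOL = "ACDEFGHILMQSTVWY"  # X of N-X-S/T may be anything but P


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one synthetic experiment.

    The mass window is the glycopeptide mass range that survives both
    fraction collection and MS detection; together with the calibration it
    fixes which glycan changes are resolvable (two monosaccharides
    anywhere in the window, one monosaccharide only near its light edge).
    """

    seed: int = 0
    n_proteins: int = 50
    peptides_per_protein: int = 8
    glycosite_rate: float = 0.8
    targeted_fraction: float = 0.3
    effects: tuple[tuple[str, float], ...] = DEFAULT_EFFECTS
    glycan_pool: tuple[tuple[str, float], ...] = DEFAULT_GLYCAN_POOL
    dropout_rate: float = 0.1
    low_localization_fraction: float = 0.15
    contaminant_rate: float = 0.05
    reverse_rate: float = 0.05
    conA_min_hex: int = 3
    multi_peptide_rate: float = 0.1
    elution_spread: int = 1
    mass_window: tuple[float, float] = (1600.0, 3400.0)
    peptide_length_range: tuple[int, int] = (7, 12)
    atlas_known_fraction: float = 0.7
    pm_gene_fraction: float = 0.42
    unannotated_gene_fraction: float = 0.05
    min_shift: int = DEFAULT_MIN_SHIFT
    calibration: SECCalibration = field(default_factory=SECCalibration)

    def __post_init__(self) -> None:
        for name in (
            "glycosite_rate", "targeted_fraction", "dropout_rate",
            "low_localization_fraction", "contaminant_rate", "reverse_rate",
            "multi_peptide_rate", "atlas_known_fraction", "pm_gene_fraction",
            "unannotated_gene_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        object.__setattr__(self, "effects", tuple((str(e), float(w)) for e, w in self.effects))
        object.__setattr__(
            self, "glycan_pool", tuple((str(c), float(w)) for c, w in self.glycan_pool)
        )
        if self.peptide_length_range[0] < 7:
            raise ValueError("minimum peptide length is 7")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"] = [list(x) for x in self.effects]
        d["glycan_pool"] = [list(x) for x in self.glycan_pool]
        d["calibration"] = self.calibration.to_dict()
        d["mass_window"] = list(self.mass_window)
        d["peptide_length_range"] = list(self.peptide_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "calibration" in d and isinstance(d["calibration"], dict):
            d["calibration"] = SECCalibration.from_dict(d["calibration"])
        for key in ("effects", "glycan_pool"):
            if key in d:
                d[key] = tuple(tuple(x) for x in d[key])
        for key in ("mass_window", "peptide_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


_SEQUON_RE = re.compile(r"N[^P][ST]")


def find_sequons(sequence: str) -> list[int]:
    """0-based positions of N-X-(S/T) sequons (X != P), overlap-aware."""
    out = []
    for i in range(len(sequence) - 2):
        if _SEQUON_RE.match(sequence, i):
            out.append(i)
    return out


_EFFECT_RE = re.compile(r"([+-]\d+)(HexNAc|Hex|dHex|Neu5Ac)")


def parse_effect(text: str) -> dict[str, int]:
    """Parse an effect string like ``"+2Hex"`` or ``"+1Hex+1HexNAc"``."""
    text = text.strip()
    delta: dict[str, int] = {}
    pos = 0
    for m in _EFFECT_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse effect {text!r}")
        delta[m.group(2)] = delta.get(m.group(2), 0) + int(m.group(1))
        pos = m.end()
    if pos != len(text) or not delta:
        raise ValueError(f"cannot parse effect {text!r}")
    return delta


def effect_to_string(delta: dict[str, int]) -> str:
    return "".join(f"{n:+d}{code}" for code, n in delta.items() if n)


@dataclass(frozen=True)
class SimPeptide:
    """One tryptic peptide; ``site_offset`` is the 0-based sequon N, if any."""

    sequence: str
    site_offset: Optional[int]


@dataclass(frozen=True)
class SimProtein:
    accession: str
    gene: str
    sequence: str
    peptides: tuple[tuple[int, SimPeptide], ...]  # (0-based start in protein, peptide)


def _draw_peptide(rng: np.random.Generator, cfg: SimulationConfig, glyco: bool) -> SimPeptide:
    lo, hi = cfg.peptide_length_range
    length = int(rng.integers(lo, hi + 1))
    chars = [str(c) for c in rng.choice(list(_BODY_POOL), size=length - 1)]
    # tryptic C-terminus; no proline at the N-terminus (trypsin does not
    # cleave before P, so such a peptide would not exist)
    chars.append("K" if rng.random() < 0.5 else "R")
    while chars[0] == "P":
        chars[0] = str(rng.choice(list(_BODY_POOL.replace("P", ""))))
    offset = None
    if glyco:
        offset = int(rng.integers(0, length - 3))  # keep sequon off the C-term K/R
        chars[offset] = "N"
        chars[offset + 1] = str(rng.choice(list(_SEQUON_X_POOL)))
        chars[offset + 2] = "S" if rng.random() < 0.5 else "T"
    return SimPeptide(sequence="".join(chars), site_offset=offset)


def generate_proteome(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> list[SimProtein]:
    """Generate proteins made of unique tryptic peptides.

    Every glycosite sits on an N-X-(S/T) sequon with X != P; peptide bodies
    contain no other asparagine, so each glycopeptide carries exactly one
    sequon.  Sequences are unique across the whole proteome.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    seen: set[str] = set()
    proteins = []
    for p in range(cfg.n_proteins):
        peptides = []
        offset = 0
        for _ in range(cfg.peptides_per_protein):
            glyco = bool(rng.random() < cfg.glycosite_rate)
            for _attempt in range(1000):
                pep = _draw_peptide(rng, cfg, glyco)
                if pep.sequence not in seen:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not draw a unique peptide sequence")
            seen.add(pep.sequence)
            peptides.append((offset, pep))
            offset += len(pep.sequence)
        sequence = "".join(pep.sequence for _s, pep in peptides)
        proteins.append(
            SimProtein(
                accession=f"P{p + 1:05d}",
                gene=f"GENE{p + 1:03d}",
                sequence=sequence,
                peptides=tuple(peptides),
            )
        )
    return proteins


@dataclass
class TruthRecord:
    """Ground truth for one simulated glycopeptide (one sequon)."""

    accession: str
    gene: str
    sequence: str
    position: int  # 1-based sequon N within the protein
    control_composition: GlycanComposition
    treated_composition: GlycanComposition
    targeted: bool
    effect: str
    control_mass: float = 0.0
    treated_mass: float = 0.0
    observed_control: bool = False
    observed_treated: bool = False
    fractions_control: tuple[int, ...] = ()
    fractions_treated: tuple[int, ...] = ()
    expected_delta_first: Optional[int] = None
    expected_delta_last: Optional[int] = None
    expected_differential: Optional[bool] = None
    known_in_atlas: bool = False
    plasma_membrane: bool = False


def assign_glycans(
    cfg: SimulationConfig,
    proteins: list[SimProtein],
    rng: Optional[np.random.Generator] = None,
) -> list[TruthRecord]:
    """Draw per-condition glycan compositions for every sequon peptide.

    Control compositions come from the configured pool; a ``targeted``
    fraction of sites gets its treated composition shifted by an effect
    delta (counts clipped at zero), the rest are identical across
    conditions.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pool = [GlycanComposition.from_string(c) for c, _w in cfg.glycan_pool]
    pool_w = np.array([w for _c, w in cfg.glycan_pool], dtype=float)
    pool_w /= pool_w.sum()
    eff = [parse_effect(e) for e, _w in cfg.effects]
    eff_w = np.array([w for _e, w in cfg.effects], dtype=float)
    eff_w /= eff_w.sum()

    truth = []
    for protein in proteins:
        for start, pep in protein.peptides:
            if pep.site_offset is None:
                continue
            control = pool[int(rng.choice(len(pool), p=pool_w))]
            targeted = bool(rng.random() < cfg.targeted_fraction)
            if targeted:
                delta = eff[int(rng.choice(len(eff), p=eff_w))]
                treated = control.add(delta, clip=True)
                effect = effect_to_string(delta)
            else:
                treated, effect = control, ""
            truth.append(
                TruthRecord(
                    accession=protein.accession,
                    gene=protein.gene,
                    sequence=pep.sequence,
                    position=start + pep.site_offset + 1,
                    control_composition=control,
                    treated_composition=treated,
                    targeted=targeted,
                    effect=effect,
                )
            )
    return truth


def _observed(cfg: SimulationConfig, comp: GlycanComposition, mass: float) -> bool:
    """Is a glycopeptide with this composition/mass observable at all?

    It must be captured by the mannose-binding lectin (Hex count >=
    ``conA_min_hex``, the trimannosyl-core requirement) and its intact
    mass must fall inside the collected + detectable window.
    """
    lo, hi = cfg.mass_window
    return comp.n_hex >= cfg.conA_min_hex and lo <= mass <= hi


def _expected_fractions(cfg: SimulationConfig, mass: float) -> tuple[int, ...]:
    f = fraction_for_mass(mass, cfg.calibration)
    last = min(f + cfg.elution_spread, cfg.calibration.n_fractions)
    return tuple(range(f, last + 1))


def build_truth(cfg: SimulationConfig, truth: list[TruthRecord]) -> list[TruthRecord]:
    """Fill in masses, observability, expected fractions and flags.

    Sites observable in neither condition are dropped (they were never
    captured / never eluted into the collection window).
    """
    kept = []
    for t in truth:
        t.control_mass = glycopeptide_mass(t.sequence, t.control_composition, "average")
        t.treated_mass = glycopeptide_mass(t.sequence, t.treated_composition, "average")
        t.observed_control = _observed(cfg, t.control_composition, t.control_mass)
        t.observed_treated = _observed(cfg, t.treated_composition, t.treated_mass)
        if not (t.observed_control or t.observed_treated):
            continue
        if t.observed_control:
            t.fractions_control = _expected_fractions(cfg, t.control_mass)
        if t.observed_treated:
            t.fractions_treated = _expected_fractions(cfg, t.treated_mass)
        if t.observed_control and t.observed_treated:
            t.expected_delta_first = min(t.fractions_control) - min(t.fractions_treated)
            t.expected_delta_last = max(t.fractions_control) - max(t.fractions_treated)
            t.expected_differential = (
                abs(t.expected_delta_first) >= cfg.min_shift
                or abs(t.expected_delta_last) >= cfg.min_shift
            )
        kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# fixture emission

_SITE_HEADER = [
    "Proteins", "Protein names", "Gene names", "Position",
    "Localization prob", "Peptide IDs", "Reverse", "Potential contaminant",
]
_PEPTIDE_HEADER = ["id", "Sequence", "Protein names", "Gene names"]

# synthetic GO cellular-component ontology: a real-id skeleton with a
# plasma-membrane branch (both is_a and part_of children) and distractors.
_GO_TERMS: tuple[tuple[str, str, tuple[tuple[str, str], ...]], ...] = (
    ("GO:0005575", "cellular_component", ()),
    ("GO:0016020", "membrane", (("is_a", "GO:0005575"),)),
    ("GO:0005886", "plasma membrane", (("is_a", "GO:0016020"),)),
    ("GO:0009897", "external side of plasma membrane", (("part_of", "GO:0005886"),)),
    ("GO:0005887", "integral component of plasma membrane",
     (("is_a", "GO:0016021"), ("part_of", "GO:0005886"))),
    ("GO:0016021", "integral component of membrane", (("is_a", "GO:0016020"),)),
    ("GO:0005737", "cytoplasm", (("is_a", "GO:0005575"),)),
    ("GO:0005634", "nucleus", (("is_a", "GO:0005575"),)),
    ("GO:0005783", "endoplasmic reticulum", (("is_a", "GO:0005737"),)),
    ("GO:0005794", "Golgi apparatus", (("is_a", "GO:0005737"),)),
)
_PM_BRANCH_TERMS = ("GO:0005886", "GO:0009897", "GO:0005887")
_NON_PM_TERMS = ("GO:0016020", "GO:0016021", "GO:0005737", "GO:0005634", "GO:0005783", "GO:0005794")


def _obo_text() -> str:
    lines = ["format-version: 1.2", "ontology: go-synthetic", ""]
    for term_id, name, rels in _GO_TERMS:
        lines += [f"[Term]", f"id: {term_id}", f"name: {name}", "namespace: cellular_component"]
        for rel, parent in rels:
            lines.append(f"is_a: {parent}" if rel == "is_a" else f"relationship: part_of {parent}")
        lines.append("")
    return "\n".join(lines)


@dataclass
class FixtureResult:
    """Paths and ground truth of one emitted fixture."""

    truth: list[TruthRecord]
    control_dir: Path
    treated_dir: Path
    truth_path: Path
    atlas_path: Path
    obo_path: Path
    annotation_path: Path
    gene_pm_flags: dict[str, bool]


def _truth_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    def na(v):
        return "NA" if v is None else v

    rows = []
    for t in truth:
        rows.append(
            {
                "accession": t.accession,
                "gene": t.gene,
                "sequence": t.sequence,
                "position": t.position,
                "control_composition": str(t.control_composition),
                "treated_composition": str(t.treated_composition),
                "targeted": t.targeted,
                "effect": t.effect,
                "control_mass": round(t.control_mass, 4),
                "treated_mass": round(t.treated_mass, 4),
                "observed_control": t.observed_control,
                "observed_treated": t.observed_treated,
                "control_fractions": ";".join(map(str, t.fractions_control)),
                "treated_fractions": ";".join(map(str, t.fractions_treated)),
                "expected_delta_first": na(t.expected_delta_first),
                "expected_delta_last": na(t.expected_delta_last),
                "expected_differential": na(t.expected_differential),
                "known_in_atlas": t.known_in_atlas,
                "plasma_membrane": t.plasma_membrane,
            }
        )
    return pd.DataFrame(rows)


def emit_fixture(cfg: SimulationConfig, outdir) -> FixtureResult:
    """Generate and write a complete fixture under ``outdir``.

    Layout: ``control/C<f>.sites.tsv`` + ``.peptides.tsv`` (one pair per
    fraction, header-only when empty), same for ``treated/T<f>``, plus
    ``truth.csv``, ``atlas.tsv``, ``go.obo`` and ``gocc_annotation.tsv``.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(cfg.seed)

    proteins = generate_proteome(cfg, rng)
    truth = build_truth(cfg, assign_glycans(cfg, proteins, rng))
    if not truth:
        logger.warning("simulation produced no observable glycopeptides")

    # known-glycosite catalogue membership
    for t in truth:
        t.known_in_atlas = bool(rng.random() < cfg.atlas_known_fraction)

    # gene -> GOCC annotation and plasma-membrane flag
    gene_terms: dict[str, tuple[str, ...]] = {}
    gene_pm: dict[str, bool] = {}
    for protein in proteins:
        if rng.random() < cfg.unannotated_gene_fraction:
            gene_pm[protein.gene] = False
            continue
        pm = bool(rng.random() < cfg.pm_gene_fraction)
        gene_pm[protein.gene] = pm
        main_pool = _PM_BRANCH_TERMS if pm else _NON_PM_TERMS
        terms = {str(rng.choice(main_pool))}
        if rng.random() < 0.5:  # a second, always non-diagnostic term
            terms.add(str(rng.choice(_NON_PM_TERMS)))
        gene_terms[protein.gene] = tuple(sorted(terms))
    for t in truth:
        t.plasma_membrane = gene_pm.get(t.gene, False)

    # per-(condition, fraction) observation rows
    rows: dict[tuple[str, int], list[dict]] = {}
    for t in truth:
        for condition, observed, fractions in (
            ("control", t.observed_control, t.fractions_control),
            ("treated", t.observed_treated, t.fractions_treated),
        ):
            if not observed:
                continue
            for fraction in fractions:
                if rng.random() < cfg.dropout_rate:
                    continue
                if rng.random() < cfg.low_localization_fraction:
                    prob = round(float(rng.uniform(0.30, 0.749)), 4)
                else:
                    prob = round(float(rng.uniform(0.7501, 0.9999)), 4)
                multi = bool(rng.random() < cfg.multi_peptide_rate)
                rows.setdefault((condition, fraction), []).append(
                    {
                        "accession": t.accession,
                        "protein_names": f"Protein {t.gene}",
                        "gene": t.gene,
                        "position": t.position,
                        "prob": prob,
                        "sequence": t.sequence,
                        "multi": multi,
                        "reverse": "",
                        "contaminant": "",
                    }
                )

    # decoy / contaminant injection, proportional to real rows per fraction
    decoy_id = 0
    for key in sorted(rows):
        real = rows[key]
        n_cont = int(rng.binomial(len(real), cfg.contaminant_rate))
        n_rev = int(rng.binomial(len(real), cfg.reverse_rate))
        for kind, n in (("contaminant", n_cont), ("reverse", n_rev)):
            for _ in range(n):
                decoy_id += 1
                seq = "".join(str(c) for c in rng.choice(list(_BODY_POOL), size=9)) + "K"
                prefix = "CON__" if kind == "contaminant" else "REV__"
                real.append(
                    {
                        "accession": f"{prefix}Q{decoy_id:05d}",
                        "protein_names": f"{prefix}decoy {decoy_id}",
                        "gene": f"{prefix}G{decoy_id}",
                        "position": int(rng.integers(1, 500)),
                        "prob": round(float(rng.uniform(0.40, 0.9999)), 4),
                        "sequence": seq,
                        "multi": False,
                        "reverse": "+" if kind == "reverse" else "",
                        "contaminant": "+" if kind == "contaminant" else "",
                    }
                )

    # write per-fraction table pairs (all fractions, header-only if empty)
    dirs = {"control": outdir / "control", "treated": outdir / "treated"}
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)
    letter = {"control": "C", "treated": "T"}
    for condition, d in dirs.items():
        for fraction in range(1, cfg.calibration.n_fractions + 1):
            frac_rows = rows.get((condition, fraction), [])
            site_rows, pep_rows = [], []
            pid = 0
            for r in frac_rows:
                ids = [pid]
                pep_rows.append([pid, r["sequence"], r["protein_names"], r["gene"]])
                pid += 1
                if r["multi"]:  # same sequence under a second peptide id
                    ids.append(pid)
                    pep_rows.append([pid, r["sequence"], r["protein_names"], r["gene"]])
                    pid += 1
                site_rows.append(
                    [
                        r["accession"], r["protein_names"], r["gene"], r["position"],
                        r["prob"], ";".join(map(str, ids)), r["reverse"], r["contaminant"],
                    ]
                )
            stem = f"{letter[condition]}{fraction}"
            pd.DataFrame(site_rows, columns=_SITE_HEADER).to_csv(
                d / f"{stem}.sites.tsv", sep="\t", index=False
            )
            pd.DataFrame(pep_rows, columns=_PEPTIDE_HEADER).to_csv(
                d / f"{stem}.peptides.tsv", sep="\t", index=False
            )

    # truth table
    truth_path = outdir / "truth.csv"
    _truth_frame(truth).to_csv(truth_path, index=False)

    # known-glycosite catalogue: true members plus fake entries
    atlas_rows = [
        {"Accession": t.accession, "Position": t.position} for t in truth if t.known_in_atlas
    ]
    for i in range(20):
        atlas_rows.append(
            {"Accession": f"Z{int(rng.integers(10000, 99999)):05d}", "Position": int(rng.integers(1, 800))}
        )
    atlas_path = outdir / "atlas.tsv"
    pd.DataFrame(atlas_rows, columns=["Accession", "Position"]).to_csv(
        atlas_path, sep="\t", index=False
    )

    # ontology + annotation
    obo_path = outdir / "go.obo"
    obo_path.write_text(_obo_text())
    term_names = {tid: name for tid, name, _r in _GO_TERMS}
    annot_rows = [
        {"gene": gene, "term": term, "term name": term_names[term]}
        for gene in sorted(gene_terms)
        for term in gene_terms[gene]
    ]
    annotation_path = outdir / "gocc_annotation.tsv"
    pd.DataFrame(annot_rows, columns=["gene", "term", "term name"]).to_csv(
        annotation_path, sep="\t", index=False
    )

    return FixtureResult(
        truth=truth,
        control_dir=dirs["control"],
        treated_dir=dirs["treated"],
        truth_path=truth_path,
        atlas_path=atlas_path,
        obo_path=obo_path,
        annotation_path=annotation_path,
        gene_pm_flags=gene_pm,
    )
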