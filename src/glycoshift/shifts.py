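"""Per-peptide SEC elution-shift analysis between two conditions.

This is the core computation of differential glycosite profiling: every
unique peptide sequence gets, per condition, the sorted set of fractions
it was identified in; the first (minimum) and last (maximum) elution
fractions are compared between control and treated, and a peptide whose
first or last elution moved by more than one fraction is classified as
differentially glycosylated.  Peptides seen in only one condition carry no
comparable information and are coded NA throughout.

Sign convention: ``delta = control - treated``, so a positive delta means
the peptide eluted *earlier* (in a lower-numbered fraction, i.e. at higher
mass) in the treated condition — "upgraded".  Negative deltas are
"downgraded".  The two elution statistics (first and last) are counted
independently: a peptide may be upgraded in one and downgraded in the
other.

Grouping is by bare amino-acid sequence only.  Carbamidomethylation,
oxidation and deamidation change mass by far too little to move a peptide
across SEC fractions, so modification state is ignored; a sequence bearing
two glycosites still yields a single profile carrying both sites' metadata.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_tables import GlycositeRecord, RunLabel

__all__ = [
    "PeptideFractionProfile",
    "ShiftResult",
    "AnnotatedResult",
    "SummaryCounts",
    "build_profiles",
    "compute_shift",
    "summarize",
    "DEFAULT_MIN_SHIFT",
]

#: minimum absolute fraction shift called differential ("larger than 1").
DEFAULT_MIN_SHIFT = 2


@dataclass(frozen=True)
class PeptideFractionProfile:
    """One unique peptide sequence with its per-condition fraction sets."""

    sequence: str
    fractions_control: Optional[tuple[int, ...]] = None
    fractions_treated: Optional[tuple[int, ...]] = None
    gene_names: tuple[str, ...] = ()
    protein_names: str = ""
    accessions: tuple[str, ...] = ()
    positions: tuple[int, ...] = ()
    site_keys: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.fractions_control is None and self.fractions_treated is None:
            raise ValueError(f"profile {self.sequence!r} has no detections in either condition")
        for fr in (self.fractions_control, self.fractions_treated):
            if fr is not None and (len(fr) == 0 or list(fr) != sorted(set(fr))):
                raise ValueError(f"fraction set {fr!r} must be sorted, unique and non-empty")


@dataclass(frozen=True)
class ShiftResult:
    """First/last-elution deltas and differential status of one peptide.

    ``differential`` is ``None`` (NA) when the peptide was seen in only one
    condition; directions are ``"upgraded"``, ``"downgraded"`` or
    ``"none"`` (``None`` when NA).
    """

    sequence: str
    min_control: Optional[int]
    max_control: Optional[int]
    min_treated: Optional[int]
    max_treated: Optional[int]
    delta_first: Optional[int]
    delta_last: Optional[int]
    differential: Optional[bool]
    direction_first: Optional[str]
    direction_last: Optional[str]


def compute_shift(profile: PeptideFractionProfile, min_shift: int = DEFAULT_MIN_SHIFT) -> ShiftResult:
    """Classify one peptide profile.

    Differential iff |delta_first| >= min_shift or |delta_last| >= min_shift
    (the default of 2 is the integer form of "absolute difference larger
    than 1").  Single-condition profiles get NA everywhere.
    """
    fc, ft = profile.fractions_control, profile.fractions_treated
    if fc is None or ft is None:
        return ShiftResult(
            sequence=profile.sequence,
            min_control=min(fc) if fc else None,
            max_control=max(fc) if fc else None,
            min_treated=min(ft) if ft else None,
            max_treated=max(ft) if ft else None,
            delta_first=None,
            delta_last=None,
            differential=None,
            direction_first=None,
            direction_last=None,
        )
    delta_first = min(fc) - min(ft)
    delta_last = max(fc) - max(ft)

    def direction(d: int) -> str:
        if d > 0:
            return "upgraded"
        if d < 0:
            return "downgraded"
        return "none"

    return ShiftResult(
        sequence=profile.sequence,
        min_control=min(fc),
        max_control=max(fc),
        min_treated=min(ft),
        max_treated=max(ft),
        delta_first=delta_first,
        delta_last=delta_last,
        differential=abs(delta_first) >= min_shift or abs(delta_last) >= min_shift,
        direction_first=direction(delta_first),
        direction_last=direction(delta_last),
    )


def build_profiles(
    rows: Iterable[tuple[GlycositeRecord, str, RunLabel]],
) -> list[PeptideFractionProfile]:
    """Group exploded site rows into per-sequence fraction profiles.

    ``rows`` carry (site record, peptide sequence, run label).  Fractions
    are deduplicated and sorted; site metadata from every contributing row
    is unioned onto the profile.  Output is sorted by sequence so repeated
    runs are reproducible.
    """
    frac: dict[str, dict[str, set[int]]] = {}
    meta: dict[str, dict[str, set]] = {}
    for record, sequence, label in rows:
        f = frac.setdefault(sequence, {"control": set(), "treated": set()})
        f[label.condition].add(label.fraction)
        m = meta.setdefault(
            sequence, {"genes": set(), "proteins": set(), "accessions": set(), "sites": set()}
        )
        m["genes"].update(record.gene_names)
        if record.protein_names:
            m["proteins"].add(record.protein_names)
        m["accessions"].update(record.accessions)
        m["sites"].add(record.site_key)

    profiles = []
    for sequence in sorted(frac):
        f, m = frac[sequence], meta[sequence]
        profiles.append(
            PeptideFractionProfile(
                sequence=sequence,
                fractions_control=tuple(sorted(f["control"])) or None,
                fractions_treated=tuple(sorted(f["treated"])) or None,
                gene_names=tuple(sorted(m["genes"])),
                protein_names=";".join(sorted(m["proteins"])),
                accessions=tuple(sorted(m["accessions"])),
                positions=tuple(sorted(p for _a, p in m["sites"])),
                site_keys=tuple(sorted(m["sites"])),
            )
        )
    return profiles


@dataclass(frozen=True)
class AnnotatedResult:
    """Final result row for one peptide: shift plus annotations."""

    sequence: str
    gene_names: tuple[str, ...]
    protein_names: str
    positions: tuple[int, ...]
    fractions_control: Optional[tuple[int, ...]]
    fractions_treated: Optional[tuple[int, ...]]
    shift: ShiftResult
    known_glycosite: bool = False
    gocc_ids: tuple[str, ...] = ()
    plasma_membrane: bool = False


@dataclass
class SummaryCounts:
    """Audit-trail counts of one profiling run.

    ``histogram_first``/``histogram_last`` count peptides per delta value
    (in-both peptides only); ``upgraded_*``/``downgraded_*`` count peptides
    whose shift reached the differential threshold, per elution statistic.
    """

    total_sites: int = 0
    known_sites: int = 0
    total_peptides: int = 0
    peptides_in_both: int = 0
    differential: int = 0
    differential_plasma_membrane: int = 0
    upgraded_first: int = 0
    downgraded_first: int = 0
    upgraded_last: int = 0
    downgraded_last: int = 0
    histogram_first: dict[int, int] = field(default_factory=dict)
    histogram_last: dict[int, int] = field(default_factory=dict)

    def check(self) -> None:
        """Assert the count ordering any valid run must satisfy."""
        ok = (
            self.differential_plasma_membrane
            <= self.differential
            <= self.peptides_in_both
            <= self.total_peptides
        )
        if not ok:
            raise AssertionError(
                "summary count ordering violated: "
                f"pm={self.differential_plasma_membrane} diff={self.differential} "
                f"both={self.peptides_in_both} total={self.total_peptides}"
            )


def summarize(
    results: Iterable[AnnotatedResult],
    total_sites: int = 0,
    known_sites: int = 0,
    min_shift: int = DEFAULT_MIN_SHIFT,
) -> SummaryCounts:
    """Tabulate a result set into summary counts and shift histograms.

    Peptides present in only one condition (NA) are excluded from the
    in-both, differential and histogram counts.
    """
    s = SummaryCounts(total_sites=total_sites, known_sites=known_sites)
    hist_first: Counter = Counter()
    hist_last: Counter = Counter()
    for r in results:
        s.total_peptides += 1
        sh = r.shift
        if sh.differential is None:
            continue
        s.peptides_in_both += 1
        hist_first[sh.delta_first] += 1
        hist_last[sh.delta_last] += 1
        if sh.differential:
            s.differential += 1
            if r.plasma_membrane:
                s.differential_plasma_membrane += 1
        if sh.delta_first >= min_shift:
            s.upgraded_first += 1
        elif sh.delta_first <= -min_shift:
            s.downgraded_first += 1
        if sh.delta_last >= min_shift:
            s.upgraded_last += 1
        elif sh.delta_last <= -min_shift:
            s.downgraded_last += 1
    s.histogram_first = dict(sorted(hist_first.items()))
    s.histogram_last = dict(sorted(hist_last.items()))
    s.check()
    return s
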