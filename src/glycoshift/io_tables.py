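"""Reading and writing the pipeline's tab-separated tables.

Inputs are per-fraction pairs of search-engine exports shaped like
MaxQuant's ``deamidation 18O (N)Sites.txt`` (one row per marked asparagine)
and ``peptides.txt`` (one row per peptide, linked from the site table via
the ``Peptide IDs`` column).  File names encode condition and fraction:
``T13`` is fraction 13 of the treated sample, ``C1`` fraction 1 of the
control.  Headers are matched case-insensitively through an alias map, so
minor dialect differences between export versions are tolerated.
Semicolon-delimited multi-value cells (accessions, gene names, peptide
IDs) are preserved as lists.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GlycositeRecord",
    "PeptideRecord",
    "RunLabel",
    "RunLabelError",
    "TableFormatError",
    "parse_run_label",
    "read_site_table",
    "read_peptide_table",
    "explode_multi_peptide_rows",
    "write_results",
    "read_results",
]


class RunLabelError(ValueError):
    """A file label did not encode a condition letter plus fraction number."""


class TableFormatError(ValueError):
    """An input table is missing columns or contains malformed cells."""


_CONDITION_CODES = {"C": "control", "T": "treated"}


@dataclass(frozen=True)
class RunLabel:
    """Condition + fraction number parsed from a file name."""

    condition: str  # "control" | "treated"
    fraction: int

    def __post_init__(self) -> None:
        if self.condition not in ("control", "treated"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.fraction < 1:
            raise ValueError(f"fraction number must be >= 1, got {self.fraction}")


_LABEL_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def parse_run_label(name: str, n_fractions: Optional[int] = None) -> RunLabel:
    """Parse ``"T13"`` (or ``"C1.sites.tsv"``, a path, ...) into a RunLabel.

    The leading non-numeric token maps C -> control, T -> treated
    (case-insensitive); the trailing digits are the fraction number.
    """
    stem = Path(name).name.split(".")[0]
    m = _LABEL_RE.match(stem)
    if not m:
        raise RunLabelError(
            f"file label {name!r}: expected <condition letter><fraction number>, e.g. 'T13'"
        )
    prefix, digits = m.group(1).upper(), m.group(2)
    if prefix not in _CONDITION_CODES:
        raise RunLabelError(
            f"file label {name!r}: unknown condition prefix {m.group(1)!r} "
            f"(expected one of {sorted(_CONDITION_CODES)})"
        )
    fraction = int(digits)
    if fraction < 1 or (n_fractions is not None and fraction > n_fractions):
        raise RunLabelError(
            f"file label {name!r}: fraction {fraction} outside 1..{n_fractions}"
        )
    return RunLabel(condition=_CONDITION_CODES[prefix], fraction=fraction)


@dataclass(frozen=True)
class GlycositeRecord:
    """One row of a marked-asparagine site table."""

    accessions: tuple[str, ...]
    position: int
    localization_probability: float
    peptide_ids: tuple[int, ...]
    protein_names: str = ""
    gene_names: tuple[str, ...] = ()
    is_reverse: bool = False
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("site record needs at least one protein accession")
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValueError(
                f"localization probability {self.localization_probability} outside [0, 1]"
            )

    @property
    def accession(self) -> str:
        """Leading (razor) accession, used for known-glycosite matching."""
        return self.accessions[0]

    @property
    def site_key(self) -> tuple[str, int]:
        return (self.accession, self.position)


@dataclass(frozen=True)
class PeptideRecord:
    peptide_id: int
    sequence: str
    protein_names: str = ""
    gene_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide record with empty sequence")


# canonical field -> accepted (lower-cased) header spellings
SITE_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "accessions": ("proteins", "protein", "leading proteins", "accession", "accessions"),
    "protein_names": ("protein names",),
    "gene_names": ("gene names",),
    "position": ("position", "positions within proteins"),
    "localization_probability": (
        "localization prob",
        "localization prob.",
        "localization probability",
    ),
    "peptide_ids": ("peptide ids",),
    "reverse": ("reverse",),
    "contaminant": ("potential contaminant", "contaminant"),
}
_SITE_REQUIRED = ("accessions", "position", "localization_probability", "peptide_ids")

PEPTIDE_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "peptide_id": ("id", "peptide id"),
    "sequence": ("sequence",),
    "protein_names": ("protein names",),
    "gene_names": ("gene names",),
}
_PEPTIDE_REQUIRED = ("peptide_id", "sequence")


def _resolve_columns(
    df: pd.DataFrame,
    aliases: Mapping[str, tuple[str, ...]],
    required: tuple[str, ...],
    path,
) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in df.columns}
    resolved = {}
    for canonical, spellings in aliases.items():
        for s in spellings:
            if s in lower:
                resolved[canonical] = lower[s]
                break
    missing = [c for c in required if c not in resolved]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {missing} "
            f"(accepted spellings: {[aliases[c] for c in missing]})"
        )
    return resolved


def _split_multi(cell: str) -> tuple[str, ...]:
    return tuple(p.strip() for p in str(cell).split(";") if p.strip())


def _flag(cell: str) -> bool:
    return str(cell).strip() not in ("", "nan", "False", "false", "0")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_site_table(path, aliases: Optional[Mapping[str, tuple[str, ...]]] = None) -> list[GlycositeRecord]:
    """Read one per-fraction site table into typed records."""
    df = _read_tsv(path)
    cols = _resolve_columns(df, aliases or SITE_COLUMN_ALIASES, _SITE_REQUIRED, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 2 = first data line
        row = dict(zip(df.columns, row))
        try:
            records.append(
                GlycositeRecord(
                    accessions=_split_multi(row[cols["accessions"]]),
                    position=int(row[cols["position"]]),
                    localization_probability=float(row[cols["localization_probability"]]),
                    peptide_ids=tuple(int(x) for x in _split_multi(row[cols["peptide_ids"]])),
                    protein_names=row.get(cols.get("protein_names", ""), "") or "",
                    gene_names=_split_multi(row.get(cols.get("gene_names", ""), "")),
                    is_reverse="reverse" in cols and _flag(row[cols["reverse"]]),
                    is_contaminant="contaminant" in cols and _flag(row[cols["contaminant"]]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path} line {i}: {exc}") from exc
    return records


def read_peptide_table(path, aliases: Optional[Mapping[str, tuple[str, ...]]] = None) -> list[PeptideRecord]:
    """Read one per-fraction peptide table into typed records."""
    df = _read_tsv(path)
    cols = _resolve_columns(df, aliases or PEPTIDE_COLUMN_ALIASES, _PEPTIDE_REQUIRED, path)
    records = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            rec = PeptideRecord(
                peptide_id=int(row[cols["peptide_id"]]),
                sequence=str(row[cols["sequence"]]).strip(),
                protein_names=row.get(cols.get("protein_names", ""), "") or "",
                gene_names=_split_multi(row.get(cols.get("gene_names", ""), "")),
            )
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path} line {i}: {exc}") from exc
        if rec.peptide_id in seen:
            raise TableFormatError(f"{path} line {i}: duplicate peptide id {rec.peptide_id}")
        seen.add(rec.peptide_id)
        records.append(rec)
    return records


def explode_multi_peptide_rows(
    records: Iterable[GlycositeRecord],
    peptides: "Iterable[PeptideRecord] | Mapping[int, PeptideRecord]",
) -> list[tuple[GlycositeRecord, str]]:
    """Resolve peptide-ID links: one output row per (site record, sequence).

    Rows listing several peptide IDs are split into one row per sequence,
    all site fields duplicated.  Links to peptide IDs absent from the
    peptide table are skipped with a warning (real exports contain
    peptides filtered out downstream of the site table).
    """
    if not isinstance(peptides, Mapping):
        peptides = {p.peptide_id: p for p in peptides}
    out = []
    for record in records:
        for pid in record.peptide_ids:
            pep = peptides.get(pid)
            if pep is None:
                logger.warning(
                    "site %s/%d links to unknown peptide id %d; skipping",
                    record.accession, record.position, pid,
                )
                continue
            out.append((record, pep.sequence))
    return out


# ---------------------------------------------------------------------------
# result table output

_RESULT_COLUMNS = [
    "sequence",
    "gene_names",
    "protein_names",
    "positions",
    "control_fractions",
    "treated_fractions",
    "delta_first",
    "delta_last",
    "differential",
    "direction_first",
    "direction_last",
    "known_glycosite",
    "gocc_ids",
    "plasma_membrane",
]

_NA = "NA"


def _join(values) -> str:
    return ";".join(str(v) for v in values)


def _cell(value) -> str:
    if value is None:
        return _NA
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, tuple):
        return _join(value)
    return str(value)


def write_results(results, path, format: str = "csv") -> None:
    """Write annotated per-peptide results; NA statuses as literal ``"NA"``.

    List-valued cells are semicolon-joined (the input tables' dialect).
    An empty result set yields a header-only file.
    """
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown output format {format!r}; expected 'csv' or 'tsv'")
    sep = "," if format == "csv" else "\t"
    rows = []
    for r in results:
        sh = r.shift
        rows.append(
            {
                "sequence": r.sequence,
                "gene_names": _join(r.gene_names),
                "protein_names": r.protein_names,
                "positions": _join(r.positions),
                "control_fractions": _cell(r.fractions_control),
                "treated_fractions": _cell(r.fractions_treated),
                "delta_first": _cell(sh.delta_first),
                "delta_last": _cell(sh.delta_last),
                "differential": _cell(sh.differential),
                "direction_first": _cell(sh.direction_first),
                "direction_last": _cell(sh.direction_last),
                "known_glycosite": _cell(r.known_glycosite),
                "gocc_ids": _join(r.gocc_ids),
                "plasma_membrane": _cell(r.plasma_membrane),
            }
        )
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, sep=sep, index=False)


def _parse_optional_int(cell: str):
    return None if cell == _NA else int(cell)


def _parse_optional_fracs(cell: str):
    if cell == _NA:
        return None
    return tuple(int(x) for x in cell.split(";") if x != "")


def _parse_tristate(cell: str):
    if cell == _NA:
        return None
    return cell == "True"


def read_results(path, format: str = "csv"):
    """Read a result table back into :class:`AnnotatedResult` rows (exact
    inverse of :func:`write_results`, including NA coding)."""
    from .shifts import AnnotatedResult, ShiftResult  # deferred: avoids import cycle

    sep = "," if format == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing result column(s) {missing}")
    out = []
    for row in df.to_dict("records"):
        fc = _parse_optional_fracs(row["control_fractions"])
        ft = _parse_optional_fracs(row["treated_fractions"])
        shift = ShiftResult(
            sequence=row["sequence"],
            min_control=min(fc) if fc else None,
            max_control=max(fc) if fc else None,
            min_treated=min(ft) if ft else None,
            max_treated=max(ft) if ft else None,
            delta_first=_parse_optional_int(row["delta_first"]),
            delta_last=_parse_optional_int(row["delta_last"]),
            differential=_parse_tristate(row["differential"]),
            direction_first=None if row["direction_first"] == _NA else row["direction_first"],
            direction_last=None if row["direction_last"] == _NA else row["direction_last"],
        )
        out.append(
            AnnotatedResult(
                sequence=row["sequence"],
                gene_names=_split_multi(row["gene_names"]),
                protein_names=row["protein_names"],
                positions=tuple(int(x) for x in row["positions"].split(";") if x != ""),
                fractions_control=fc,
                fractions_treated=ft,
                shift=shift,
                known_glycosite=row["known_glycosite"] == "True",
                gocc_ids=_split_multi(row["gocc_ids"]),
                plasma_membrane=row["plasma_membrane"] == "True",
            )
        )
    return out
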