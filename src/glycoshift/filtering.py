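"""Quality filtering of site identifications and known-glycosite matching.

Sites are kept only when they are not decoy (reverse-database) matches,
not common contaminants, and carry a localization probability strictly
greater than 0.75 — i.e. the search engine is confident about *which*
asparagine carries the ¹⁸O deamidation marker.  Kept sites can then be
flagged against a catalogue of experimentally observed N-glycosites
(an N-GlycositeAtlas-style table of accession + 1-based position).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .io_tables import GlycositeRecord, TableFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "filter_sites",
    "load_atlas",
    "match_known_glycosites",
]


@dataclass(frozen=True)
class FilterConfig:
    """Site-level quality filter; the probability cut is strictly >."""

    min_localization_probability: float = 0.75
    drop_reverse: bool = True
    drop_contaminants: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_localization_probability <= 1.0:
            raise ValueError("localization-probability threshold must lie in [0, 1]")


def filter_sites(
    records: Iterable[GlycositeRecord],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[GlycositeRecord], list[tuple[GlycositeRecord, str]]]:
    """Split records into (kept, dropped-with-reason).

    A record is kept iff it passes every enabled rule; dropped records are
    labelled with the first failing rule among ``reverse``,
    ``contaminant``, ``localization``.  The filter is idempotent.
    """
    kept, dropped = [], []
    for r in records:
        if cfg.drop_reverse and r.is_reverse:
            dropped.append((r, "reverse"))
        elif cfg.drop_contaminants and r.is_contaminant:
            dropped.append((r, "contaminant"))
        elif not r.localization_probability > cfg.min_localization_probability:
            dropped.append((r, "localization"))
        else:
            kept.append(r)
    return kept, dropped


ATLAS_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "accession": (
        "accession",
        "uniprot accession",
        "protein accession",
        "protein",
        "uniprotkb",
        "uniprot",
    ),
    "position": ("position", "site", "site position", "n position", "position within protein"),
}


def load_atlas(path, aliases: Optional[Mapping[str, tuple[str, ...]]] = None) -> set[tuple[str, int]]:
    """Load a known-glycosite table into a set of (accession, position).

    Rows whose position does not parse as a positive integer are skipped
    with a warning rather than aborting the run.
    """
    aliases = aliases or ATLAS_COLUMN_ALIASES
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lower = {c.lower().strip(): c for c in df.columns}
    cols = {}
    for canonical, spellings in aliases.items():
        for s in spellings:
            if s in lower:
                cols[canonical] = lower[s]
                break
    missing = [c for c in aliases if c not in cols]
    if missing:
        raise TableFormatError(f"{path}: missing atlas column(s) {missing}")
    atlas: set[tuple[str, int]] = set()
    for i, row in enumerate(df.to_dict("records"), start=2):
        acc = str(row[cols["accession"]]).strip()
        try:
            pos = int(str(row[cols["position"]]).strip())
            if not acc or pos < 1:
                raise ValueError
        except ValueError:
            logger.warning("%s line %d: malformed atlas row %r; skipping", path, i, row)
            continue
        atlas.add((acc, pos))
    return atlas


_ISOFORM_SUFFIX = re.compile(r"-\d+$")


def _base_accession(acc: str) -> str:
    return _ISOFORM_SUFFIX.sub("", acc)


def match_known_glycosites(
    site_keys: Iterable[tuple[str, int]],
    atlas: set[tuple[str, int]],
    base_accession_fallback: bool = False,
) -> list[bool]:
    """Flag each (accession, position) site as known iff present in the atlas.

    Matching is exact by default.  With ``base_accession_fallback`` an
    isoform accession ("P01234-2") additionally matches an atlas entry for
    its base accession ("P01234"), since catalogues often list canonical
    sequences only.
    """
    base_atlas = {( _base_accession(a), p) for a, p in atlas} if base_accession_fallback else None
    flags = []
    for acc, pos in site_keys:
        known = (acc, pos) in atlas
        if not known and base_atlas is not None:
            known = (_base_accession(acc), pos) in base_atlas
        flags.append(known)
    return flags
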