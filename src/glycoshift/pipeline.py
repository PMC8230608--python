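"""End-to-end orchestration: read -> filter -> explode -> profiles ->
shifts -> annotation -> summary -> output files.

Every stage logs its record counts at INFO so a run leaves the same audit
trail a summary table would: sites read, sites kept, unique peptides,
peptides in both conditions, differential peptides, plasma-membrane
differential peptides.  Any stage failure aborts with the stage name and
cause, and partial output files are removed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .filtering import FilterConfig, filter_sites, load_atlas, match_known_glycosites
from .go import PLASMA_MEMBRANE, annotate_and_flag, load_gene_annotation, load_obo
from .io_tables import (
    GlycositeRecord,
    PeptideRecord,
    RunLabel,
    explode_multi_peptide_rows,
    parse_run_label,
    read_peptide_table,
    read_site_table,
    write_results,
)
from .shifts import (
    DEFAULT_MIN_SHIFT,
    AnnotatedResult,
    SummaryCounts,
    build_profiles,
    compute_shift,
    summarize,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "PipelineStageError", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """The pipeline configuration is inconsistent or references missing files."""


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    control_dir: Path
    treated_dir: Path
    out_dir: Optional[Path] = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_shift: int = DEFAULT_MIN_SHIFT
    atlas_path: Optional[Path] = None
    atlas_base_accession_fallback: bool = False
    obo_path: Optional[Path] = None
    annotation_path: Optional[Path] = None
    go_root: str = PLASMA_MEMBRANE
    n_fractions: int = 20
    output_format: str = "csv"

    def __post_init__(self) -> None:
        self.control_dir = Path(self.control_dir)
        self.treated_dir = Path(self.treated_dir)
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)
        if not (isinstance(self.min_shift, int) and self.min_shift >= 1):
            raise ConfigError(f"min_shift must be an integer >= 1, got {self.min_shift!r}")

    def validate(self) -> None:
        for name, d in (("control", self.control_dir), ("treated", self.treated_dir)):
            if not d.is_dir():
                raise ConfigError(f"{name} directory {d} does not exist")
        if (self.obo_path is None) != (self.annotation_path is None):
            raise ConfigError(
                "GO filtering needs both an OBO file and a gene annotation table "
                "(got only one of --obo / --gocc-annot)"
            )
        for p in (self.atlas_path, self.obo_path, self.annotation_path):
            if p is not None and not Path(p).is_file():
                raise ConfigError(f"input file {p} does not exist")
        if self.output_format not in ("csv", "tsv"):
            raise ConfigError(f"unknown output format {self.output_format!r}")


@dataclass
class PipelineResult:
    results: list[AnnotatedResult]
    summary: SummaryCounts
    dropped: dict[str, int]
    output_paths: dict[str, Path] = field(default_factory=dict)


def _discover_runs(directory: Path, condition: str, n_fractions: int):
    runs = []
    for sites_path in sorted(directory.glob("*.sites.tsv")):
        label = parse_run_label(sites_path.name, n_fractions=n_fractions)
        if label.condition != condition:
            raise ConfigError(
                f"{sites_path} is labelled {label.condition!r} but sits in the "
                f"{condition} directory"
            )
        peptides_path = sites_path.with_name(sites_path.name.replace(".sites.tsv", ".peptides.tsv"))
        if not peptides_path.is_file():
            raise ConfigError(f"{sites_path} has no matching peptide table {peptides_path.name}")
        runs.append((label, sites_path, peptides_path))
    return runs


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full differential-profiling pipeline.

    Returns the annotated per-peptide results and summary counts; when
    ``cfg.out_dir`` is set, also writes ``results.<fmt>``, ``summary.json``
    and ``histograms.csv`` there.
    """
    # -- config ---------------------------------------------------------
    try:
        cfg.validate()
    except ConfigError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError("config", exc) from exc

    stage = "read"
    try:
        runs = _discover_runs(cfg.control_dir, "control", cfg.n_fractions)
        runs += _discover_runs(cfg.treated_dir, "treated", cfg.n_fractions)
        loaded: list[tuple[RunLabel, list[GlycositeRecord], dict[int, PeptideRecord]]] = []
        n_sites_read = 0
        for label, sites_path, peptides_path in runs:
            records = read_site_table(sites_path)
            peptides = {p.peptide_id: p for p in read_peptide_table(peptides_path)}
            loaded.append((label, records, peptides))
            n_sites_read += len(records)
        logger.info("read %d site rows from %d fraction files", n_sites_read, len(runs))

        stage = "filter"
        dropped_counts: dict[str, int] = {"reverse": 0, "contaminant": 0, "localization": 0}
        filtered: list[tuple[RunLabel, list[GlycositeRecord], dict[int, PeptideRecord]]] = []
        for label, records, peptides in loaded:
            kept, dropped = filter_sites(records, cfg.filter)
            for _r, reason in dropped:
                dropped_counts[reason] = dropped_counts.get(reason, 0) + 1
            filtered.append((label, kept, peptides))
        n_kept = sum(len(k) for _l, k, _p in filtered)
        logger.info("filter kept %d site rows (dropped %s)", n_kept, dropped_counts)

        stage = "explode"
        rows = []
        site_keys: set[tuple[str, int]] = set()
        for label, kept, peptides in filtered:
            for record, sequence in explode_multi_peptide_rows(kept, peptides):
                rows.append((record, sequence, label))
            site_keys.update(r.site_key for r in kept)
        logger.info("%d exploded rows, %d unique sites", len(rows), len(site_keys))

        stage = "profiles"
        profiles = build_profiles(rows)
        logger.info("%d unique peptide sequences", len(profiles))

        stage = "shift"
        shifts = [compute_shift(p, min_shift=cfg.min_shift) for p in profiles]

        stage = "annotate"
        known_sites = 0
        if cfg.atlas_path is not None:
            atlas = load_atlas(cfg.atlas_path)
            known_sites = sum(
                match_known_glycosites(
                    sorted(site_keys), atlas, cfg.atlas_base_accession_fallback
                )
            )
            peptide_known = [
                any(
                    match_known_glycosites(p.site_keys, atlas, cfg.atlas_base_accession_fallback)
                )
                for p in profiles
            ]
        else:
            peptide_known = [False] * len(profiles)
        if cfg.obo_path is not None:
            dag = load_obo(cfg.obo_path)
            annotation, _term_names = load_gene_annotation(cfg.annotation_path)
            go_flags = annotate_and_flag(
                [p.gene_names for p in profiles], annotation, dag, root=cfg.go_root
            )
        else:
            go_flags = [((), False)] * len(profiles)

        results = [
            AnnotatedResult(
                sequence=p.sequence,
                gene_names=p.gene_names,
                protein_names=p.protein_names,
                positions=p.positions,
                fractions_control=p.fractions_control,
                fractions_treated=p.fractions_treated,
                shift=sh,
                known_glycosite=kn,
                gocc_ids=terms,
                plasma_membrane=pm,
            )
            for p, sh, kn, (terms, pm) in zip(profiles, shifts, peptide_known, go_flags)
        ]

        stage = "summarize"
        summary = summarize(
            results, total_sites=len(site_keys), known_sites=known_sites, min_shift=cfg.min_shift
        )
        logger.info(
            "sites=%d known=%d peptides=%d in_both=%d differential=%d differential_pm=%d",
            summary.total_sites, summary.known_sites, summary.total_peptides,
            summary.peptides_in_both, summary.differential,
            summary.differential_plasma_membrane,
        )
    except (PipelineStageError, ConfigError):
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    result = PipelineResult(results=results, summary=summary, dropped=dropped_counts)
    if cfg.out_dir is not None:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: PipelineConfig, result: PipelineResult) -> None:
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out / f"results.{cfg.output_format}",
        "summary": out / "summary.json",
        "histograms": out / "histograms.csv",
    }
    written = []
    try:
        write_results(result.results, paths["results"], format=cfg.output_format)
        written.append(paths["results"])
        summary_dict = dataclasses.asdict(result.summary)
        paths["summary"].write_text(json.dumps(summary_dict, indent=2, sort_keys=True) + "\n")
        written.append(paths["summary"])
        hist_rows = [
            {"statistic": stat, "delta": delta, "count": count}
            for stat, hist in (
                ("first", result.summary.histogram_first),
                ("last", result.summary.histogram_last),
            )
            for delta, count in hist.items()
        ]
        pd.DataFrame(hist_rows, columns=["statistic", "delta", "count"]).to_csv(
            paths["histograms"], index=False
        )
        written.append(paths["histograms"])
    except Exception as exc:
        for p in written:  # do not leave partial outputs behind
            try:
                p.unlink()
            except OSError:  # pragma: no cover
                pass
        raise PipelineStageError("write", exc) from exc
    result.output_paths = paths
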