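"""End-to-end run: simulate a two-condition experiment, then profile it.

Writes a ground-truthed synthetic fixture (per-fraction site/peptide
tables, known-glycosite catalogue, GO ontology + annotations), runs the
full differential-profiling pipeline on it and compares the result with
the injected truth.
"""

import tempfile
from pathlib import Path

from glycoshift import PipelineConfig, SimulationConfig, run_pipeline
from glycoshift.simulate import emit_fixture

with tempfile.TemporaryDirectory() as tmp:
    fixture = emit_fixture(SimulationConfig(seed=1), Path(tmp))
    truth_diff = {t.sequence for t in fixture.truth if t.expected_differential}
    print(f"Simulated {len(fixture.truth)} glycopeptides; "
          f"{len(truth_diff)} expected differential (no-dropout model)")

    result = run_pipeline(
        PipelineConfig(
            control_dir=fixture.control_dir,
            treated_dir=fixture.treated_dir,
            atlas_path=fixture.atlas_path,
            obo_path=fixture.obo_path,
            annotation_path=fixture.annotation_path,
            out_dir=Path(tmp) / "out",
        )
    )
    s = result.summary
    print("\nPipeline summary (counts, audit-trail order):")
    print(f"  identified sites              {s.total_sites}")
    print(f"  known glycosites              {s.known_sites}")
    print(f"  glycopeptides (all fractions) {s.total_peptides}")
    print(f"  glycopeptides in both         {s.peptides_in_both}")
    print(f"  differential glycopeptides    {s.differential}")
    print(f"  differential plasma membrane  {s.differential_plasma_membrane}")

    detected = {r.sequence for r in result.results if r.shift.differential}
    print(f"\nDetected {len(detected)} differential peptides; "
          f"{len(detected & truth_diff)} overlap the injected truth "
          f"(misses here reflect the simulated 10% detection dropout).")
    print(f"First-elution shifts: {s.upgraded_first} upgraded vs "
          f"{s.downgraded_first} downgraded — the mass-gain-biased effect "
          f"model moves peptides to earlier fractions.")
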