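import dataclasses

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

from glycoshift.io_tables import GlycositeRecord
from glycoshift.simulate import SimulationConfig, emit_fixture


def make_record(
    accession="P00001",
    position=10,
    prob=0.99,
    peptide_ids=(1,),
    gene_names=("GENE001",),
    reverse=False,
    contaminant=False,
):
    """Handmade site record with sensible defaults."""
    return GlycositeRecord(
        accessions=(accession,) if isinstance(accession, str) else tuple(accession),
        position=position,
        localization_probability=prob,
        peptide_ids=tuple(peptide_ids),
        protein_names=f"Protein {gene_names[0]}" if gene_names else "",
        gene_names=tuple(gene_names),
        is_reverse=reverse,
        is_contaminant=contaminant,
    )


@pytest.fixture(scope="session")
def recovery_fixture(tmp_path_factory):
    """No dropout, confident localization everywhere: the conditions under
    which the pipeline must recover the simulated truth exactly."""
    cfg = dataclasses.replace(
        SimulationConfig(seed=1), dropout_rate=0.0, low_localization_fraction=0.0
    )
    return cfg, emit_fixture(cfg, tmp_path_factory.mktemp("recovery"))


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """Study-condition defaults: dropout, decoys and a localization mixture."""
    cfg = SimulationConfig(seed=11)
    return cfg, emit_fixture(cfg, tmp_path_factory.mktemp("default"))
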