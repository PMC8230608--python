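"""Synthetic-fixture generator: sequons, glycans, determinism, truth."""

import hashlib
from pathlib import Path

import pytest

from glycoshift.filtering import filter_sites
from glycoshift.io_tables import read_site_table
from glycoshift.masses import GlycanComposition, glycopeptide_mass
from glycoshift.sec import fraction_for_mass
from glycoshift.simulate import (
    SimulationConfig,
    assign_glycans,
    build_truth,
    emit_fixture,
    find_sequons,
    generate_proteome,
    parse_effect,
)


class TestSequons:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("AANGTAA", [2]),       # N-G-T
            ("AANPTAA", []),        # X = P never glycosylated
            ("NASNGS", [0, 3]),
            ("GGGGGGG", []),
            ("NNSS", [0, 1]),       # overlapping sequons both count
        ],
    )
    def test_motif_detection(self, seq, expected):
        assert find_sequons(seq) == expected


class TestParseEffect:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("+2Hex", {"Hex": 2}),
            ("-1Neu5Ac", {"Neu5Ac": -1}),
            ("+1Hex+1HexNAc", {"Hex": 1, "HexNAc": 1}),
            ("-2Hex+1dHex", {"Hex": -2, "dHex": 1}),
        ],
    )
    def test_parse(self, text, expected):
        assert parse_effect(text) == expected

    @pytest.mark.parametrize("text", ["", "2Hex", "+2Pent", "+2Hex junk"])
    def test_rejects_malformed(self, text):
        with pytest.raises(ValueError):
            parse_effect(text)


class TestProteome:
    cfg = SimulationConfig(seed=5, n_proteins=10)

    def test_deterministic(self):
        assert generate_proteome(self.cfg) == generate_proteome(self.cfg)

    def test_peptides_are_tryptic_and_long_enough(self):
        for protein in generate_proteome(self.cfg):
            for _start, pep in protein.peptides:
                assert len(pep.sequence) >= 7
                assert pep.sequence[-1] in "KR"
                assert pep.sequence[0] != "P"

    def test_glycosites_sit_on_sequons(self):
        for protein in generate_proteome(self.cfg):
            for start, pep in protein.peptides:
                if pep.site_offset is None:
                    assert find_sequons(pep.sequence) == []
                else:
                    assert find_sequons(pep.sequence) == [pep.site_offset]
                    # 1-based protein coordinate points at the sequon N
                    assert protein.sequence[start + pep.site_offset] == "N"

    def test_sequences_unique_across_proteome(self):
        seqs = [
            pep.sequence
            for protein in generate_proteome(self.cfg)
            for _s, pep in protein.peptides
        ]
        assert len(seqs) == len(set(seqs))


class TestAssignGlycans:
    def test_zero_effect_fraction_leaves_conditions_identical(self):
        cfg = SimulationConfig(seed=2, n_proteins=10, targeted_fraction=0.0)
        truth = assign_glycans(cfg, generate_proteome(cfg))
        assert truth and all(t.control_composition == t.treated_composition for t in truth)

    def test_two_hex_effect_mass_delta(self):
        cfg = SimulationConfig(
            seed=2, n_proteins=10, targeted_fraction=1.0, effects=(("+2Hex", 1.0),)
        )
        truth = build_truth(cfg, assign_glycans(cfg, generate_proteome(cfg)))
        assert truth
        for t in truth:
            assert t.treated_mass - t.control_mass == pytest.approx(324.28, abs=0.01)

    def test_loss_effects_clip_at_zero(self):
        comp = GlycanComposition.from_string("Hex1HexNAc2")
        assert comp.add({"Hex": -3}, clip=True).n_hex == 0

    def test_lectin_capture_requires_hexose_core(self):
        # raise the capture requirement above the whole pool: nothing observable
        # (13 exceeds even Man9 plus the largest +3Hex gain)
        cfg = SimulationConfig(seed=3, n_proteins=10, conA_min_hex=13)
        truth = build_truth(cfg, assign_glycans(cfg, generate_proteome(cfg)))
        assert truth == []


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestEmitFixture:
    def test_byte_identical_for_same_seed(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_proteins=12)
        emit_fixture(cfg, tmp_path / "a")
        emit_fixture(cfg, tmp_path / "b")
        assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")

    def test_different_seeds_same_schema(self, tmp_path):
        fx1 = emit_fixture(SimulationConfig(seed=1, n_proteins=8), tmp_path / "s1")
        fx2 = emit_fixture(SimulationConfig(seed=2, n_proteins=8), tmp_path / "s2")
        assert _tree_digest(tmp_path / "s1") != _tree_digest(tmp_path / "s2")
        h1 = (fx1.control_dir / "C1.sites.tsv").read_text().splitlines()[0]
        h2 = (fx2.control_dir / "C1.sites.tsv").read_text().splitlines()[0]
        assert h1 == h2

    def test_all_fraction_file_pairs_written(self, default_fixture):
        cfg, fx = default_fixture
        n = cfg.calibration.n_fractions
        assert len(list(fx.control_dir.glob("*.sites.tsv"))) == n
        assert len(list(fx.control_dir.glob("*.peptides.tsv"))) == n
        assert len(list(fx.treated_dir.glob("*.sites.tsv"))) == n

    def test_decoy_rows_carry_flags_and_are_filtered(self, default_fixture):
        _cfg, fx = default_fixture
        flagged = 0
        for path in fx.control_dir.glob("*.sites.tsv"):
            records = read_site_table(path)
            kept, dropped = filter_sites(records)
            assert not any(r.is_reverse or r.is_contaminant for r in kept)
            flagged += sum(1 for r in records if r.is_reverse or r.is_contaminant)
        assert flagged > 0  # the default rates do inject decoys

    def test_truth_flags_recomputable_from_composition_and_calibration(self, default_fixture):
        cfg, fx = default_fixture
        lo, hi = cfg.mass_window
        for t in fx.truth:
            for comp, observed, fractions in (
                (t.control_composition, t.observed_control, t.fractions_control),
                (t.treated_composition, t.observed_treated, t.fractions_treated),
            ):
                mass = glycopeptide_mass(t.sequence, comp, "average")
                expect_obs = comp.n_hex >= cfg.conA_min_hex and lo <= mass <= hi
                assert observed == expect_obs
                if observed:
                    assert min(fractions) == fraction_for_mass(mass, cfg.calibration)
            if t.observed_control and t.observed_treated:
                d1 = min(t.fractions_control) - min(t.fractions_treated)
                dn = max(t.fractions_control) - max(t.fractions_treated)
                assert t.expected_differential == (
                    abs(d1) >= cfg.min_shift or abs(dn) >= cfg.min_shift
                )
            else:
                assert t.expected_differential is None

    def test_mass_gain_bias_yields_more_upgraded(self, default_fixture):
        # the default effect pool gains mass more often than it loses:
        # treated glycopeptides should move to earlier fractions more often
        _cfg, fx = default_fixture
        up = sum(
            1 for t in fx.truth if t.expected_differential and t.expected_delta_first > 0
        )
        down = sum(
            1 for t in fx.truth if t.expected_differential and t.expected_delta_first < 0
        )
        assert up >= down

    def test_config_round_trips_through_dict(self):
        cfg = SimulationConfig(seed=4, effects=(("+1Hex", 1.0),))
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg
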