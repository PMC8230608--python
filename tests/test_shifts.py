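"""Elution-shift computation, classification rule and summaries."""

import random

import pytest
from hypothesis import given, strategies as st

from glycoshift.io_tables import RunLabel
from glycoshift.shifts import (
    AnnotatedResult,
    PeptideFractionProfile,
    build_profiles,
    compute_shift,
    summarize,
)

from conftest import make_record


def profile(sequence="ANGTSEK", control=None, treated=None):
    return PeptideFractionProfile(
        sequence=sequence,
        fractions_control=tuple(sorted(control)) if control else None,
        fractions_treated=tuple(sorted(treated)) if treated else None,
    )


class TestComputeShift:
    def test_upgraded_at_threshold(self):
        sh = compute_shift(profile(control={13}, treated={11}))
        assert (sh.delta_first, sh.differential, sh.direction_first) == (2, True, "upgraded")

    def test_one_fraction_shift_not_differential(self):
        sh = compute_shift(profile(control={5, 6}, treated={5, 7}))
        assert (sh.delta_first, sh.delta_last, sh.differential) == (0, -1, False)
        assert sh.direction_last == "downgraded"

    def test_single_condition_is_na(self):
        sh = compute_shift(profile(control={8}, treated=None))
        assert sh.differential is None
        assert sh.delta_first is None and sh.direction_first is None
        assert sh.min_control == 8

    def test_opposite_directions_counted_per_statistic(self):
        sh = compute_shift(profile(control={5, 10}, treated={8, 7}))
        assert sh.direction_first == "downgraded" and sh.direction_last == "upgraded"
        assert sh.differential is True

    frac_sets = st.sets(st.integers(1, 20), min_size=1, max_size=6)

    @given(control=frac_sets, treated=frac_sets)
    def test_label_swap_symmetry(self, control, treated):
        fwd = compute_shift(profile(control=control, treated=treated))
        rev = compute_shift(profile(control=treated, treated=control))
        assert rev.delta_first == -fwd.delta_first
        assert rev.delta_last == -fwd.delta_last
        assert rev.differential == fwd.differential
        swap = {"upgraded": "downgraded", "downgraded": "upgraded", "none": "none"}
        assert rev.direction_first == swap[fwd.direction_first]
        assert rev.direction_last == swap[fwd.direction_last]


class TestBuildProfiles:
    def _row(self, seq, condition, fraction, **kw):
        return (make_record(**kw), seq, RunLabel(condition=condition, fraction=fraction))

    def test_fractions_are_unioned_and_sorted(self):
        rows = [self._row("ANGTSEK", "treated", 13), self._row("ANGTSEK", "treated", 11)]
        (p,) = build_profiles(rows)
        assert p.fractions_treated == (11, 13)
        assert p.fractions_control is None

    def test_duplicate_detection_collapses(self):
        rows = [self._row("ANGTSEK", "control", 5)] * 3
        (p,) = build_profiles(rows)
        assert p.fractions_control == (5,)

    def test_two_sites_one_sequence_single_profile(self):
        rows = [
            self._row("ANGTSNRTK", "control", 5, position=10),
            self._row("ANGTSNRTK", "control", 5, position=15),
        ]
        (p,) = build_profiles(rows)
        assert p.positions == (10, 15)

    def test_row_order_irrelevant(self):
        rows = [
            self._row("ANGTSEK", "control", 5),
            self._row("ANGTSEK", "treated", 9),
            self._row("LLNWSIR", "treated", 2),
            self._row("LLNWSIR", "control", 2),
            self._row("TTNASHK", "control", 11),
        ]
        reference = build_profiles(rows)
        rng = random.Random(0)
        for _ in range(10):
            shuffled = rows[:]
            rng.shuffle(shuffled)
            assert build_profiles(shuffled) == reference

    def test_extra_detection_in_known_fraction_is_inert(self):
        rows = [self._row("ANGTSEK", "control", 5), self._row("ANGTSEK", "treated", 9)]
        base = compute_shift(build_profiles(rows)[0])
        extra = compute_shift(build_profiles(rows + [rows[0]])[0])
        assert extra == base


def naive_classification(raw_rows, min_shift=2):
    """Brute-force oracle: scan all rows per sequence, apply the rule."""
    out = {}
    for seq in {s for s, _c, _f in raw_rows}:
        cf = sorted({f for s, c, f in raw_rows if s == seq and c == "control"})
        tf = sorted({f for s, c, f in raw_rows if s == seq and c == "treated"})
        if not cf or not tf:
            out[seq] = None
        else:
            out[seq] = (
                abs(min(cf) - min(tf)) > min_shift - 1 or abs(max(cf) - max(tf)) > min_shift - 1
            )
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_fixture_matches_naive_scan(self, seed):
        rng = random.Random(seed)
        n_peptides = rng.randint(50, 200)
        raw = []
        for i in range(n_peptides):
            seq = f"PEP{i:04d}"  # identity key only; content irrelevant here
            for condition in ("control", "treated"):
                if rng.random() < 0.15:
                    continue  # absent in this condition
                for f in rng.sample(range(1, 21), rng.randint(1, 4)):
                    raw.append((seq, condition, f))
        expected = naive_classification(raw)
        rows = [
            (make_record(), seq, RunLabel(condition=c, fraction=f)) for seq, c, f in raw
        ]
        got = {p.sequence: compute_shift(p).differential for p in build_profiles(rows)}
        assert got == expected


def annotated(seq, control, treated, pm=False):
    p = profile(seq, control, treated)
    return AnnotatedResult(
        sequence=seq,
        gene_names=(),
        protein_names="",
        positions=(),
        fractions_control=p.fractions_control,
        fractions_treated=p.fractions_treated,
        shift=compute_shift(p),
        plasma_membrane=pm,
    )


class TestSummarize:
    def test_empty_input_all_zero(self):
        s = summarize([])
        assert (s.total_peptides, s.peptides_in_both, s.differential) == (0, 0, 0)
        assert s.histogram_first == {}

    def test_hand_enumerated_fixture(self):
        results = [
            annotated("A" * 7, {10}, {7}, pm=True),   # diff, upgraded (+3)
            annotated("B" * 7, {4}, {6}),             # diff, downgraded (-2)
            annotated("C" * 7, {5}, {5}),             # not differential
            annotated("D" * 7, {5}, None),            # NA
        ]
        s = summarize(results, total_sites=4, known_sites=2)
        assert s.total_peptides == 4
        assert s.peptides_in_both == 3
        assert s.differential == 2
        assert s.differential_plasma_membrane == 1
        assert (s.upgraded_first, s.downgraded_first) == (1, 1)
        assert s.histogram_first == {-2: 1, 0: 1, 3: 1}

    def test_all_small_shifts_give_zero_differential(self):
        results = [annotated(f"P{i}XXXXXX", {5}, {5 + (i % 2)}) for i in range(10)]
        assert summarize(results).differential == 0

    def test_count_ordering_enforced(self):
        s = summarize([annotated("A" * 7, {10}, {1}, pm=True)])
        s.differential_plasma_membrane = 5  # corrupt
        with pytest.raises(AssertionError):
            s.check()
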