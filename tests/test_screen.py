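"""Differential-position screen, region filter and cross-species profiler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pufascreen.screen import (
    STATUS_CANDIDATE,
    STATUS_EXCLUDED_DISTAL,
    STATUS_EXCLUDED_PORE,
    STATUS_OUTSIDE_WINDOW,
    CLASS_FULL,
    CLASS_NOT,
    CLASS_PARTIAL,
    CandidatePosition,
    ConservationThresholds,
    apply_region_filter,
    cross_species_conservation,
    find_differential_positions,
)

from conftest import make_alignment, random_alignment
from oracles import brute_force_differential_columns, brute_force_group_conservation

SENS = ["TRPL", "TRPgamma"]


def positions(alignment):
    return [
        c.reference_position
        for c in find_differential_positions(alignment, SENS, "TRP")
    ]


def test_toy_alignment_yields_positions_4_and_8(toy_alignment):
    assert positions(toy_alignment) == [4, 8]


def test_identical_sequences_yield_no_candidates():
    aln = make_alignment(
        {"a|TRPL": "ACDEF", "a|TRPgamma": "ACDEF", "a|TRP": "ACDEF"}, "a|TRPL"
    )
    assert positions(aln) == []


def test_sensitive_group_disagreement_excludes_column():
    # TRPL and TRPgamma disagree at column 0 although TRP differs from both
    aln = make_alignment(
        {"a|TRPL": "A", "a|TRPgamma": "C", "a|TRP": "D"}, "a|TRPL"
    )
    assert positions(aln) == []


def test_gap_in_insensitive_counts_as_different():
    aln = make_alignment(
        {"a|TRPL": "A", "a|TRPgamma": "A", "a|TRP": "-"}, "a|TRPL"
    )
    assert positions(aln) == [1]


def test_gap_in_sensitive_group_disqualifies_column():
    aln = make_alignment(
        {"a|TRPL": "A", "a|TRPgamma": "-", "a|TRP": "C"}, "a|TRPL"
    )
    assert positions(aln) == []


def test_reference_gap_column_gets_no_position():
    # column 1 is differential but gapped in the reference: unnumbered, skipped
    aln = make_alignment(
        {"a|TRPL": "A-C", "a|TRPgamma": "AAC", "a|TRP": "CCA"}, "a|TRPL"
    )
    # rule (i) fails at column 1 (gap in a sensitive seq), columns 0 and 2 hit
    assert positions(aln) == [1, 2]


def test_missing_group_label_raises(toy_alignment):
    with pytest.raises(ValueError, match="absent"):
        find_differential_positions(toy_alignment, SENS, "TRPC6")


def test_reference_must_be_in_sensitive_group(toy_alignment):
    with pytest.raises(ValueError, match="sensitive"):
        find_differential_positions(toy_alignment, ["TRPgamma"], "TRP")


def test_screen_equals_brute_force_on_random_alignments():
    """Exhaustive per-column oracle equivalence on 1000 random small alignments."""
    rng = np.random.default_rng(2024)
    for trial in range(1000):
        n_cols = int(rng.integers(1, 21))
        aln, sequences, sens_ids, insens_ids = random_alignment(rng, n_cols)
        refmap_cols = brute_force_differential_columns(sequences, sens_ids, insens_ids)
        # oracle works in columns; convert to reference positions by counting
        ref = sequences["sp1|TRPL"]
        expected = []
        pos = 0
        for col, char in enumerate(ref):
            if char != "-":
                pos += 1
                if col in refmap_cols:
                    expected.append(pos)
        assert positions(aln) == expected, f"trial {trial}"


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_adding_sensitive_sequence_only_shrinks_candidate_set(seed):
    rng = np.random.default_rng(seed)
    aln, sequences, _, _ = random_alignment(rng, 15)
    base = set(positions(aln))
    extra = dict(sequences)
    extra["sp4|TRPL"] = "".join(
        rng.choice(list("ACDE-"), size=aln.n_columns)
    )
    grown = make_alignment(extra, "sp1|TRPL")
    assert set(positions(grown)) <= base


def _candidates(*refpos):
    return [
        CandidatePosition(reference_position=p, column_index=p - 1, residues={})
        for p in refpos
    ]


def test_region_filter_statuses(topology):
    # pore-proximal 631, distal 833, outside-window 200, retained S3 465
    filtered = apply_region_filter(_candidates(631, 833, 200, 465), topology)
    by_pos = {c.reference_position: c for c in filtered}
    assert by_pos[631].status == STATUS_EXCLUDED_PORE
    assert by_pos[833].status == STATUS_EXCLUDED_DISTAL
    assert by_pos[200].status == STATUS_OUTSIDE_WINDOW
    assert by_pos[465].status == STATUS_CANDIDATE
    assert by_pos[465].region == "S3"


def test_region_filter_is_a_partition(topology):
    rng = np.random.default_rng(5)
    pos = rng.choice(np.arange(1, 1125), size=80, replace=False)
    filtered = apply_region_filter(_candidates(*pos), topology)
    statuses = [c.status for c in filtered]
    assert len(filtered) == 80
    assert sum(
        statuses.count(s)
        for s in (
            STATUS_CANDIDATE,
            STATUS_EXCLUDED_PORE,
            STATUS_EXCLUDED_DISTAL,
            STATUS_OUTSIDE_WINDOW,
        )
    ) == 80


def test_region_filter_rejects_window_outside_span(topology):
    with pytest.raises(ValueError, match="window"):
        apply_region_filter(_candidates(465), topology, window=(0, 2000))


def _ten_species_alignment(sens_letters, insens_letters):
    sequences = {}
    for i in range(10):
        sequences[f"s{i:02d}|TRPL"] = sens_letters[i]
        sequences[f"s{i:02d}|TRPgamma"] = sens_letters[10 + i]
        sequences[f"s{i:02d}|TRP"] = insens_letters[i]
    return make_alignment(sequences, "s00|TRPL")


def test_fully_conserved_both_groups():
    aln = _ten_species_alignment(["I"] * 20, ["V"] * 10)
    (prof,) = cross_species_conservation(aln, [1], SENS, "TRP")
    assert prof.sensitive_fraction == 1.0
    assert prof.insensitive_fraction == 1.0
    assert prof.conservation_class == CLASS_FULL


def test_partial_conservation_fraction_is_arithmetic():
    aln = _ten_species_alignment(["I"] * 19 + ["L"], ["V"] * 10)
    (prof,) = cross_species_conservation(aln, [1], SENS, "TRP")
    assert prof.sensitive_fraction == pytest.approx(0.95)
    assert prof.conservation_class == CLASS_PARTIAL


def test_low_conservation_classified_not_conserved():
    aln = _ten_species_alignment(list("ACDEACDEACDEACDEACDE"), ["V"] * 10)
    (prof,) = cross_species_conservation(aln, [1], SENS, "TRP")
    assert prof.conservation_class == CLASS_NOT


def test_unmapped_position_reported_not_fatal(toy_alignment):
    profiles = cross_species_conservation(toy_alignment, [4, 99], SENS, "TRP")
    assert profiles[0].conservation_class is not None
    assert profiles[1].error is not None
    assert profiles[1].conservation_class is None


@pytest.mark.parametrize("seed", range(5))
def test_conservation_fractions_match_brute_force_tally(seed):
    rng = np.random.default_rng(seed)
    aln, sequences, sens_ids, insens_ids = random_alignment(rng, 12, gap_rate=0.2)
    ref = sequences["sp1|TRPL"]
    n_positions = sum(c != "-" for c in ref)
    profiles = cross_species_conservation(
        aln, range(1, n_positions + 1), SENS, "TRP"
    )
    pos = 0
    for col, char in enumerate(ref):
        if char == "-":
            continue
        prof = profiles[pos]
        pos += 1
        cons, frac = brute_force_group_conservation(
            [sequences[i][col] for i in sens_ids]
        )
        assert prof.sensitive_consensus == cons
        assert prof.sensitive_fraction == pytest.approx(frac)
        cons_i, frac_i = brute_force_group_conservation(
            [sequences[i][col] for i in insens_ids]
        )
        assert prof.insensitive_consensus == cons_i
        assert prof.insensitive_fraction == pytest.approx(frac_i)
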