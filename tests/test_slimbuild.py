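"""Motif patterns, occurrence matching and candidate enumeration."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimq.seqdata import AMINO_ACIDS, MaskedSequence, no_mask
from slimq.slimbuild import (
    Motif,
    MotifError,
    MotifSpace,
    PatternInfo,
    enumerate_dataset_motifs,
    enumerate_query_motifs,
    extend_ambiguity,
    find_occurrences,
    motif_space_size,
    parse_pattern,
)
from slimq.upc import build_upcs

from conftest import make_record, random_sequence


def masked_from(seq, masked_positions=()):
    mask = tuple(i in set(masked_positions) for i in range(len(seq)))
    masked = "".join("X" if m else c for c, m in zip(seq, mask))
    return MaskedSequence("P1", seq, mask, masked)


class TestPatternLanguage:
    @pytest.mark.parametrize(
        "text", ["LIG", "Q.[IL].FF", "A..C", "^MA", "KR$", "[DE][ST]"]
    )
    def test_round_trip(self, text):
        assert parse_pattern(text).pattern == text

    def test_structure(self):
        motif = parse_pattern("Q.[IL].FF")
        assert motif.defined_length == 4
        assert motif.span == 6
        assert motif.gaps == (1, 1, 0)
        assert not motif.is_fixed
        assert motif.columns()[2] == frozenset("IL")

    @pytest.mark.parametrize("bad", ["", ".AB", "AB.", "A[]B", "A[B]C", "a1"])
    def test_malformed(self, bad):
        with pytest.raises(MotifError):
            parse_pattern(bad)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_random_round_trip(self, data):
        n_pos = data.draw(st.integers(2, 5))
        positions = tuple(
            frozenset(
                data.draw(
                    st.sets(st.sampled_from(AMINO_ACIDS), min_size=1, max_size=4)
                )
            )
            for _ in range(n_pos)
        )
        gaps = tuple(data.draw(st.integers(0, 3)) for _ in range(n_pos - 1))
        motif = Motif(positions, gaps)
        assert parse_pattern(motif.pattern) == motif


class TestMotifSpaceSize:
    def test_single_position(self):
        assert motif_space_size(1, 5) == 20

    def test_dimers_no_wildcards(self):
        assert motif_space_size(2, 0) == 400

    def test_invalid(self):
        with pytest.raises(MotifError):
            motif_space_size(0, 2)


class TestFindOccurrences:
    def test_degenerate_pattern(self):
        motif = parse_pattern("Q.[IL].FF")
        occs = find_occurrences(motif, masked_from("QAIAFF"))
        assert [(o.start, o.end, o.match) for o in occs] == [(1, 6, "QAIAFF")]

    def test_overlapping_matches(self):
        occs = find_occurrences(parse_pattern("AA"), masked_from("AAA"))
        assert [o.start for o in occs] == [1, 2]

    def test_fully_masked(self):
        seq = "QAIAFF"
        occs = find_occurrences(
            parse_pattern("Q.[IL].FF"), masked_from(seq, range(len(seq)))
        )
        assert occs == []

    def test_defined_position_never_on_mask(self):
        # mask the I at index 2: defined position cannot sit on X
        occs = find_occurrences(parse_pattern("Q.[IL].FF"),
                                masked_from("QAIAFF", [2]))
        assert occs == []
        # wildcard positions may cross X (index 1 masked)
        occs = find_occurrences(parse_pattern("Q.[IL].FF"),
                                masked_from("QAIAFF", [1]))
        assert [o.start for o in occs] == [1]

    def test_anchors(self):
        assert [o.start for o in
                find_occurrences(parse_pattern("^MA"), masked_from("MAMA"))] == [1]
        assert [o.start for o in
                find_occurrences(parse_pattern("MA$"), masked_from("MAMA"))] == [3]
        assert find_occurrences(parse_pattern("^AA"), masked_from("MAA")) == []


def brute_force_query_space(region, L, W):
    """Exhaustive oracle: choose index subsets, filter spacing, render."""
    unmasked = [i for i, c in enumerate(region) if c in AMINO_ACIDS]
    patterns = {length: set() for length in range(2, L + 1)}
    for length in range(2, L + 1):
        for combo in itertools.combinations(unmasked, length):
            if any(b - a > W + 1 for a, b in zip(combo, combo[1:])):
                continue
            text = region[combo[0]]
            for a, b in zip(combo, combo[1:]):
                text += "." * (b - a - 1) + region[b]
            patterns[length].add(text)
    return patterns


class TestEnumerateQueryMotifs:
    def test_homopolymer_collapses_duplicates(self):
        space = enumerate_query_motifs("AAAA", L=2, W=2)
        assert {m.pattern for m in space.patterns} == {"AA", "A.A", "A..A"}
        assert space.sizes[2] == 3

    def test_three_residues(self):
        space = enumerate_query_motifs("ACD", L=2, W=1)
        assert {m.pattern for m in space.patterns} == {"AC", "CD", "A.D"}

    def test_too_short_error(self):
        with pytest.raises(MotifError):
            enumerate_query_motifs("A", L=3, W=2)
        with pytest.raises(MotifError):
            enumerate_query_motifs("XXXX", L=3, W=2)

    def test_masked_residues_skipped(self):
        space = enumerate_query_motifs("AXD", L=2, W=1)
        assert {m.pattern for m in space.patterns} == {"A.D"}

    def test_matches_brute_force_random_regions(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 13))
            L = int(rng.integers(2, 5))
            W = int(rng.integers(0, 4))
            region = random_sequence(rng, n)
            space = enumerate_query_motifs(region, L=L, W=W)
            oracle = brute_force_query_space(region, L, W)
            for length in range(2, L + 1):
                got = {m.pattern for m in space.patterns
                       if m.defined_length == length}
                assert got == oracle[length]
                assert space.sizes.get(length, 0) == len(oracle[length])
                assert space.sizes.get(length, 0) <= motif_space_size(length, W)


class TestEnumerateDatasetMotifs:
    def test_shared_trimer(self):
        records = [
            make_record("P1", "AAALIGAAA"),
            make_record("P2", "CCCLIGCCC"),
        ]
        part = build_upcs(["P1", "P2"])
        space = enumerate_dataset_motifs(
            [no_mask(r) for r in records], part, L=3, W=0, min_support=2
        )
        patterns = {m.pattern: info for m, info in space.patterns.items()}
        assert patterns["LIG"].support == 2
        assert patterns["LI"].support == 2
        assert patterns["IG"].support == 2

    def test_unsatisfiable_support(self):
        records = [make_record("P1", "AAALIGAAA"), make_record("P2", "CLIGC")]
        part = build_upcs(["P1", "P2"])
        space = enumerate_dataset_motifs(
            [no_mask(r) for r in records], part, min_support=3
        )
        assert len(space) == 0

    def test_single_record_no_support(self):
        records = [make_record("P1", "AAALIGAAA")]
        part = build_upcs(["P1"])
        space = enumerate_dataset_motifs(
            [no_mask(r) for r in records], part, min_support=2
        )
        assert len(space) == 0

    def test_self_consistent_with_find_occurrences(self, rng):
        records = [
            make_record(f"P{i}", random_sequence(rng, 60)) for i in range(6)
        ]
        part = build_upcs([r.id for r in records])
        masked = [no_mask(r) for r in records]
        space = enumerate_dataset_motifs(masked, part, L=3, W=2, min_support=3)
        index = part.index()
        for motif, info in space.patterns.items():
            upcs = set()
            for m in masked:
                if find_occurrences(motif, m):
                    upcs.add(index[m.record_id])
            assert upcs == set(info.support_upcs)
            assert len(upcs) >= 3


def space_with(patterns):
    """A dataset space stub from {pattern: support-upc-set}."""
    return MotifSpace(
        "dataset", 3, 2,
        {
            parse_pattern(p): PatternInfo((), frozenset(upcs))
            for p, upcs in patterns.items()
        },
    )


class TestExtendAmbiguity:
    def test_support_gain_merges(self):
        space = space_with({"LIG": {0, 1, 2}, "MIG": {3, 4}})
        extended = extend_ambiguity(space)
        merged = {m.pattern: info for m, info in extended.patterns.items()}
        assert "[LM]IG" in merged
        assert merged["[LM]IG"].support == 5

    def test_no_gain_no_merge(self):
        space = space_with({"LIG": {0, 1, 2}, "MIG": {0, 1}})
        extended = extend_ambiguity(space)
        assert "[LM]IG" not in {m.pattern for m in extended.patterns}

    def test_cross_group_never_merged(self):
        space = space_with({"LIG": {0, 1}, "DIG": {2, 3}})
        extended = extend_ambiguity(space)
        assert len(extended.patterns) == 2

    def test_malformed_group_error(self):
        space = space_with({"LIG": {0}})
        with pytest.raises(MotifError):
            extend_ambiguity(space, equivalences=("IL1",))
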