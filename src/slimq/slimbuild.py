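"""Motif representation and candidate enumeration.

A motif here is an ordered list of *defined positions* — a fixed residue or a
small ambiguity set — separated by runs of wildcard spacers.  The pattern
string rendering follows the field's convention: ``Q.[IL].FF`` is glutamine,
any residue, isoleucine-or-leucine, any residue, then two phenylalanines.
Optional ``^``/``$`` anchors pin a pattern to a protein terminus.

Two enumeration modes exist:

* **query mode** — all patterns empirically present in a (masked) query
  region, which *is* the motif space for the query-restricted search; its
  per-length cardinality replaces the combinatorial space size in the
  multiple-testing correction.
* **dataset mode** — all patterns occurring in at least ``min_support``
  unrelated protein clusters anywhere in the dataset.  Enumeration grows
  patterns one defined position at a time and prunes on support (a prefix
  occurs wherever its extension does, so support never increases with
  length), which keeps the search tractable without changing the result.

The combinatorial motif space for a pattern of ``L`` defined positions with
wildcard spacers up to ``W`` is ``20**L * (W+1)**(L-1)``, counted
independently for each length.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from .seqdata import AMINO_ACIDS, MASK_CHAR, MaskedSequence
from .upc import UPCPartition

#: Default ambiguity equivalence groups (chemically similar residues).
DEFAULT_EQUIVALENCE = ("ILMVF", "FYW", "FYH", "KRH", "DE", "ST")


class MotifError(ValueError):
    """Malformed motif pattern or enumeration input."""


@dataclass(frozen=True)
class Motif:
    """An ordered series of defined positions separated by wildcard runs.

    ``positions[i]`` is the set of residues allowed at defined position ``i``
    (a singleton for a fixed position); ``gaps[i]`` is the number of wildcard
    spacers between defined positions ``i`` and ``i+1``.
    """

    positions: tuple[frozenset[str], ...]
    gaps: tuple[int, ...] = ()
    n_anchor: bool = False
    c_anchor: bool = False

    def __post_init__(self) -> None:
        if not self.positions:
            raise MotifError("motif needs at least one defined position")
        if len(self.gaps) != len(self.positions) - 1:
            raise MotifError(
                f"motif with {len(self.positions)} defined positions needs "
                f"{len(self.positions) - 1} gap entries, got {len(self.gaps)}"
            )
        for pos in self.positions:
            if not pos or not set(pos) <= set(AMINO_ACIDS):
                raise MotifError(f"invalid defined position {sorted(pos)}")
        if any(g < 0 for g in self.gaps):
            raise MotifError("negative wildcard gap")

    @property
    def defined_length(self) -> int:
        """Number of defined (non-wildcard) positions."""
        return len(self.positions)

    @property
    def span(self) -> int:
        """Total footprint in residues, wildcards included."""
        return len(self.positions) + sum(self.gaps)

    @property
    def is_fixed(self) -> bool:
        """True when every defined position is a single residue."""
        return all(len(p) == 1 for p in self.positions)

    @property
    def pattern(self) -> str:
        parts = ["^"] if self.n_anchor else []
        for i, pos in enumerate(self.positions):
            if i:
                parts.append("." * self.gaps[i - 1])
            if len(pos) == 1:
                parts.append(next(iter(pos)))
            else:
                parts.append("[" + "".join(sorted(pos)) + "]")
        if self.c_anchor:
            parts.append("$")
        return "".join(parts)

    def __str__(self) -> str:
        return self.pattern

    def columns(self) -> list[frozenset[str] | None]:
        """Expand to one entry per residue column (``None`` = wildcard)."""
        cols: list[frozenset[str] | None] = []
        for i, pos in enumerate(self.positions):
            if i:
                cols.extend([None] * self.gaps[i - 1])
            cols.append(pos)
        return cols


_PATTERN_TOKEN = re.compile(r"\[([A-Z]+)\]|([A-Z])|(\.)")


def parse_pattern(text: str) -> Motif:
    """Parse a pattern string like ``Q.[IL].FF`` (optional ``^``/``$``)."""
    raw = text.strip()
    if not raw:
        raise MotifError("empty pattern")
    n_anchor = raw.startswith("^")
    c_anchor = raw.endswith("$")
    body = raw[1 if n_anchor else 0 : len(raw) - 1 if c_anchor else len(raw)]
    positions: list[frozenset[str]] = []
    gaps: list[int] = []
    pending_gap = 0
    pos = 0
    while pos < len(body):
        m = _PATTERN_TOKEN.match(body, pos)
        if m is None:
            raise MotifError(f"cannot parse pattern {text!r} at {body[pos:]!r}")
        pos = m.end()
        if m.group(3):  # wildcard
            if not positions:
                raise MotifError(
                    f"pattern {text!r} must begin with a defined position"
                )
            pending_gap += 1
            continue
        residues = m.group(1) or m.group(2)
        if not set(residues) <= set(AMINO_ACIDS):
            raise MotifError(f"non-amino-acid residues in pattern {text!r}")
        if m.group(1) and len(set(residues)) < 2:
            raise MotifError(f"ambiguity set in {text!r} needs >= 2 residues")
        if positions:
            gaps.append(pending_gap)
        pending_gap = 0
        positions.append(frozenset(residues))
    if pending_gap:
        raise MotifError(f"pattern {text!r} must end with a defined position")
    if not positions:
        raise MotifError(f"pattern {text!r} has no defined positions")
    return Motif(tuple(positions), tuple(gaps), n_anchor, c_anchor)


@dataclass(frozen=True)
class Occurrence:
    """One match of a motif pattern in a protein (1-based inclusive span)."""

    protein_id: str
    start: int
    end: int
    match: str
    pattern: str


@lru_cache(maxsize=65536)
def _compiled(pattern: str) -> re.Pattern[str]:
    motif = parse_pattern(pattern)
    parts = []
    for i, pos in enumerate(motif.positions):
        if i:
            parts.append("." * motif.gaps[i - 1])
        if len(pos) == 1:
            parts.append(next(iter(pos)))
        else:
            parts.append("[" + "".join(sorted(pos)) + "]")
    return re.compile("".join(parts))


def find_occurrences(motif: Motif, masked: MaskedSequence) -> list[Occurrence]:
    """All (overlapping) occurrences of ``motif`` in a masked sequence.

    Defined positions never match a masked residue (``X``); wildcards may
    cross masked residues.  Anchored motifs match only at the termini.
    """
    seq = masked.masked_string
    span = motif.span
    if span > len(seq):
        return []
    regex = _compiled(motif.pattern)
    starts: Iterable[int]
    if motif.n_anchor:
        starts = (0,)
    elif motif.c_anchor:
        starts = (len(seq) - span,)
    else:
        starts = range(len(seq) - span + 1)
    out = []
    for s in starts:
        if motif.c_anchor and s + span != len(seq):
            continue
        m = regex.match(seq, s)
        if m is not None and m.start() == s:
            out.append(
                Occurrence(masked.record_id, s + 1, s + span, seq[s : s + span],
                           motif.pattern)
            )
    return out


def motif_space_size(L: int, W: int) -> int:
    """Combinatorial motif space for ``L`` defined positions, max wildcard ``W``.

    ``20**L * (W+1)**(L-1)`` — e.g. 4,320,000 four-position motifs at W=2.
    """
    if L < 1:
        raise MotifError("L must be >= 1")
    if W < 0:
        raise MotifError("W must be >= 0")
    return 20**L * (W + 1) ** (L - 1)


@dataclass
class PatternInfo:
    """Occurrences and UPC support recorded for one enumerated pattern."""

    occurrences: tuple[Occurrence, ...] = ()
    support_upcs: frozenset[int] = frozenset()

    @property
    def support(self) -> int:
        return len(self.support_upcs)


@dataclass
class MotifSpace:
    """The set of candidate patterns for a search, with bookkeeping.

    For a query-restricted search the multiple-testing denominator per
    defined length is the number of distinct patterns enumerated from the
    query region (``sizes``); for a whole-dataset search it is the
    combinatorial space ``20**L * (W+1)**(L-1)``.
    """

    source: str  # "query" | "dataset"
    L: int
    W: int
    patterns: dict[Motif, PatternInfo] = field(default_factory=dict)
    sizes: dict[int, int] = field(default_factory=dict)

    def space_size(self, defined_length: int) -> int:
        if self.source == "query":
            return self.sizes.get(defined_length, 0)
        return motif_space_size(defined_length, self.W)

    def __len__(self) -> int:
        return len(self.patterns)


def _key_to_motif(key: tuple) -> Motif:
    positions = tuple(frozenset(key[i]) for i in range(0, len(key), 2))
    gaps = tuple(key[i] for i in range(1, len(key), 2))
    return Motif(positions, gaps)


def enumerate_query_motifs(region: str, L: int = 5, W: int = 2) -> MotifSpace:
    """All distinct patterns present in a masked query region.

    For each defined length 2..L, patterns are formed by choosing residues of
    the region in order with at most ``W`` wildcards between consecutive
    choices; duplicates collapse, so the per-length cardinality is the size
    of the restricted motif space actually searched.
    """
    if L < 2:
        raise MotifError("L must be >= 2 for query enumeration")
    unmasked = [i for i, c in enumerate(region) if c in AMINO_ACIDS]
    if len(unmasked) < 2:
        raise MotifError(
            "query region has fewer than 2 unmasked residues; nothing to search"
        )
    n = len(region)
    found: dict[int, set[tuple]] = {length: set() for length in range(2, L + 1)}

    def extend(key: tuple, last: int) -> None:
        length = (len(key) + 1) // 2
        if length >= 2:
            found[length].add(key)
        if length == L:
            return
        for g in range(W + 1):
            j = last + 1 + g
            if j < n and region[j] in AMINO_ACIDS:
                extend(key + (g, region[j]), j)

    for i in unmasked:
        extend((region[i],), i)

    patterns = {
        _key_to_motif(key): PatternInfo()
        for keys in found.values()
        for key in keys
    }
    sizes = {length: len(keys) for length, keys in found.items() if keys}
    return MotifSpace("query", L, W, patterns, sizes)


def enumerate_dataset_motifs(
    masked_seqs: Sequence[MaskedSequence],
    partition: UPCPartition,
    L: int = 5,
    W: int = 2,
    min_support: int = 3,
) -> MotifSpace:
    """All patterns occurring in at least ``min_support`` distinct UPCs.

    Support-pruned breadth-first growth: length-2 patterns are seeded from
    every unmasked residue pair within wildcard reach, and only patterns
    meeting the support threshold are extended (support is monotone
    non-increasing in pattern length, so nothing is lost).
    """
    if L < 2:
        raise MotifError("L must be >= 2")
    upc_of = partition.index()
    seqs = {m.record_id: m.masked_string for m in masked_seqs}
    for rid in seqs:
        if rid not in upc_of:
            raise MotifError(f"record {rid!r} missing from UPC partition")

    level: dict[tuple, list[tuple[str, int, int]]] = defaultdict(list)
    for rid, s in seqs.items():
        n = len(s)
        for i, aa in enumerate(s):
            if aa == MASK_CHAR:
                continue
            for g in range(W + 1):
                j = i + 1 + g
                if j < n and s[j] != MASK_CHAR:
                    level[(aa, g, s[j])].append((rid, i, j))

    kept_all: dict[tuple, tuple[list[tuple[str, int, int]], frozenset[int]]] = {}
    length = 2
    while level:
        kept = {}
        for key, occs in level.items():
            support = frozenset(upc_of[rid] for rid, _, _ in occs)
            if len(support) >= min_support:
                kept[key] = (occs, support)
        kept_all.update(kept)
        if length == L or not kept:
            break
        nxt: dict[tuple, list[tuple[str, int, int]]] = defaultdict(list)
        for key, (occs, _support) in kept.items():
            for rid, start, last in occs:
                s = seqs[rid]
                n = len(s)
                for g in range(W + 1):
                    j = last + 1 + g
                    if j < n and s[j] != MASK_CHAR:
                        nxt[key + (g, s[j])].append((rid, start, j))
        level = nxt
        length += 1

    patterns: dict[Motif, PatternInfo] = {}
    sizes: Counter[int] = Counter()
    for key, (occs, support) in kept_all.items():
        motif = _key_to_motif(key)
        occurrences = tuple(
            Occurrence(rid, start + 1, end + 1, seqs[rid][start : end + 1],
                       motif.pattern)
            for rid, start, end in occs
        )
        patterns[motif] = PatternInfo(occurrences, support)
        sizes[motif.defined_length] += 1
    return MotifSpace("dataset", L, W, patterns, dict(sizes))


def extend_ambiguity(
    space: MotifSpace,
    equivalences: Sequence[str] = DEFAULT_EQUIVALENCE,
    max_aa: int = 5,
) -> MotifSpace:
    """Add degenerate patterns built from fixed variants within one
    equivalence group.

    Fixed patterns identical except at a single position, whose differing
    residues all belong to one permitted equivalence group, are merged into
    an ambiguous pattern — but only when the merged UPC support strictly
    exceeds the support of every contributing fixed variant (the degenerate
    pattern must extend dataset coverage to earn its place).
    """
    groups = []
    for group in equivalences:
        if not set(group) <= set(AMINO_ACIDS):
            raise MotifError(f"equivalence group {group!r} has non-amino-acid letters")
        groups.append(frozenset(group))

    buckets: dict[tuple, dict[str, Motif]] = defaultdict(dict)
    for motif, info in space.patterns.items():
        if not motif.is_fixed:
            continue
        residues = [next(iter(p)) for p in motif.positions]
        for pi in range(len(residues)):
            template = (
                tuple(residues[:pi]),
                tuple(residues[pi + 1 :]),
                motif.gaps,
            )
            buckets[template][residues[pi]] = motif

    new_space = MotifSpace(space.source, space.L, space.W, dict(space.patterns),
                           dict(space.sizes))
    for (before, after, gaps), variants in buckets.items():
        for group in groups:
            members = {r: m for r, m in variants.items() if r in group}
            if not (2 <= len(members) <= max_aa):
                continue
            union_support = frozenset().union(
                *(space.patterns[m].support_upcs for m in members.values())
            )
            best_single = max(
                space.patterns[m].support for m in members.values()
            )
            if len(union_support) <= best_single:
                continue
            positions = (
                tuple(frozenset(r) for r in before)
                + (frozenset(members),)
                + tuple(frozenset(r) for r in after)
            )
            merged = Motif(positions, gaps)
            if merged in new_space.patterns:
                continue
            occurrences = tuple(
                occ
                for m in members.values()
                for occ in space.patterns[m].occurrences
            )
            new_space.patterns[merged] = PatternInfo(occurrences, union_support)
    return new_space
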