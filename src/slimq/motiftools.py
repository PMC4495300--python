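"""Motif induction from aligned instances, information content, and
motif-motif comparison.

``slimmaker`` re-derives a motif definition purely from aligned peptide
instances: per column, residues recurring in enough instances are kept if
they jointly cover most occurrences, otherwise the column becomes a
wildcard; instances that no longer match are dropped and the process
iterates to a fixpoint.  This yields definitions a de novo discovery method
could plausibly recover, unlike manually curated regular expressions that
encode specificity absent from the known instances.

Information content uses the 20-letter alphabet scale where a fixed position
scores 1 and an ambiguity set of ``a`` residues scores ``1 - ln(a)/ln(20)``.
Motif-motif comparison slides one pattern along the other; aligned defined
positions with intersecting residue sets contribute the information content
of the intersection, and predictions are rated true-positive, off-target or
false-positive against a motif library using fixed thresholds on the matched
information content.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seqdata import AMINO_ACIDS
from .slimbuild import Motif, MotifError

_LN20 = math.log(20.0)

# Rating thresholds: a motif match needs >= 2 aligned defined positions,
# MatchIC >= 1.5 and NormIC >= 0.5; an off-target match to a different
# library motif needs MatchIC >= 2.5 or NormIC >= 1.0.
MATCH_MIN_POSITIONS = 2
MATCH_MIN_IC = 1.5
MATCH_MIN_NORM_IC = 0.5
STRICT_MATCH_IC = 2.5
STRICT_NORM_IC = 1.0


class AlignmentError(ValueError):
    """Malformed instance alignment."""


class IrreducibleAlignmentError(ValueError):
    """Alignment reduced to a motif with no defined positions."""


def position_ic(allowed: Iterable[str] | None) -> float:
    """Information content of one position: wildcard 0, a residue set of
    size ``a`` scores ``1 - ln(a)/ln(20)`` (fixed position = 1)."""
    if allowed is None:
        return 0.0
    residues = frozenset(allowed)
    if not residues:
        raise MotifError("empty residue set has no information content")
    if not residues <= set(AMINO_ACIDS):
        raise MotifError(f"invalid residues {sorted(residues)}")
    return 1.0 - math.log(len(residues)) / _LN20


def motif_ic(motif: Motif) -> float:
    """Summed information content over defined positions (wildcards add 0)."""
    return sum(position_ic(pos) for pos in motif.positions)


def reduce_position(
    counts: Mapping[str, int],
    n: int,
    min_occ: int = 3,
    min_freq: float = 0.75,
    max_aa: int = 5,
) -> frozenset[str] | None:
    """Reduce one alignment column to a residue set or a wildcard.

    Residues occurring in at least ``min_occ`` instances are accepted; the
    column becomes a wildcard (``None``) when no residue qualifies, when more
    than ``max_aa`` qualify, or when the accepted residues jointly cover less
    than ``min_freq`` of the ``n`` instances.
    """
    if n <= 0:
        raise AlignmentError("instance count must be positive")
    if sum(counts.values()) > n:
        raise AlignmentError("column counts exceed instance count")
    accepted = frozenset(aa for aa, c in counts.items() if c >= min_occ)
    if not accepted or len(accepted) > max_aa:
        return None
    if sum(counts[aa] for aa in accepted) / n < min_freq:
        return None
    return accepted


@dataclass(frozen=True)
class InstanceAlignment:
    """Gap-free aligned peptide instances of equal length.

    Peptides flagged ``n_terminal``/``c_terminal`` start/end at their
    protein's terminus; a terminal anchor survives into the reduced motif
    only when every retained instance carries the flag.
    """

    peptides: tuple[str, ...]
    n_terminal: tuple[bool, ...] = ()
    c_terminal: tuple[bool, ...] = ()
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.peptides:
            raise AlignmentError("alignment needs at least one instance")
        width = len(self.peptides[0])
        if width < 1:
            raise AlignmentError("empty peptide")
        for p in self.peptides:
            if len(p) != width:
                raise AlignmentError("aligned peptides must have equal length")
            if not set(p) <= set(AMINO_ACIDS):
                raise AlignmentError(f"non-amino-acid residues in {p!r}")
        for name in ("n_terminal", "c_terminal"):
            flags = getattr(self, name)
            if flags and len(flags) != len(self.peptides):
                raise AlignmentError(f"{name} flags must match instance count")

    @classmethod
    def from_strings(cls, lines: Iterable[str]) -> "InstanceAlignment":
        """Parse peptides, one per line; a leading ``^`` / trailing ``$``
        marks an instance as protein-terminal."""
        peptides, n_flags, c_flags = [], [], []
        for line in lines:
            text = line.strip().upper()
            if not text or text.startswith("#"):
                continue
            n_flags.append(text.startswith("^"))
            c_flags.append(text.endswith("$"))
            peptides.append(text.strip("^$"))
        if not peptides:
            raise AlignmentError("no instances found")
        return cls(tuple(peptides), tuple(n_flags), tuple(c_flags))

    @property
    def width(self) -> int:
        return len(self.peptides[0])

    def __len__(self) -> int:
        return len(self.peptides)


@dataclass(frozen=True)
class SlimMakerResult:
    motif: Motif
    retained: tuple[int, ...]  # indices into the input alignment
    iterations: int


def _reduce_columns(
    alignment: InstanceAlignment,
    retained: Sequence[int],
    min_occ: int,
    min_freq: float,
    max_aa: int,
) -> list[frozenset[str] | None]:
    n = len(retained)
    return [
        reduce_position(
            Counter(alignment.peptides[i][col] for i in retained),
            n, min_occ, min_freq, max_aa,
        )
        for col in range(alignment.width)
    ]


def _columns_to_motif(
    columns: Sequence[frozenset[str] | None], n_anchor: bool, c_anchor: bool
) -> tuple[Motif, int, int]:
    """Trim flanking wildcards and assemble a motif; returns the motif plus
    the trimmed column offsets."""
    defined = [i for i, c in enumerate(columns) if c is not None]
    if not defined:
        raise IrreducibleAlignmentError(
            "alignment reduces to all-wildcard; motif is irreducible"
        )
    first, last = defined[0], defined[-1]
    positions, gaps = [columns[first]], []
    prev = first
    for i in defined[1:]:
        gaps.append(i - prev - 1)
        positions.append(columns[i])
        prev = i
    return (
        Motif(tuple(positions), tuple(gaps),
              n_anchor and first == 0,
              c_anchor and last == len(columns) - 1),
        first,
        last,
    )


def _instance_matches(
    peptide: str, columns: Sequence[frozenset[str] | None]
) -> bool:
    return all(
        col is None or peptide[i] in col for i, col in enumerate(columns)
    )


def slimmaker(
    alignment: InstanceAlignment,
    min_occ: int = 3,
    min_freq: float = 0.75,
    max_aa: int = 5,
) -> SlimMakerResult:
    """Induce a motif definition from aligned instances, iterating to a
    fixpoint.

    Each round reduces every column with :func:`reduce_position`, trims
    flanking wildcards, drops instances that no longer match the interior
    columns, and repeats on the retained subset until the retained set is
    stable.  Terminal anchors are kept only while every retained instance is
    terminal.  Termination is guaranteed because the retained set never
    grows.
    """
    retained = list(range(len(alignment)))
    iterations = 0
    while True:
        iterations += 1
        columns = _reduce_columns(alignment, retained, min_occ, min_freq, max_aa)
        n_anchor = bool(alignment.n_terminal) and all(
            alignment.n_terminal[i] for i in retained
        )
        c_anchor = bool(alignment.c_terminal) and all(
            alignment.c_terminal[i] for i in retained
        )
        motif, _first, _last = _columns_to_motif(columns, n_anchor, c_anchor)
        new_retained = [
            i for i in retained
            if _instance_matches(alignment.peptides[i], columns)
        ]
        if not new_retained:
            raise IrreducibleAlignmentError(
                "no instance matches the reduced motif"
            )
        if new_retained == retained:
            return SlimMakerResult(motif, tuple(retained), iterations)
        retained = new_retained


@dataclass(frozen=True)
class MatchResult:
    """Best ungapped alignment of two motif patterns.

    ``match_ic`` sums the information content of the residue-set
    intersections at aligned defined positions; ``norm_ic`` scales it by the
    information content of the smaller motif, capped at 1.
    """

    motif_a: str
    motif_b: str
    matched_positions: int
    match_ic: float
    norm_ic: float
    offset: int

    @property
    def is_match(self) -> bool:
        return (
            self.matched_positions >= MATCH_MIN_POSITIONS
            and self.match_ic >= MATCH_MIN_IC
            and self.norm_ic >= MATCH_MIN_NORM_IC
        )


def compare_motifs(a: Motif, b: Motif) -> MatchResult:
    """Score the best ungapped relative alignment of two patterns.

    Every relative offset where the patterns overlap is tried; a position
    pair matches when both columns are defined and their residue sets
    intersect, contributing the information content of the intersection.
    """
    cols_a, cols_b = a.columns(), b.columns()
    best_ic, best_count, best_offset = 0.0, 0, 0
    for offset in range(-(len(cols_b) - 1), len(cols_a)):
        ic, count = 0.0, 0
        for j, col_b in enumerate(cols_b):
            i = offset + j
            if 0 <= i < len(cols_a):
                col_a = cols_a[i]
                if col_a is not None and col_b is not None:
                    inter = col_a & col_b
                    if inter:
                        ic += position_ic(inter)
                        count += 1
        if (ic, count) > (best_ic, best_count):
            best_ic, best_count, best_offset = ic, count, offset
    min_ic = min(motif_ic(a), motif_ic(b))
    norm = min(1.0, best_ic / min_ic) if min_ic > 0 and best_ic > 0 else 0.0
    return MatchResult(a.pattern, b.pattern, best_count, best_ic, norm,
                       best_offset)


def rate_prediction(
    pattern: Motif,
    dataset_motif: str,
    motif_library: Mapping[str, Motif],
    tp_registry: Iterable[str] = (),
) -> str:
    """Rate a predicted pattern as ``"TP"``, ``"OT"`` or ``"FP"``.

    A library hit is a *motif match* when it aligns at two or more defined
    positions with MatchIC >= 1.5 and NormIC >= 0.5.  A match to the motif
    the dataset was built from is a true positive.  Remaining matches are
    off-target when the pattern was already recognised as a TP in another
    dataset (``tp_registry`` of pattern strings) or when a different library
    motif is matched at the stricter MatchIC >= 2.5 or NormIC >= 1.0.
    Everything else is a false positive.
    """
    if not motif_library:
        raise MotifError("motif library is empty")
    matches = {
        name: compare_motifs(pattern, motif)
        for name, motif in motif_library.items()
    }
    matches = {name: r for name, r in matches.items() if r.is_match}
    if dataset_motif in matches:
        return "TP"
    if not matches:
        return "FP"
    if pattern.pattern in set(tp_registry):
        return "OT"
    if any(
        r.match_ic >= STRICT_MATCH_IC or r.norm_ic >= STRICT_NORM_IC
        for r in matches.values()
    ):
        return "OT"
    return "FP"
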