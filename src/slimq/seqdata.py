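"""Protein sequence handling: FASTA and disorder-score I/O, disorder-based
masking and query-region selection.

Short linear motifs occur predominantly in intrinsically disordered regions,
so motif discovery normally masks away ordered sequence first: residues whose
per-residue disorder score falls below a threshold are replaced by ``X`` and
excluded from motif building.  Runs of either state shorter than a minimum
region size are smoothed away so that only (dis)ordered regions of a
biologically sensible size survive.

Coordinates are 1-based inclusive at every interface; internal indices are
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MASK_CHAR = "X"
ALPHABET = AMINO_ACIDS + MASK_CHAR

#: The six query flanking-region strategies, from least to most resolved.
STRATEGIES = ("none", "win300", "win100", "win50", "flank5", "site")
_WINDOW_SIZES = {"win300": 300, "win100": 100, "win50": 50}
_FLANK = 5


class SequenceError(ValueError):
    """Malformed sequence input: bad residues, duplicate ids, empty files."""


@dataclass(frozen=True, eq=True)
class ProteinRecord:
    """One protein sequence with optional per-residue disorder scores.

    Parameters
    ----------
    id:
        Unique accession within a dataset.
    sequence:
        Upper-case amino-acid string over the 20-letter alphabet plus ``X``.
    disorder:
        Optional per-residue disorder scores in ``[0, 1]`` (IUPred-style),
        one score per residue.
    annotations:
        Optional mapping of labels to 1-based inclusive intervals, e.g. a
        known motif instance span under the key ``"instance"``.
    """

    id: str
    sequence: str
    disorder: tuple[float, ...] | None = None
    annotations: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("protein id must be non-empty")
        if not self.sequence:
            raise SequenceError(f"sequence for {self.id!r} is empty")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise SequenceError(
                f"sequence for {self.id!r} contains non-amino-acid "
                f"characters: {sorted(bad)}"
            )
        if self.disorder is not None:
            if len(self.disorder) != len(self.sequence):
                raise SequenceError(
                    f"disorder scores for {self.id!r} have length "
                    f"{len(self.disorder)}, sequence has {len(self.sequence)}"
                )
        for label, (start, end) in self.annotations.items():
            if not (1 <= start <= end <= len(self.sequence)):
                raise SequenceError(
                    f"annotation {label!r} interval ({start}, {end}) outside "
                    f"protein {self.id!r} of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MaskedSequence:
    """A sequence with a per-residue boolean mask (``True`` = masked).

    ``masked_string`` is the sequence with masked residues replaced by ``X``;
    motif occurrences may never place a defined position on a masked residue,
    while wildcard spacers may cross one.
    """

    record_id: str
    sequence: str
    mask: tuple[bool, ...]
    masked_string: str

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.mask) == len(self.masked_string)):
            raise SequenceError("mask/sequence length mismatch")

    @property
    def unmasked_count(self) -> int:
        return len(self.mask) - sum(self.mask)

    def segments(self) -> Iterator[tuple[int, int]]:
        """Yield maximal unmasked segments as 0-based half-open intervals."""
        start = None
        for i, m in enumerate(self.mask):
            if not m and start is None:
                start = i
            elif m and start is not None:
                yield (start, i)
                start = None
        if start is not None:
            yield (start, len(self.mask))

    def segment_lengths(self) -> list[int]:
        return [j - i for i, j in self.segments()]


@dataclass(frozen=True)
class QueryRegion:
    """A 1-based inclusive interval of a query protein with its strategy label."""

    protein_id: str
    start: int
    end: int
    strategy: str = "site"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise SequenceError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if not (1 <= self.start <= self.end):
            raise SequenceError(
                f"invalid query region ({self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id; sequences
    are upper-cased and stop characters (``*``) stripped.  Duplicate ids and
    empty files raise :class:`SequenceError`.
    """
    path = Path(path)
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise SequenceError(f"no FASTA entries found in {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in entries:
        pid = entry.id
        if pid in seen:
            raise SequenceError(f"duplicate sequence id {pid!r} in {path}")
        seen.add(pid)
        seq = str(entry.seq).upper().replace("*", "")
        records.append(ProteinRecord(pid, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (ids only, no descriptions)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_disorder_tsv(path: str | Path) -> dict[str, tuple[float, ...]]:
    """Read a disorder score table.

    Format: tab-separated with a header row ``protein  position  score`` and
    optional ``#`` comment lines; one row per residue, positions 1-based and
    contiguous per protein.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["protein", "position", "score"]
    if list(df.columns[:3]) != expected:
        raise SequenceError(
            f"disorder table {path} must have columns {expected}, "
            f"got {list(df.columns)}"
        )
    table: dict[str, tuple[float, ...]] = {}
    for pid, sub in df.groupby("protein", sort=False):
        sub = sub.sort_values("position")
        positions = sub["position"].to_numpy()
        if positions[0] != 1 or (positions != range(1, len(sub) + 1)).any():
            raise SequenceError(
                f"disorder positions for {pid!r} are not contiguous from 1"
            )
        scores = tuple(float(s) for s in sub["score"])
        if any(not (0.0 <= s <= 1.0) for s in scores):
            raise SequenceError(f"disorder scores for {pid!r} outside [0, 1]")
        table[str(pid)] = scores
    return table


def write_disorder_tsv(records: Iterable[ProteinRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        if r.disorder is None:
            raise SequenceError(f"record {r.id!r} has no disorder scores")
        for i, s in enumerate(r.disorder, start=1):
            rows.append((r.id, i, s))
    pd.DataFrame(rows, columns=["protein", "position", "score"]).to_csv(
        path, sep="\t", index=False
    )


def attach_disorder(
    records: Iterable[ProteinRecord], scores: Mapping[str, Sequence[float]]
) -> list[ProteinRecord]:
    """Return new records carrying disorder scores from ``scores``."""
    out = []
    for r in records:
        if r.id not in scores:
            raise SequenceError(f"no disorder scores for protein {r.id!r}")
        out.append(
            ProteinRecord(r.id, r.sequence, tuple(scores[r.id]), dict(r.annotations))
        )
    return out


def smooth_runs(states: Sequence[bool], min_region: int) -> list[bool]:
    """Flip runs of identical state shorter than ``min_region``.

    Runs are processed left to right: the first run shorter than
    ``min_region`` is flipped to the opposite state, runs are recomputed, and
    the process repeats until no short run remains.  A single full-sequence
    run is always allowed, however short.
    """
    mask = list(states)
    while True:
        runs = _runs(mask)
        if len(runs) <= 1:
            break
        short = next((r for r in runs if r[1] - r[0] < min_region), None)
        if short is None:
            break
        for i in range(short[0], short[1]):
            mask[i] = not mask[i]
    return mask


def _runs(mask: Sequence[bool]) -> list[tuple[int, int]]:
    runs = []
    start = 0
    for i in range(1, len(mask) + 1):
        if i == len(mask) or mask[i] != mask[start]:
            runs.append((start, i))
            start = i
    return runs


def disorder_mask(
    record: ProteinRecord, threshold: float = 0.2, min_region: int = 5
) -> MaskedSequence:
    """Mask residues predicted ordered (disorder score below ``threshold``).

    After thresholding, runs of either mask state shorter than ``min_region``
    are smoothed away (see :func:`smooth_runs`) so both ordered and
    disordered regions have a minimum size.
    """
    if record.disorder is None:
        raise SequenceError(
            f"record {record.id!r} has no disorder scores; supply a score "
            "table or disable disorder masking"
        )
    raw = [s < threshold for s in record.disorder]
    mask = tuple(smooth_runs(raw, min_region))
    return _apply_mask(record, mask)


def no_mask(record: ProteinRecord) -> MaskedSequence:
    """A pass-through mask (nothing masked)."""
    mask = (False,) * len(record)
    return MaskedSequence(record.id, record.sequence, mask, record.sequence)


def _apply_mask(record: ProteinRecord, mask: tuple[bool, ...]) -> MaskedSequence:
    masked = "".join(
        MASK_CHAR if m else c for c, m in zip(record.sequence, mask)
    )
    return MaskedSequence(record.id, record.sequence, mask, masked)


def select_query_region(
    record: ProteinRecord,
    strategy: str,
    instance: tuple[int, int] | None = None,
) -> QueryRegion:
    """Select the query region for one of the six flanking strategies.

    ``none`` returns the whole protein; ``winN`` a window of N residues
    centred on the instance midpoint, shifted to the terminal N residues when
    the instance lies within N/2 of a terminus; ``flank5`` the instance
    extended five residues each side (clipped at termini); ``site`` the
    instance exactly.
    """
    if strategy not in STRATEGIES:
        raise SequenceError(
            f"unknown strategy {strategy!r}; expected one of {STRATEGIES}"
        )
    length = len(record)
    if strategy == "none":
        return QueryRegion(record.id, 1, length, "none")
    if instance is None:
        raise SequenceError(f"strategy {strategy!r} requires a motif instance")
    start, end = instance
    if not (1 <= start <= end <= length):
        raise SequenceError(
            f"instance ({start}, {end}) outside protein {record.id!r} "
            f"of length {length}"
        )
    if strategy == "site":
        return QueryRegion(record.id, start, end, "site")
    if strategy == "flank5":
        return QueryRegion(
            record.id, max(1, start - _FLANK), min(length, end + _FLANK), "flank5"
        )
    n = _WINDOW_SIZES[strategy]
    if length <= n:
        return QueryRegion(record.id, 1, length, strategy)
    centre = (start + end) // 2
    w_start = centre - n // 2 + 1
    w_end = w_start + n - 1
    if w_start < 1:  # instance within N/2 of the N-terminus
        w_start, w_end = 1, n
    elif w_end > length:  # within N/2 of the C-terminus
        w_start, w_end = length - n + 1, length
    return QueryRegion(record.id, w_start, w_end, strategy)
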