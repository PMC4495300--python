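"""Benchmark dataset simulation and performance metrics.

Simulated interaction datasets mix a known proportion of *signal* proteins —
all carrying an implanted instance of a chosen motif in a disordered region —
with random *noise* proteins, across signal counts of 5 or 10 (including the
query) and signal-to-noise ratios 1:0, 1:1, 1:4, 1:9 and 1:19.  Each positive
dataset is paired with a true-negative dataset sharing the same query but
with every other protein drawn at random and implant-free.  A synthetic
proteome generator stands in for a real proteome: lengths, residue
composition, homologous families and an alternating ordered/disordered block
structure are all configurable and every artifact is reproducible from its
seed.

Prediction performance is summarised by SN — the proportion of (positive)
datasets returning a true-positive motif — and FPX — the proportion of
(negative) datasets returning a false positive — with off-target matches
excluded from both numerators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqdata import (
    AMINO_ACIDS,
    ProteinRecord,
    QueryRegion,
    STRATEGIES,
    select_query_region,
)
from .slimbuild import Motif, parse_pattern
from .upc import pairwise_related, partition_dataset

#: Roughly vertebrate-like background amino-acid frequencies.
DEFAULT_AA_FREQS: dict[str, float] = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.053, "W": 0.012, "Y": 0.027, "V": 0.061,
}

RATIOS: dict[str, int] = {"1:0": 0, "1:1": 1, "1:4": 4, "1:9": 9, "1:19": 19}

DISORDER_THRESHOLD = 0.2


class BenchError(ValueError):
    """Invalid simulation request (insufficient proteins, no disorder, ...)."""


@dataclass(frozen=True)
class ProteomeParams:
    """Shape of a synthetic proteome.

    Disorder is generated as alternating ordered/disordered blocks with
    uniform lengths in the stated ranges; disordered residues score in
    ``[0.2, 1)`` and ordered residues in ``[0, 0.2)``, so the standard
    masking threshold recovers the block structure exactly.  Families are
    generated by mutating a parent sequence at ``family_mutation_rate`` per
    site, which keeps members detectably homologous.
    """

    n_proteins: int = 50
    min_length: int = 150
    max_length: int = 300
    aa_freqs: Mapping[str, float] | None = None
    n_families: int = 0
    family_size: int = 3
    family_mutation_rate: float = 0.05
    ordered_block: tuple[int, int] = (10, 30)
    disordered_block: tuple[int, int] = (20, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0 or self.n_families < 0 or self.family_size < 1:
            raise BenchError("counts must be non-negative")
        if not 0.0 <= self.family_mutation_rate <= 1.0:
            raise BenchError("mutation rate must be in [0, 1]")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise BenchError("invalid length range")


def _freq_arrays(
    aa_freqs: Mapping[str, float] | None,
) -> tuple[np.ndarray, np.ndarray]:
    freqs = dict(DEFAULT_AA_FREQS if aa_freqs is None else aa_freqs)
    letters = np.array(list(AMINO_ACIDS))
    probs = np.array([freqs.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    if probs.sum() <= 0:
        raise BenchError("amino-acid frequency profile is empty")
    return letters, probs / probs.sum()


def _random_sequence(
    rng: np.random.Generator, length: int, letters: np.ndarray, probs: np.ndarray
) -> str:
    return "".join(rng.choice(letters, size=length, p=probs))


def _random_disorder(
    rng: np.random.Generator, length: int, params: ProteomeParams
) -> tuple[float, ...]:
    scores: list[float] = []
    disordered = bool(rng.integers(0, 2))
    while len(scores) < length:
        lo, hi = (
            params.disordered_block if disordered else params.ordered_block
        )
        block = int(rng.integers(lo, hi + 1))
        if disordered:
            vals = rng.uniform(DISORDER_THRESHOLD, 1.0, size=block)
        else:
            vals = rng.uniform(0.0, DISORDER_THRESHOLD, size=block)
        scores.extend(float(v) for v in vals)
        disordered = not disordered
    return tuple(scores[:length])


def _mutate(
    rng: np.random.Generator,
    sequence: str,
    rate: float,
    letters: np.ndarray,
    probs: np.ndarray,
) -> str:
    out = list(sequence)
    hits = np.flatnonzero(rng.random(len(sequence)) < rate)
    for i in hits:
        choices = [aa for aa in AMINO_ACIDS if aa != out[i]]
        out[i] = str(rng.choice(choices))
    return "".join(out)


def generate_proteome(params: ProteomeParams) -> list[ProteinRecord]:
    """Generate a reproducible synthetic proteome.

    Singleton proteins are mutually unrelated (independent random sequences);
    family members descend from a common parent and are detectably
    homologous to each other.
    """
    rng = np.random.default_rng(params.seed)
    letters, probs = _freq_arrays(params.aa_freqs)
    records: list[ProteinRecord] = []
    for fam in range(params.n_families):
        length = int(rng.integers(params.min_length, params.max_length + 1))
        parent = _random_sequence(rng, length, letters, probs)
        for member in range(params.family_size):
            seq = (
                parent
                if member == 0
                else _mutate(rng, parent, params.family_mutation_rate,
                             letters, probs)
            )
            records.append(
                ProteinRecord(
                    f"FAM{fam + 1}_{member + 1}",
                    seq,
                    _random_disorder(rng, length, params),
                )
            )
    for i in range(params.n_proteins):
        length = int(rng.integers(params.min_length, params.max_length + 1))
        records.append(
            ProteinRecord(
                f"SYN{i + 1:04d}",
                _random_sequence(rng, length, letters, probs),
                _random_disorder(rng, length, params),
            )
        )
    return records


def _disordered_starts(record: ProteinRecord, span: int) -> list[int]:
    if record.disorder is None:
        raise BenchError(f"record {record.id!r} has no disorder scores")
    ok = [s >= DISORDER_THRESHOLD for s in record.disorder]
    return [
        i
        for i in range(len(record) - span + 1)
        if all(ok[i : i + span])
    ]


def implant_instance(
    record: ProteinRecord,
    motif: Motif | str,
    rng: np.random.Generator,
    aa_freqs: Mapping[str, float] | None = None,
) -> ProteinRecord:
    """Implant a concrete realisation of ``motif`` into a disordered region.

    A peptide is sampled uniformly from the pattern's match set (wildcards
    drawn from the background profile), placed at a uniformly chosen
    position whose whole span is disordered, and recorded under the
    ``"instance"`` annotation.
    """
    if isinstance(motif, str):
        motif = parse_pattern(motif)
    letters, probs = _freq_arrays(aa_freqs)
    span = motif.span
    starts = _disordered_starts(record, span)
    if not starts:
        raise BenchError(
            f"record {record.id!r} has no disordered region of >= {span} residues"
        )
    start = int(rng.choice(starts))
    peptide = []
    for col in motif.columns():
        if col is None:
            peptide.append(str(rng.choice(letters, p=probs)))
        else:
            peptide.append(str(rng.choice(sorted(col))))
    seq = record.sequence[:start] + "".join(peptide) + record.sequence[start + span :]
    annotations = dict(record.annotations)
    annotations["instance"] = (start + 1, start + span)
    return ProteinRecord(record.id, seq, record.disorder, annotations)


@dataclass(frozen=True)
class SimDatasetSpec:
    """One simulated dataset request."""

    motif: str
    signal: int = 10
    ratio: str = "1:0"
    replicate: int = 1
    strategy: str = "site"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal not in (5, 10):
            raise BenchError("signal count must be 5 or 10")
        if self.ratio not in RATIOS:
            raise BenchError(
                f"ratio {self.ratio!r} not one of {sorted(RATIOS)}"
            )
        if self.strategy not in STRATEGIES:
            raise BenchError(f"unknown strategy {self.strategy!r}")

    @property
    def total(self) -> int:
        return self.signal * (1 + RATIOS[self.ratio])


@dataclass(frozen=True)
class BenchmarkDataset:
    """A labelled simulated dataset with a designated query."""

    records: tuple[ProteinRecord, ...]
    query_id: str
    labels: Mapping[str, str]  # id -> "signal" | "noise"
    kind: str  # "positive" | "negative"
    motif: str
    strategy: str
    seed: int

    @property
    def query_record(self) -> ProteinRecord:
        for r in self.records:
            if r.id == self.query_id:
                return r
        raise BenchError("query record missing")

    def query_region(self) -> QueryRegion:
        record = self.query_record
        instance = record.annotations.get("instance")
        return select_query_region(record, self.strategy, instance)


def _select_unrelated_implanted(
    rng: np.random.Generator,
    candidates: Sequence[ProteinRecord],
    motif: Motif,
    count: int,
    evalue: float,
) -> list[ProteinRecord]:
    """Greedily pick ``count`` implanted proteins that remain pairwise
    unrelated.

    Unrelatedness is checked *after* implantation, because a shared implanted
    peptide occasionally pushes an otherwise-random pair over the relatedness
    threshold; checking the final sequences guarantees the signal proteins
    form one UPC each under the same scorer the search will use.
    """
    order = list(rng.permutation(len(candidates)))
    chosen: list[ProteinRecord] = []
    for idx in order:
        candidate = implant_instance(candidates[idx], motif, rng)
        if all(not pairwise_related(candidate, c, evalue)[0] for c in chosen):
            chosen.append(candidate)
        if len(chosen) == count:
            return chosen
    raise BenchError(
        f"insufficient mutually unrelated signal proteins: needed {count}, "
        f"found {len(chosen)}"
    )


def build_simbench(
    proteome: Sequence[ProteinRecord],
    spec: SimDatasetSpec,
    evalue: float = 1e-4,
) -> tuple[BenchmarkDataset, BenchmarkDataset]:
    """Build one positive dataset and its paired true-negative dataset.

    The positive dataset is the query plus ``signal - 1`` further mutually
    unrelated proteins, each implanted with the motif in a disordered
    region, completed with randomly drawn noise proteins.  The negative
    twin keeps the same query (implant included) but fills the rest of the
    dataset with random, implant-free proteins of the same total count.
    """
    spec_motif = parse_pattern(spec.motif)
    rng = np.random.default_rng(spec.seed)
    total = spec.total
    if len(proteome) < total:
        raise BenchError(
            f"proteome of {len(proteome)} proteins cannot fill a dataset of {total}"
        )
    eligible = [
        r for r in proteome if _disordered_starts(r, spec_motif.span)
    ]
    signal = _select_unrelated_implanted(
        rng, eligible, spec_motif, spec.signal, evalue
    )
    query = signal[0]
    signal_ids = {r.id for r in signal}

    remainder = [r for r in proteome if r.id not in signal_ids]
    n_noise = total - spec.signal
    if len(remainder) < n_noise:
        raise BenchError("insufficient noise proteins in proteome")
    noise_idx = rng.choice(len(remainder), size=n_noise, replace=False)
    noise = [remainder[int(i)] for i in noise_idx]

    positive = BenchmarkDataset(
        tuple(signal + noise),
        query.id,
        {**{r.id: "signal" for r in signal}, **{r.id: "noise" for r in noise}},
        "positive",
        spec.motif,
        spec.strategy,
        spec.seed,
    )

    others = [r for r in proteome if r.id != query.id]
    neg_idx = rng.choice(len(others), size=total - 1, replace=False)
    negatives = [others[int(i)] for i in neg_idx]
    negative = BenchmarkDataset(
        tuple([query] + negatives),
        query.id,
        {query.id: "signal", **{r.id: "noise" for r in negatives}},
        "negative",
        spec.motif,
        spec.strategy,
        spec.seed,
    )
    return positive, negative


def verify_signal_unrelated(
    dataset: BenchmarkDataset, evalue: float = 1e-4
) -> bool:
    """Check that the signal proteins of a dataset are pairwise unrelated."""
    signal = [r for r in dataset.records if dataset.labels[r.id] == "signal"]
    partition = partition_dataset(signal, evalue)
    return partition.n == len(signal)


@dataclass(frozen=True)
class ElmBenchJob:
    """One search job: a dataset member used as query at one resolution."""

    query_id: str
    strategy: str
    region: QueryRegion


def build_elmbench(
    records: Sequence[ProteinRecord],
    strategies: Sequence[str] = STRATEGIES,
) -> list[ElmBenchJob]:
    """Expand an instance-annotated dataset into per-query, per-strategy jobs.

    Every record is taken in turn as the query, masked at each of the six
    resolution levels, giving ``len(records) * len(strategies)`` jobs over
    the shared dataset.
    """
    jobs = []
    for record in records:
        instance = record.annotations.get("instance")
        if instance is None:
            raise BenchError(
                f"record {record.id!r} has no 'instance' annotation"
            )
        for strategy in strategies:
            region = select_query_region(record, strategy, instance)
            jobs.append(ElmBenchJob(record.id, strategy, region))
    return jobs


def compute_metrics(
    ratings: pd.DataFrame,
    group_by: Sequence[str] = (),
    normalise_by_motif: bool = False,
) -> pd.DataFrame:
    """Aggregate per-dataset ratings into SN/FPX cells.

    ``ratings`` needs columns ``motif``, ``kind`` ("positive"/"negative")
    and ``rating`` ("TP"/"OT"/"FP" or missing for no prediction).  SN is the
    proportion of positive datasets rated TP; FPX the proportion of negative
    datasets rated FP; off-target ratings count in neither numerator.  With
    ``normalise_by_motif`` the cell value is the mean of per-motif
    proportions, so motifs with unequal dataset counts weigh equally.
    Empty denominators yield NaN, never silent zeros.
    """
    required = {"motif", "kind", "rating"}
    if not required <= set(ratings.columns):
        raise BenchError(f"ratings table needs columns {sorted(required)}")

    def _cell(sub: pd.DataFrame) -> pd.Series:
        pos = sub[sub["kind"] == "positive"]
        neg = sub[sub["kind"] == "negative"]
        return pd.Series(
            {
                "SN": (pos["rating"] == "TP").mean() if len(pos) else np.nan,
                "FPX": (neg["rating"] == "FP").mean() if len(neg) else np.nan,
                "n_positive": len(pos),
                "n_negative": len(neg),
            }
        )

    if normalise_by_motif:
        per_motif_keys = list(group_by) + ["motif"]
        per_motif = (
            ratings.groupby(per_motif_keys, sort=True)
            .apply(_cell, include_groups=False)
            .reset_index()
        )
        if not group_by:
            return pd.DataFrame(
                {
                    "SN": [per_motif["SN"].mean()],
                    "FPX": [per_motif["FPX"].mean()],
                    "n_positive": [int(per_motif["n_positive"].sum())],
                    "n_negative": [int(per_motif["n_negative"].sum())],
                }
            )
        return (
            per_motif.groupby(list(group_by), sort=True)
            .agg(
                SN=("SN", "mean"),
                FPX=("FPX", "mean"),
                n_positive=("n_positive", "sum"),
                n_negative=("n_negative", "sum"),
            )
            .reset_index()
        )
    if not group_by:
        return _cell(ratings).to_frame().T
    return (
        ratings.groupby(list(group_by), sort=True)
        .apply(_cell, include_groups=False)
        .reset_index()
    )
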