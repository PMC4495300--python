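"""Unrelated protein clusters (UPC).

Motif over-representation statistics must count evolutionary relatives once:
homologous proteins share motifs by descent, not by convergence.  Proteins
are therefore grouped into UPCs — connected components of a pairwise
relatedness graph — such that no protein in one cluster has detectable
homology (E-value below a threshold, default 1e-4) with a protein in
another.  The UPC, not the protein, is the statistical unit of support.

The built-in relatedness scorer is a Smith–Waterman local alignment with
BLOSUM62 scoring and a Karlin–Altschul-form significance estimate,
calibrated so that identical or lightly mutated sequences of typical length
are related while independently random pairs are not.  Users with a
precomputed homology search can supply an edge list instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seqdata import ProteinRecord

DEFAULT_EVALUE = 1e-4

# Karlin–Altschul parameters for gapped BLOSUM62 (open 11, extend 1) scoring;
# the calibration contract (random pairs unrelated, mutated pairs related) is
# what matters, not the historical constants.
_LAMBDA = 0.267
_KAPPA = 0.041


class UPCError(ValueError):
    """Bad input to UPC construction (unknown ids in an edge list, ...)."""


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def alignment_evalue(score: float, m: int, n: int) -> float:
    """Extreme-value significance estimate for a local alignment score."""
    return _KAPPA * m * n * math.exp(-_LAMBDA * score)


def pairwise_related(
    a: ProteinRecord, b: ProteinRecord, evalue_threshold: float = DEFAULT_EVALUE
) -> tuple[bool, float]:
    """Decide whether two proteins are detectably homologous.

    Returns ``(related, evalue)`` where ``related`` is true when the
    local-alignment significance estimate falls below ``evalue_threshold``.
    """
    score = _aligner().score(a.sequence, b.sequence)
    evalue = alignment_evalue(score, len(a), len(b))
    return evalue < evalue_threshold, evalue


def relatedness_edges(
    records: Sequence[ProteinRecord], evalue_threshold: float = DEFAULT_EVALUE
) -> list[tuple[str, str, float]]:
    """All related pairs among ``records`` under the built-in scorer."""
    edges = []
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            related, evalue = pairwise_related(a, b, evalue_threshold)
            if related:
                edges.append((a.id, b.id, evalue))
    return edges


def read_edges_tsv(
    path: str | Path, evalue_threshold: float = DEFAULT_EVALUE
) -> list[tuple[str, str, float]]:
    """Read a precomputed homology edge list (columns id_a, id_b, evalue).

    Only edges below ``evalue_threshold`` are returned, so a full all-vs-all
    search output can be supplied unfiltered.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["id_a", "id_b", "evalue"]
    if list(df.columns[:3]) != expected:
        raise UPCError(
            f"edge list {path} must have columns {expected}, got {list(df.columns)}"
        )
    return [
        (str(r.id_a), str(r.id_b), float(r.evalue))
        for r in df.itertuples()
        if float(r.evalue) < evalue_threshold
    ]


@dataclass(frozen=True)
class UPCPartition:
    """Disjoint clusters of related proteins covering a dataset.

    Clusters are ordered deterministically by their smallest member id.
    """

    clusters: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cluster in self.clusters:
            if not cluster:
                raise UPCError("empty UPC cluster")
            if cluster & seen:
                raise UPCError("UPC clusters are not disjoint")
            seen |= cluster

    @property
    def n(self) -> int:
        return len(self.clusters)

    def index(self) -> dict[str, int]:
        """Map each protein id to its cluster index."""
        return {
            pid: ci for ci, cluster in enumerate(self.clusters) for pid in cluster
        }

    def cluster_of(self, protein_id: str) -> int:
        for ci, cluster in enumerate(self.clusters):
            if protein_id in cluster:
                return ci
        raise UPCError(f"protein {protein_id!r} not in partition")


def build_upcs(
    ids: Iterable[str], edges: Iterable[tuple[str, str, float]] = ()
) -> UPCPartition:
    """Cluster proteins into UPCs by single linkage over a relatedness graph.

    Clusters are the connected components, so no edge ever crosses clusters.
    """
    graph = nx.Graph()
    id_list = list(ids)
    if len(id_list) != len(set(id_list)):
        raise UPCError("duplicate protein ids")
    graph.add_nodes_from(id_list)
    known = set(id_list)
    for a, b, _evalue in edges:
        if a not in known or b not in known:
            missing = a if a not in known else b
            raise UPCError(f"edge references unknown protein id {missing!r}")
        graph.add_edge(a, b)
    components = [frozenset(c) for c in nx.connected_components(graph)]
    components.sort(key=min)
    return UPCPartition(tuple(components))


def partition_dataset(
    records: Sequence[ProteinRecord],
    evalue_threshold: float = DEFAULT_EVALUE,
    edges: Iterable[tuple[str, str, float]] | None = None,
) -> UPCPartition:
    """Build the UPC partition for a dataset.

    Uses the supplied edge list when given, otherwise the built-in
    all-vs-all local-alignment scorer.
    """
    if edges is None:
        edges = relatedness_edges(records, evalue_threshold)
    return build_upcs([r.id for r in records], edges)
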