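"""Full motif discovery runs: masking, clustering, enumeration, statistics,
cloud grouping and ranked output.

Two modes share the pipeline.  A whole-dataset search enumerates every
pattern supported by enough unrelated protein clusters and corrects its
significance against the full combinatorial motif space.  A query-restricted
search enumerates patterns from a designated query region only, removes the
query's cluster from all support counting, and corrects against the (much
smaller) empirical query motif space — trading one motif occurrence for a
reduction of the multiple-testing burden by orders of magnitude.

Result motifs with overlapping patterns and instances are grouped into
"clouds"; downstream assessment conventionally keeps only each cloud's
top-ranked member.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from . import __version__
from .seqdata import (
    MaskedSequence,
    ProteinRecord,
    QueryRegion,
    disorder_mask,
    no_mask,
)
from .slimbuild import (
    Motif,
    MotifSpace,
    Occurrence,
    PatternInfo,
    extend_ambiguity,
    enumerate_dataset_motifs,
    enumerate_query_motifs,
    find_occurrences,
)
from .slimchance import (
    ChanceInputs,
    aa_frequencies,
    score_motif,
    upc_site_count,
)
from .upc import UPCPartition, partition_dataset


class SearchError(ValueError):
    """Invalid search configuration or unusable dataset."""


@dataclass(frozen=True)
class SearchParams:
    """Configuration for one discovery run.

    ``max_defined``/``max_wildcard`` are the enumeration limits L and W;
    ``min_support`` is the minimum UPC support for a candidate;
    ``sig_cutoff`` the reporting threshold on the corrected significance.
    """

    mode: str = "slimfinder"  # "slimfinder" | "qslimfinder"
    max_defined: int = 5
    max_wildcard: int = 2
    min_support: int = 3
    sig_cutoff: float = 0.1
    ambiguity: bool = False
    cloudfix: bool = False
    dis_mask: bool = True
    disorder_threshold: float = 0.2
    min_region: int = 5
    evalue: float = 1e-4
    query: QueryRegion | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("slimfinder", "qslimfinder"):
            raise SearchError(f"unknown mode {self.mode!r}")
        if self.mode == "qslimfinder" and self.query is None:
            raise SearchError("query-restricted mode requires a query region")
        if not 0.0 < self.sig_cutoff <= 1.0:
            raise SearchError("sig_cutoff must be in (0, 1]")


@dataclass
class SLiMResult:
    """One scored motif with its support bookkeeping."""

    motif: Motif
    k: int
    n: int
    M: int
    p_site: float
    mean_p1: float
    prob: float
    sig: float
    occurrences: tuple[Occurrence, ...]
    mode: str
    rank: int | None = None
    cloud: int | None = None

    @property
    def pattern(self) -> str:
        return self.motif.pattern


@dataclass
class Cloud:
    """A connected group of result motifs with overlapping patterns/instances."""

    members: list[SLiMResult]
    representative: SLiMResult
    contains_fixed_significant: bool


@dataclass
class SearchResult:
    """Everything a discovery run produced."""

    params: SearchParams
    partition: UPCPartition
    results: list[SLiMResult]  # significant, ranked
    clouds: list[Cloud]
    all_scored: list[SLiMResult]  # every candidate, unfiltered
    aa_freqs: dict[str, float]
    n_upc: int

    @property
    def top_cloud(self) -> Cloud | None:
        return self.clouds[0] if self.clouds else None


def _result_key(r: SLiMResult) -> tuple:
    # Sig ascending; ties: higher support, longer pattern, lexicographic.
    return (r.sig, -r.k, -r.motif.defined_length, r.pattern)


def mask_dataset(
    records: Sequence[ProteinRecord], params: SearchParams
) -> dict[str, MaskedSequence]:
    masked = {}
    for r in records:
        if params.dis_mask and r.disorder is not None:
            masked[r.id] = disorder_mask(
                r, params.disorder_threshold, params.min_region
            )
        else:
            masked[r.id] = no_mask(r)
    return masked


def _sub_pattern(a: Motif, b: Motif) -> bool:
    """True when ``a``'s defined positions appear as a contiguous slice of
    ``b``'s with identical gaps and compatible residue sets."""
    la, lb = a.defined_length, b.defined_length
    if la > lb:
        return False
    for off in range(lb - la + 1):
        if a.gaps != b.gaps[off : off + la - 1]:
            continue
        if all(a.positions[i] & b.positions[off + i] for i in range(la)):
            return True
    return False


def _shared_instances(a: SLiMResult, b: SLiMResult) -> int:
    """Number of ``a`` occurrences overlapping a ``b`` occurrence in the
    same protein."""
    by_protein: dict[str, list[Occurrence]] = {}
    for occ in b.occurrences:
        by_protein.setdefault(occ.protein_id, []).append(occ)
    shared = 0
    for occ in a.occurrences:
        for other in by_protein.get(occ.protein_id, ()):
            if occ.start <= other.end and other.start <= occ.end:
                shared += 1
                break
    return shared


def build_clouds(results: Sequence[SLiMResult]) -> list[Cloud]:
    """Group motifs whose patterns or instances overlap into clouds.

    Two motifs share an edge when one is a sub-pattern of the other or when
    at least two of their occurrences overlap in the same proteins; clouds
    are the connected components, ordered by their best member.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(results)))
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            a, b = results[i], results[j]
            if (
                _sub_pattern(a.motif, b.motif)
                or _sub_pattern(b.motif, a.motif)
                or _shared_instances(a, b) >= 2
            ):
                graph.add_edge(i, j)
    clouds = []
    for component in nx.connected_components(graph):
        members = sorted((results[i] for i in component), key=_result_key)
        fixed_sig = any(m.motif.is_fixed for m in members)
        clouds.append(Cloud(members, members[0], fixed_sig))
    clouds.sort(key=lambda c: _result_key(c.representative))
    return clouds


def apply_cloudfix(clouds: Iterable[Cloud]) -> list[Cloud]:
    """Drop clouds without a significant fixed-position member.

    Ambiguous patterns are prone to over-prediction in query-restricted
    searches; this filter keeps them only when a fixed pattern in the same
    cloud independently reaches significance.
    """
    return [c for c in clouds if c.contains_fixed_significant]


def _count_query_support(
    space: MotifSpace,
    masked: dict[str, MaskedSequence],
    counting_ids: Sequence[str],
    cluster_index: dict[str, int],
    min_support: int,
) -> dict[Motif, PatternInfo]:
    kept: dict[Motif, PatternInfo] = {}
    for motif in space.patterns:
        occurrences: list[Occurrence] = []
        support: set[int] = set()
        for rid in counting_ids:
            found = find_occurrences(motif, masked[rid])
            if found:
                occurrences.extend(found)
                support.add(cluster_index[rid])
        if len(support) >= min_support:
            kept[motif] = PatternInfo(tuple(occurrences), frozenset(support))
    return kept


def run_search(
    records: Sequence[ProteinRecord],
    params: SearchParams,
    edges: Iterable[tuple[str, str, float]] | None = None,
) -> SearchResult:
    """Run a full discovery pipeline on a dataset.

    Pipeline: disorder masking, UPC clustering, candidate enumeration
    (query-restricted or whole-dataset), UPC support counting, the
    three-cycle binomial statistics, significance filtering, cloud grouping
    and ranking.  With identical inputs and parameters the output is
    deterministic.
    """
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise SearchError("duplicate protein ids in dataset")
    masked = mask_dataset(records, params)
    if all(m.unmasked_count == 0 for m in masked.values()):
        raise SearchError("all residues masked; no searchable sequence")
    partition = partition_dataset(records, params.evalue, edges)

    L, W = params.max_defined, params.max_wildcard
    if params.mode == "qslimfinder":
        query = params.query
        assert query is not None
        if query.protein_id not in masked:
            raise SearchError(f"query protein {query.protein_id!r} not in dataset")
        qmask = masked[query.protein_id]
        if query.end > len(qmask.sequence):
            raise SearchError("query region extends beyond the query protein")
        region = qmask.masked_string[query.start - 1 : query.end]
        space = enumerate_query_motifs(region, L, W)
        query_upc = partition.cluster_of(query.protein_id)
        counting_clusters = [
            c for i, c in enumerate(partition.clusters) if i != query_upc
        ]
        if not counting_clusters:
            raise SearchError("no unrelated clusters beyond the query")
        cluster_index = {
            pid: ci
            for ci, cluster in enumerate(counting_clusters)
            for pid in cluster
        }
        counting_ids = [rid for rid in ids if rid in cluster_index]
        supported = _count_query_support(
            space, masked, counting_ids, cluster_index, params.min_support
        )
        space = MotifSpace("query", L, W, supported, space.sizes)
    else:
        counting_clusters = list(partition.clusters)
        cluster_index = partition.index()
        counting_ids = ids
        space = enumerate_dataset_motifs(
            [masked[rid] for rid in ids], partition, L, W, params.min_support
        )

    if params.ambiguity:
        space = extend_ambiguity(space)

    freqs = aa_frequencies([masked[rid] for rid in counting_ids])
    n_upc = len(counting_clusters)
    members_by_cluster = [
        [masked[pid] for pid in sorted(cluster)] for cluster in counting_clusters
    ]
    site_cache: dict[int, tuple[int, ...]] = {}

    all_scored: list[SLiMResult] = []
    for motif, info in space.patterns.items():
        span = motif.span
        if span not in site_cache:
            site_cache[span] = tuple(
                upc_site_count(members, span) for members in members_by_cluster
            )
        inputs = ChanceInputs(
            freqs, site_cache[span], info.support, n_upc,
            space.space_size(motif.defined_length),
        )
        scored = score_motif(motif, inputs)
        all_scored.append(
            SLiMResult(
                motif, info.support, n_upc, inputs.M, scored.p_site,
                scored.mean_p1, scored.prob, scored.sig, info.occurrences,
                params.mode,
            )
        )

    significant = sorted(
        (r for r in all_scored if r.sig <= params.sig_cutoff), key=_result_key
    )
    clouds = build_clouds(significant)
    if params.cloudfix:
        clouds = apply_cloudfix(clouds)
        keep = {id(m) for c in clouds for m in c.members}
        significant = [r for r in significant if id(r) in keep]
    for rank, result in enumerate(significant, start=1):
        result.rank = rank
    for ci, cloud in enumerate(clouds, start=1):
        for member in cloud.members:
            member.cloud = ci
    return SearchResult(
        params, partition, significant, clouds, all_scored, freqs, n_upc
    )


# ---------------------------------------------------------------------------
# output writers


def results_frame(search: SearchResult) -> pd.DataFrame:
    rows = [
        {
            "rank": r.rank,
            "pattern": r.pattern,
            "length": r.motif.defined_length,
            "support": r.k,
            "n_upc": r.n,
            "p_site": r.p_site,
            "mean_p1": r.mean_p1,
            "prob": r.prob,
            "sig": r.sig,
            "mode": r.mode,
            "motif_space": r.M,
            "cloud": r.cloud,
        }
        for r in search.results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "pattern", "length", "support", "n_upc", "p_site",
            "mean_p1", "prob", "sig", "mode", "motif_space", "cloud",
        ],
    )


def occurrences_frame(search: SearchResult) -> pd.DataFrame:
    rows = [
        {
            "pattern": r.pattern,
            "protein": occ.protein_id,
            "start": occ.start,
            "end": occ.end,
            "match": occ.match,
        }
        for r in search.results
        for occ in r.occurrences
    ]
    return pd.DataFrame(
        rows, columns=["pattern", "protein", "start", "end", "match"]
    )


def dataset_digest(records: Sequence[ProteinRecord]) -> str:
    h = hashlib.sha256()
    for r in records:
        h.update(f"{r.id}:{r.sequence}\n".encode())
    return h.hexdigest()


def write_outputs(
    search: SearchResult,
    records: Sequence[ProteinRecord],
    outdir: str | Path,
) -> None:
    """Write results.tsv, occurrences.tsv and a re-runnable manifest/log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results_frame(search).to_csv(outdir / "results.tsv", sep="\t", index=False)
    occurrences_frame(search).to_csv(
        outdir / "occurrences.tsv", sep="\t", index=False
    )
    params = search.params
    manifest = {
        "version": __version__,
        "mode": params.mode,
        "max_defined": params.max_defined,
        "max_wildcard": params.max_wildcard,
        "min_support": params.min_support,
        "sig_cutoff": params.sig_cutoff,
        "ambiguity": params.ambiguity,
        "cloudfix": params.cloudfix,
        "dis_mask": params.dis_mask,
        "disorder_threshold": params.disorder_threshold,
        "min_region": params.min_region,
        "evalue": params.evalue,
        "seed": params.seed,
        "query": (
            {
                "protein_id": params.query.protein_id,
                "start": params.query.start,
                "end": params.query.end,
                "strategy": params.query.strategy,
            }
            if params.query
            else None
        ),
        "n_records": len(records),
        "n_upc": search.partition.n,
        "input_sha256": dataset_digest(records),
        "n_significant": len(search.results),
        "n_clouds": len(search.clouds),
    }
    (outdir / "run.json").write_text(json.dumps(manifest, indent=2) + "\n")
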