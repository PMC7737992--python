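"""Unified enhancer catalog: ID assignment, overlap clustering, source statistics.

The catalog keeps every record from every source — overlapping and even
coordinate-identical entries from different sources remain distinct entries,
because each source's calling pipeline is treated as independent evidence that
a region is an enhancer. ENCODE cCRE records keep their native alphanumeric
IDs; all other records get sequential numeric string IDs assigned in
(chrom, start, end, source) order.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx

from .genomic_core import (
    GenomicInterval,
    IntervalIndex,
    ParameterError,
    ValidationError,
    overlap_bp,
    reciprocal_or,
)
from .records import SourcedEnhancerRecord

__all__ = [
    "CatalogEntry",
    "EnhancerCatalog",
    "SourceOverlapMatrix",
    "CatalogComparison",
    "assemble_catalog",
    "cluster_enhancers",
    "source_overlap_matrix",
    "compare_catalogs",
]


@dataclass(frozen=True)
class CatalogEntry:
    enhancer_id: str
    interval: GenomicInterval
    source: str

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class EnhancerCatalog:
    """The assembled enhancer set with unique IDs and optional clustering."""

    enhancers: List[CatalogEntry]
    clusters: Optional[Dict[str, int]] = None
    merged_regions: Optional[List[GenomicInterval]] = None

    def __post_init__(self) -> None:
        ids = [e.enhancer_id for e in self.enhancers]
        if len(ids) != len(set(ids)):
            raise ValidationError("enhancer IDs are not unique across the catalog")
        self._by_id = {e.enhancer_id: e for e in self.enhancers}

    def __len__(self) -> int:
        return len(self.enhancers)

    def __getitem__(self, enhancer_id: str) -> CatalogEntry:
        return self._by_id[enhancer_id]

    def __contains__(self, enhancer_id: str) -> bool:
        return enhancer_id in self._by_id

    def index(self) -> IntervalIndex[CatalogEntry]:
        return IntervalIndex.from_pairs((e.interval, e) for e in self.enhancers)

    def sources(self) -> List[str]:
        seen: List[str] = []
        for e in self.enhancers:
            if e.source not in seen:
                seen.append(e.source)
        return seen


@dataclass
class SourceOverlapMatrix:
    """Row source x column source overlap counts at the 1-bp threshold.

    Cell (r, c) counts row-source enhancers sharing >= 1 bp with at least one
    column-source enhancer (each counted once however many partners it has);
    the diagonal is the per-source total, i.e. 100%.
    """

    sources: List[str]
    counts: Dict[Tuple[str, str], int]
    percentages: Dict[Tuple[str, str], float]


@dataclass
class CatalogComparison:
    """Two-catalog overlap report under a stated overlap mode."""

    mode: str
    n_A: int
    n_B: int
    n_A_overlapping_B: int
    n_B_overlapping_A: int
    clusters_A: int
    clusters_B: int
    mean_len_A: int
    mean_len_B: int
    mean_cluster_len_A: int
    mean_cluster_len_B: int


def assemble_catalog(records: Sequence[SourcedEnhancerRecord]) -> EnhancerCatalog:
    """Assign IDs and build the catalog; no deduplication or filtering.

    ENCODE records must carry native IDs and keep them; every other record
    receives the next numeric string ID in (chrom, start, end, source) sort
    order, starting at "1".
    """
    encode_ids = [r.native_id for r in records if r.source == "ENCODE"]
    if any(i is None for i in encode_ids):
        raise ValidationError("ENCODE enhancer records must carry native IDs")
    if len(encode_ids) != len(set(encode_ids)):
        raise ValidationError("duplicate native IDs within the ENCODE input")
    taken = set(encode_ids)

    others = [r for r in records if r.source != "ENCODE"]
    others.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.source))
    next_id = 1
    assigned: Dict[int, str] = {}
    for r in others:
        sid = str(next_id)
        if sid in taken:
            raise ValidationError(f"numeric ID {sid} collides with a native ENCODE ID")
        assigned[id(r)] = sid
        next_id += 1

    entries = []
    for r in records:
        if r.source == "ENCODE":
            entries.append(CatalogEntry(r.native_id, r.interval, r.source))
        else:
            entries.append(CatalogEntry(assigned[id(r)], r.interval, r.source))
    return EnhancerCatalog(entries)


def cluster_enhancers(
    catalog: EnhancerCatalog, min_overlap_bp: int = 1
) -> Tuple[Dict[str, int], List[GenomicInterval]]:
    """Connected components under the >= min_overlap_bp overlap relation.

    Returns (enhancer_id -> cluster_id, merged regions). Cluster IDs number
    the components 0.. in (chrom, start) order of their merged regions, which
    are the per-cluster coordinate unions (contiguous by connectivity) and are
    pairwise non-overlapping. Book-ended intervals share 0 bases and are not
    merged.
    """
    if min_overlap_bp < 1:
        raise ParameterError("min_overlap_bp must be >= 1")

    graph = nx.Graph()
    graph.add_nodes_from(e.enhancer_id for e in catalog.enhancers)
    index = catalog.index()
    for e in catalog.enhancers:
        for _, other in index.query(e.interval):
            if other.enhancer_id == e.enhancer_id:
                continue
            if overlap_bp(e.interval, other.interval) >= min_overlap_bp:
                graph.add_edge(e.enhancer_id, other.enhancer_id)

    components = []
    for comp in nx.connected_components(graph):
        ivs = [catalog[eid].interval for eid in comp]
        merged = GenomicInterval(
            ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs)
        )
        components.append((merged, sorted(comp)))
    components.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))

    clusters: Dict[str, int] = {}
    merged_regions: List[GenomicInterval] = []
    for cid, (merged, members) in enumerate(components):
        merged_regions.append(merged)
        for eid in members:
            clusters[eid] = cid
    return clusters, merged_regions


def source_overlap_matrix(catalog: EnhancerCatalog) -> SourceOverlapMatrix:
    """Pairwise source overlap counts at the minimum 1-bp threshold."""
    sources = catalog.sources()
    if not sources:
        raise ValidationError("catalog has no sources")
    by_source: Dict[str, List[CatalogEntry]] = defaultdict(list)
    for e in catalog.enhancers:
        by_source[e.source].append(e)
    indexes = {
        s: IntervalIndex.from_pairs((e.interval, e) for e in by_source[s]) for s in sources
    }

    counts: Dict[Tuple[str, str], int] = {}
    percentages: Dict[Tuple[str, str], float] = {}
    for r in sources:
        total = len(by_source[r])
        for c in sources:
            if r == c:
                n = total
            else:
                idx = indexes[c]
                n = sum(1 for e in by_source[r] if idx.query(e.interval))
            counts[(r, c)] = n
            percentages[(r, c)] = n / total
    return SourceOverlapMatrix(sources, counts, percentages)


def _mean_len(intervals: Sequence[GenomicInterval]) -> int:
    if not intervals:
        return 0
    return round(sum(iv.length for iv in intervals) / len(intervals))


def compare_catalogs(
    cat_a: EnhancerCatalog, cat_b: EnhancerCatalog, mode: str = "any_1bp"
) -> CatalogComparison:
    """Cross-catalog overlap counts, cluster counts, and mean lengths.

    ``any_1bp`` counts an enhancer as overlapping when it shares >= 1 bp with
    any element of the other catalog; ``either_50pct`` requires at least half
    of one of the two elements to be covered by the other.
    """
    if mode not in ("any_1bp", "either_50pct"):
        raise ParameterError(f"unknown comparison mode {mode!r}")

    def count_overlapping(cat_x: EnhancerCatalog, cat_y: EnhancerCatalog) -> int:
        idx = cat_y.index()
        n = 0
        for e in cat_x.enhancers:
            hits = idx.query(e.interval)
            if mode == "any_1bp":
                ok = bool(hits)
            else:
                ok = any(reciprocal_or(e.interval, h.interval, 0.5) for _, h in hits)
            n += ok
        return n

    clusters_a, merged_a = cluster_enhancers(cat_a) if len(cat_a) else ({}, [])
    clusters_b, merged_b = cluster_enhancers(cat_b) if len(cat_b) else ({}, [])

    return CatalogComparison(
        mode=mode,
        n_A=len(cat_a),
        n_B=len(cat_b),
        n_A_overlapping_B=count_overlapping(cat_a, cat_b) if len(cat_b) else 0,
        n_B_overlapping_A=count_overlapping(cat_b, cat_a) if len(cat_a) else 0,
        clusters_A=len(merged_a),
        clusters_B=len(merged_b),
        mean_len_A=_mean_len([e.interval for e in cat_a.enhancers]),
        mean_len_B=_mean_len([e.interval for e in cat_b.enhancers]),
        mean_cluster_len_A=_mean_len(merged_a),
        mean_cluster_len_B=_mean_len(merged_b),
    )
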