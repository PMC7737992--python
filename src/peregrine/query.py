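"""Variant / gene / enhancer queries over a built catalog and link database."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .enhancer_assembly import EnhancerCatalog
from .evidence_store import LinkDB
from .io_formats import read_vcf_positions
from .records import EvidenceRecord

__all__ = ["QueryResult", "query_variants", "query_gene", "query_enhancer"]


@dataclass
class QueryResult:
    """Hits for one query, deterministically ordered by (enhancer_id, gene_id)."""

    query_kind: str  # variant | gene | enhancer
    key: str
    hits: List[Tuple[str, str, Tuple[EvidenceRecord, ...]]] = field(default_factory=list)
    notice: Optional[str] = None

    def __post_init__(self) -> None:
        self.hits.sort(key=lambda h: (h[0], h[1]))

    @property
    def found(self) -> bool:
        return bool(self.hits)


def query_variants(
    vcf_path, catalog: EnhancerCatalog, linkdb: LinkDB
) -> List[QueryResult]:
    """Map each VCF variant to containing enhancers and their linked genes.

    The variant's POS (single anchoring base, converted to 0-based) is tested
    for containment in every catalog enhancer; each containing enhancer
    expands to its links. Variants hitting no enhancer come back with an
    "unmapped" notice and no hits.
    """
    enh_index = catalog.index()
    by_enh: Dict[str, List[Tuple[str, str]]] = defaultdict(list)
    for enh, gene in linkdb.links:
        by_enh[enh].append((enh, gene))

    results = []
    for vid, point in read_vcf_positions(vcf_path):
        hits = []
        for _, entry in enh_index.query(point):
            for enh, gene in by_enh.get(entry.enhancer_id, []):
                hits.append((enh, gene, linkdb.evidence[(enh, gene)]))
        results.append(
            QueryResult(
                "variant",
                vid,
                hits,
                notice=None if hits else "variant maps to no enhancer-gene link",
            )
        )
    return results


def query_gene(gene_id: str, linkdb: LinkDB) -> QueryResult:
    """All enhancers linked to one gene, with per-evidence detail."""
    hits = [
        (enh, gene, linkdb.evidence[(enh, gene)])
        for enh, gene in linkdb.links
        if gene == gene_id
    ]
    return QueryResult(
        "gene", gene_id, hits, notice=None if hits else f"gene {gene_id} has no links"
    )


def query_enhancer(
    enhancer_id: str, linkdb: LinkDB, catalog: Optional[EnhancerCatalog] = None
) -> QueryResult:
    """All genes linked to one enhancer; coordinates/source when a catalog is given."""
    hits = [
        (enh, gene, linkdb.evidence[(enh, gene)])
        for enh, gene in linkdb.links
        if enh == enhancer_id
    ]
    notice = None
    if not hits:
        notice = f"enhancer {enhancer_id} has no links"
    elif catalog is not None and enhancer_id in catalog:
        entry = catalog[enhancer_id]
        notice = f"{entry.interval} source={entry.source}"
    return QueryResult("enhancer", enhancer_id, hits, notice=notice)
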