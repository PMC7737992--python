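"""The four evidence-specific enhancer-gene linking procedures.

Each linker turns one assay's records into :class:`CandidateLink`s against an
assembled enhancer catalog and a set of protein-coding gene models:

* ChIA-PET: an interaction pair links every enhancer reciprocally-overlapping
  (>= 50% of either element) one anchor to every gene whose promoter
  reciprocally-overlaps the other anchor, when the interaction p-value is
  significant. Both anchor orientations are screened; an enhancer and a
  promoter sharing a single anchor do not link through that anchor alone.
* eQTL: a significant, non-exonic variant sitting inside an enhancer links
  that enhancer to the gene whose expression the variant is associated with.
* Hierarchical TAD: an enhancer at least 90% contained in a region called as
  interacting with a gene's promoter (FDR-filtered) links to that gene.
* Linear TAD: the cross product of enhancers and promoters at least 90%
  contained in the same TAD — candidates only, retained solely for pairs
  already supported by another assay (:func:`condition_tad_links`).

Significance cutoffs are strict (p < alpha, FDR < 0.01); geometric thresholds
are inclusive (>= 50%, >= 90%). The promoter is the TSS plus the 600 bp
immediately upstream of it, 601 bp in total, strand-aware.

Only protein-coding genes are ever linked; linkers that receive gene models
filter on ``coding`` themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .enhancer_assembly import EnhancerCatalog
from .genomic_core import (
    GenomicInterval,
    IntervalIndex,
    ParameterError,
    ValidationError,
    contained_fraction,
    point_in,
    reciprocal_or,
)
from .records import (
    CandidateLink,
    ChiaPetPair,
    EqtlRecord,
    EvidenceRecord,
    GeneModel,
    HierTadRecord,
    TadRecord,
)

log = logging.getLogger(__name__)

__all__ = [
    "PromoterWindow",
    "CandidateLink",
    "EvidenceRecord",
    "derive_promoter",
    "derive_promoters",
    "link_chiapet",
    "link_eqtl",
    "link_hier_tad",
    "link_tad",
    "condition_tad_links",
]

PROMOTER_UPSTREAM_BP = 600


@dataclass(frozen=True)
class PromoterWindow:
    """The strand-aware 601-bp window anchored at a gene's TSS.

    Contains the TSS base and the 600 bp upstream of it; shorter only when
    clipped at the chromosome start.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str


def derive_promoter(gene: GeneModel) -> PromoterWindow:
    """TSS plus the preceding (upstream) 600 bp.

    Plus strand, TSS at 0-based t: [t-600, t+1). Minus strand: [t, t+601).
    Clipped at position 0 with a warning when the TSS sits within 600 bp of
    the chromosome start on the plus strand.
    """
    t = gene.tss.pos
    if gene.strand == "+":
        start, end = t - PROMOTER_UPSTREAM_BP, t + 1
        if start < 0:
            log.warning(
                "promoter of %s clipped at chromosome start (TSS at %d)", gene.gene_id, t
            )
            start = 0
    else:
        start, end = t, t + PROMOTER_UPSTREAM_BP + 1
    return PromoterWindow(gene.gene_id, GenomicInterval(gene.chrom, start, end), gene.strand)


def derive_promoters(genes: Iterable[GeneModel], coding_only: bool = True) -> List[PromoterWindow]:
    """Promoter windows for (by default) the protein-coding genes only."""
    return [derive_promoter(g) for g in genes if g.coding or not coding_only]


def _reciprocal_hits(
    index: IntervalIndex, anchor: GenomicInterval, t: float
) -> List[Tuple[GenomicInterval, object]]:
    """Index payloads whose interval reciprocally-overlaps the anchor at threshold t."""
    return [
        (iv, payload)
        for iv, payload in index.query(anchor)
        if reciprocal_or(iv, anchor, t)
    ]


def link_chiapet(
    pairs: Sequence[ChiaPetPair],
    catalog: EnhancerCatalog,
    promoters: Sequence[PromoterWindow],
    alpha: float = 0.05,
    t: float = 0.5,
) -> List[CandidateLink]:
    """Enhancer-promoter links through significant ChIA-PET interactions.

    For each pair with p < alpha, both anchor orientations are screened:
    enhancers in one anchor x promoters in the other. Duplicate
    (enhancer, gene, cell type) candidates arising from one pair (e.g. via
    both orientations) collapse to a single record keeping the minimum p.
    """
    enh_index = catalog.index()
    prom_index = IntervalIndex.from_pairs((p.interval, p) for p in promoters)

    best: Dict[Tuple[str, str, str], float] = {}
    for pair in pairs:
        if not (pair.p_value < alpha):
            continue
        for anchor_e, anchor_p in ((pair.anchor1, pair.anchor2), (pair.anchor2, pair.anchor1)):
            enh_hits = _reciprocal_hits(enh_index, anchor_e, t)
            if not enh_hits:
                continue
            prom_hits = _reciprocal_hits(prom_index, anchor_p, t)
            for _, entry in enh_hits:
                for _, prom in prom_hits:
                    key = (entry.enhancer_id, prom.gene_id, pair.cell_type)
                    if key not in best or pair.p_value < best[key]:
                        best[key] = pair.p_value

    return [
        CandidateLink(
            enhancer_id=eid,
            gene_id=gid,
            evidence=EvidenceRecord(
                assay="CHIAPET", tissue=cell, score_type="p_value", score=p
            ),
        )
        for (eid, gid, cell), p in sorted(best.items())
    ]


def link_eqtl(
    eqtls: Sequence[EqtlRecord],
    catalog: EnhancerCatalog,
    genes: Sequence[GeneModel],
    alpha: float = 0.05,
) -> List[CandidateLink]:
    """Enhancer-gene links through significant eQTLs located inside enhancers.

    An eQTL is discarded when non-significant (p >= alpha), when its position
    falls inside any exon of its associated gene (the exonic-exclusion rule —
    exons of *other* genes do not exclude), when its gene is unknown, or when
    its gene is non-coding. A variant inside several overlapping enhancers
    links each of them.
    """
    by_id: Dict[str, GeneModel] = {g.gene_id: g for g in genes}
    enh_index = catalog.index()

    links: List[CandidateLink] = []
    for q in eqtls:
        if not (q.p_value < alpha):
            continue
        gene = by_id.get(q.gene_id)
        if gene is None:
            log.warning("eQTL %s references unknown gene %s; skipped", q.variant_id, q.gene_id)
            continue
        if not gene.coding:
            continue
        if any(point_in(q.position, ex) for ex in gene.exons):
            continue
        for _, entry in enh_index.query(q.position):
            links.append(
                CandidateLink(
                    enhancer_id=entry.enhancer_id,
                    gene_id=gene.gene_id,
                    evidence=EvidenceRecord(
                        assay="EQTL",
                        tissue=q.tissue,
                        score_type="p_value",
                        score=q.p_value,
                        eqtl_id=q.variant_id,
                    ),
                )
            )
    links.sort(key=lambda c: (c.enhancer_id, c.gene_id, c.evidence.sort_key()))
    return links


def link_hier_tad(
    calls: Sequence[HierTadRecord],
    catalog: EnhancerCatalog,
    fdr_max: float = 0.01,
    t: float = 0.9,
    genes: Optional[Sequence[GeneModel]] = None,
) -> List[CandidateLink]:
    """Links through promoter-interacting regions inside TADs.

    Every enhancer at least 90% contained in a region called (FDR < fdr_max)
    as interacting with a gene's promoter links to that gene. When gene
    models are supplied, calls naming unknown or non-coding genes are
    dropped.
    """
    coding: Optional[Set[str]] = None
    if genes is not None:
        coding = {g.gene_id for g in genes if g.coding}
    enh_index = catalog.index()

    links: List[CandidateLink] = []
    for call in calls:
        if not (call.fdr < fdr_max):
            continue
        if coding is not None and call.gene_id not in coding:
            continue
        for iv, entry in enh_index.query(call.region):
            if contained_fraction(iv, call.region, t):
                links.append(
                    CandidateLink(
                        enhancer_id=entry.enhancer_id,
                        gene_id=call.gene_id,
                        evidence=EvidenceRecord(
                            assay="HTAD",
                            tissue=call.cell_type,
                            score_type="fdr",
                            score=call.fdr,
                        ),
                    )
                )
    links.sort(key=lambda c: (c.enhancer_id, c.gene_id, c.evidence.sort_key()))
    return links


def link_tad(
    tads: Sequence[TadRecord],
    catalog: EnhancerCatalog,
    promoters: Sequence[PromoterWindow],
    t: float = 0.9,
) -> List[CandidateLink]:
    """Same-TAD candidates: enhancers x promoters >= 90% contained in one TAD.

    These are candidates only; same-TAD co-residence alone is weak evidence,
    so callers must pass the result through :func:`condition_tad_links` before
    aggregation.
    """
    enh_index = catalog.index()
    prom_index = IntervalIndex.from_pairs((p.interval, p) for p in promoters)

    links: List[CandidateLink] = []
    for tad in tads:
        enh_in = [
            entry
            for iv, entry in enh_index.query(tad.region)
            if contained_fraction(iv, tad.region, t)
        ]
        if not enh_in:
            continue
        genes_in = [
            prom.gene_id
            for iv, prom in prom_index.query(tad.region)
            if contained_fraction(iv, tad.region, t)
        ]
        for entry in enh_in:
            for gid in genes_in:
                links.append(
                    CandidateLink(
                        enhancer_id=entry.enhancer_id,
                        gene_id=gid,
                        evidence=EvidenceRecord(
                            assay="TAD", tissue=tad.cell_type, score_type="none"
                        ),
                    )
                )
    links.sort(key=lambda c: (c.enhancer_id, c.gene_id, c.evidence.sort_key()))
    return links


def condition_tad_links(
    tad_candidates: Sequence[CandidateLink],
    other_links: Sequence[CandidateLink],
) -> List[CandidateLink]:
    """Keep same-TAD candidates only for pairs already linked by another assay.

    ``other_links`` must come from the ChIA-PET / eQTL / hierarchical-TAD
    linkers; a TAD record among them would let TAD evidence support itself and
    is rejected. Tissue labels need not match across assays — support is at
    the (enhancer, gene) pair level.
    """
    for link in other_links:
        if link.evidence.assay == "TAD":
            raise ValidationError(
                "other_links contains TAD-assay records; TAD evidence cannot support itself"
            )
    supported: Set[Tuple[str, str]] = {(l.enhancer_id, l.gene_id) for l in other_links}
    return [c for c in tad_candidates if (c.enhancer_id, c.gene_id) in supported]
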