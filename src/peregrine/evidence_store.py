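"""Aggregation of candidate links into a deduplicated, queryable link database."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .genomic_core import GenomicInterval, ValidationError
from .records import ASSAYS, CandidateLink, EvidenceRecord

__all__ = ["LinkDB", "LinkSupport", "aggregate", "support_counts", "assay_combination_counts"]


@dataclass
class LinkDB:
    """Deduplicated (enhancer, gene) links with all attached evidence.

    Invariants: every link carries at least one evidence record, and a link
    carrying same-TAD evidence also carries evidence from another assay (the
    conditioning rule). ``coords`` optionally maps enhancer IDs to their
    catalog intervals for export and queries; ``provenance`` records run
    metadata (thresholds used, input labels).
    """

    evidence: Dict[Tuple[str, str], Tuple[EvidenceRecord, ...]]
    coords: Dict[str, GenomicInterval] = field(default_factory=dict)
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, evs in self.evidence.items():
            if not evs:
                raise ValidationError(f"link {pair} has no evidence")
            assays = {e.assay for e in evs}
            if assays == {"TAD"}:
                raise ValidationError(
                    f"link {pair} is supported by same-TAD evidence alone"
                )

    @classmethod
    def from_evidence(
        cls,
        evidence: Mapping[Tuple[str, str], Iterable[EvidenceRecord]],
        coords: Optional[Dict[str, GenomicInterval]] = None,
        provenance: Optional[Dict[str, object]] = None,
    ) -> "LinkDB":
        dedup = {
            pair: tuple(sorted(set(evs), key=EvidenceRecord.sort_key))
            for pair, evs in evidence.items()
        }
        return cls(dedup, coords=coords or {}, provenance=provenance or {})

    @property
    def links(self) -> Set[Tuple[str, str]]:
        return set(self.evidence.keys())

    def __len__(self) -> int:
        return len(self.evidence)

    def assays_of(self, pair: Tuple[str, str]) -> FrozenSet[str]:
        return frozenset(e.assay for e in self.evidence[pair])

    def comparable(self):
        """Canonical form for equality testing between independent builders."""
        return {pair: tuple(evs) for pair, evs in self.evidence.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinkDB):
            return NotImplemented
        return self.comparable() == other.comparable()


@dataclass(frozen=True)
class LinkSupport:
    """Per-link support breadth: distinct assays and distinct tissue labels."""

    link: Tuple[str, str]
    n_assays: int
    n_tissues: int


def aggregate(
    candidates: Sequence[CandidateLink],
    coords: Optional[Dict[str, GenomicInterval]] = None,
    provenance: Optional[Dict[str, object]] = None,
) -> LinkDB:
    """Union candidates from all linkers into a LinkDB.

    TAD candidates must already be conditioned; a pair supported by TAD alone
    fails construction. Evidence is deduplicated on the full record (assay,
    tissue, score_type, score, eqtl_id) and deterministically ordered, so the
    result is insensitive to candidate input order.
    """
    by_pair: Dict[Tuple[str, str], Set[EvidenceRecord]] = defaultdict(set)
    for c in candidates:
        by_pair[(c.enhancer_id, c.gene_id)].add(c.evidence)
    return LinkDB.from_evidence(by_pair, coords=coords, provenance=provenance)


def support_counts(linkdb: LinkDB) -> List[LinkSupport]:
    """Distinct-assay and pooled distinct-tissue counts per link.

    Tissue and cell-type labels from different assays pool into one label set
    (compared as exact trimmed strings, no ontology mapping).
    """
    out = []
    for pair in sorted(linkdb.links):
        evs = linkdb.evidence[pair]
        out.append(
            LinkSupport(
                link=pair,
                n_assays=len({e.assay for e in evs}),
                n_tissues=len({e.tissue.strip() for e in evs}),
            )
        )
    return out


def assay_combination_counts(linkdb: LinkDB) -> Dict[FrozenSet[str], int]:
    """Partition links by their exact supporting-assay set.

    Counts over the 15 non-empty subsets of {CHIAPET, EQTL, HTAD, TAD} sum to
    the number of links; the {TAD}-only cell is structurally forced to zero
    by the conditioning rule. Subsets with no links are reported as 0.
    """
    counts: Dict[FrozenSet[str], int] = {
        frozenset(sub): 0
        for r in range(1, len(ASSAYS) + 1)
        for sub in combinations(ASSAYS, r)
    }
    for pair in linkdb.links:
        counts[linkdb.assays_of(pair)] += 1
    return counts
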