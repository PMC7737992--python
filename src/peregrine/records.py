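"""Domain record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

from .genomic_core import GenomicInterval, StrandedPoint, ValidationError

ENHANCER_SOURCES = ("ENCODE", "Ensembl", "FANTOM", "VISTA", "other")

ASSAYS = ("CHIAPET", "EQTL", "HTAD", "TAD")


@dataclass(frozen=True)
class SourcedEnhancerRecord:
    """One enhancer call from one source catalog, pre-assembly."""

    interval: GenomicInterval
    source: str
    native_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source not in ENHANCER_SOURCES:
            raise ValidationError(
                f"unknown enhancer source {self.source!r}; expected one of {ENHANCER_SOURCES}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS and exon structure.

    Only ``coding=True`` genes ever receive links; the exons feed the eQTL
    exonic-exclusion rule, the TSS anchors the promoter window.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: StrandedPoint
    exons: Tuple[GenomicInterval, ...]
    coding: bool = True
    symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: exon list is empty")
        if self.tss.chrom != self.chrom:
            raise ValidationError(f"gene {self.gene_id}: TSS not on gene chromosome")
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValidationError(
                    f"gene {self.gene_id}: exon {ex} not on gene chromosome"
                )


def _check_probability(value: float, what: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{what} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class ChiaPetPair:
    """One significant-or-not ChIA-PET interaction: two anchors and a p-value."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    p_value: float
    cell_type: str

    def __post_init__(self) -> None:
        _check_probability(self.p_value, "ChIA-PET p-value")


@dataclass(frozen=True)
class EqtlRecord:
    """One tissue-specific eQTL: a variant associated with one gene's expression."""

    variant_id: str
    position: StrandedPoint
    gene_id: str
    tissue: str
    p_value: float

    def __post_init__(self) -> None:
        _check_probability(self.p_value, "eQTL p-value")


@dataclass(frozen=True)
class HierTadRecord:
    """A within-TAD region called as interacting with one gene's promoter."""

    region: GenomicInterval
    gene_id: str
    fdr: float
    cell_type: str

    def __post_init__(self) -> None:
        _check_probability(self.fdr, "hierarchical-TAD FDR")


@dataclass(frozen=True)
class TadRecord:
    """A topologically associated domain from one cell type."""

    region: GenomicInterval
    cell_type: str


@dataclass(frozen=True)
class EvidenceRecord:
    """One assay observation supporting one enhancer-gene pair."""

    assay: str
    tissue: str
    score_type: str  # p_value | fdr | none
    score: Optional[float] = None
    eqtl_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if self.assay == "EQTL":
            if self.eqtl_id is None or self.score_type != "p_value":
                raise ValidationError("EQTL evidence requires an eqtl_id and a p_value score")
        if self.assay == "HTAD" and self.score_type != "fdr":
            raise ValidationError("HTAD evidence carries an FDR score")
        if self.assay == "TAD" and self.score_type != "none":
            raise ValidationError("TAD evidence carries no score")
        if self.score is not None:
            _check_probability(self.score, "evidence score")
        if self.score_type not in ("p_value", "fdr", "none"):
            raise ValidationError(f"unknown score_type {self.score_type!r}")
        if (self.score is None) != (self.score_type == "none"):
            raise ValidationError("score and score_type must be consistent")

    def sort_key(self):
        return (
            self.assay,
            self.tissue,
            self.score_type,
            -1.0 if self.score is None else self.score,
            self.eqtl_id or "",
        )


@dataclass(frozen=True)
class CandidateLink:
    """One (enhancer, gene) pair proposed by one linker with its evidence."""

    enhancer_id: str
    gene_id: str
    evidence: EvidenceRecord
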