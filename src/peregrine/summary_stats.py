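"""Distribution tables, summary means, tissue binning and association tests.

Operates either on a live :class:`~peregrine.evidence_store.LinkDB` or on the
packaged machine-readable copies of the published per-source catalog summary
and genes-per-enhancer distribution tables (see :mod:`peregrine.tables`).

Percent summaries are rounded half-away-from-zero to the nearest integer
percent; mean lengths to the nearest bp; ratio means to 2 decimals — matching
how such tables are conventionally printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
from scipy import stats as sps

from .enhancer_assembly import EnhancerCatalog
from .evidence_store import LinkDB, LinkSupport
from .genomic_core import ParameterError, ValidationError
from .records import ASSAYS

__all__ = [
    "TargetDistribution",
    "CatalogSummaryTable",
    "AssociationResult",
    "round_half_away",
    "target_distribution",
    "distribution_summaries",
    "catalog_summary",
    "per_assay_means",
    "bin_tissue_counts",
    "assay_tissue_association",
    "export_gene_enhancer_counts",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (0.5 -> 1), unlike banker's rounding."""
    factor = 10**ndigits
    scaled = x * factor
    r = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return r / factor if ndigits else float(r)


@dataclass
class TargetDistribution:
    """Histogram of target-gene counts per linked enhancer with cumulative fractions."""

    rows: List[Tuple[int, int]]  # (k targets, number of enhancers)

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.rows]
        if ks != sorted(set(ks)):
            raise ValidationError("distribution rows must have strictly increasing k")
        if any(n < 0 for _, n in self.rows):
            raise ValidationError("enhancer counts must be non-negative")

    @property
    def total_enhancers(self) -> int:
        return sum(n for _, n in self.rows)

    @property
    def total_links(self) -> int:
        return sum(k * n for k, n in self.rows)

    def cumulative_fractions(self) -> List[Tuple[int, float]]:
        total = self.total_enhancers
        out, running = [], 0
        for k, n in self.rows:
            running += n
            out.append((k, running / total))
        return out

    def cumulative_fraction_at(self, k: int) -> float:
        """Fraction of linked enhancers with at most k target genes."""
        total = self.total_enhancers
        return sum(n for kk, n in self.rows if kk <= k) / total


@dataclass
class CatalogSummaryTable:
    """Per-source enhancer counts and mean lengths (published-summary shape)."""

    rows: List[Tuple[str, int, float]]  # (source, n_enhancers, mean_length_bp)

    def __post_init__(self) -> None:
        if any(n < 0 for _, n, _ in self.rows):
            raise ValidationError("per-source counts must be non-negative")


@dataclass
class AssociationResult:
    """Chi-squared independence test plus Pearson correlation for support breadth."""

    chi2: float
    df: int
    p: float
    pearson_r: float
    pearson_p: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValidationError("chi-squared degrees of freedom must be >= 1")


def target_distribution(linkdb: LinkDB) -> TargetDistribution:
    """Genes-per-enhancer histogram over enhancers with at least one link."""
    genes_per_enh: Dict[str, set] = {}
    for enh, gene in linkdb.links:
        genes_per_enh.setdefault(enh, set()).add(gene)
    counts = pd.Series([len(gs) for gs in genes_per_enh.values()], dtype=int)
    if counts.empty:
        return TargetDistribution([])
    vc = counts.value_counts().sort_index()
    return TargetDistribution([(int(k), int(n)) for k, n in vc.items()])


@dataclass
class DistributionSummary:
    total_enhancers: int
    total_links: int
    mean_genes_per_enhancer: float
    mean_enhancers_per_gene: Optional[float]

    def pct_with_k_or_fewer(self, dist: "TargetDistribution", k: int) -> int:
        return int(round_half_away(100 * dist.cumulative_fraction_at(k)))


def distribution_summaries(
    dist: TargetDistribution, n_genes: Optional[int] = None
) -> DistributionSummary:
    """Totals and per-enhancer / per-gene means from a target distribution.

    ``mean_enhancers_per_gene`` needs the number of linked genes, which the
    distribution itself does not determine; it is reported only when
    ``n_genes`` is supplied. Means are rounded to 2 decimals.
    """
    total = dist.total_enhancers
    if total == 0:
        raise ValidationError("distribution is empty")
    links = dist.total_links
    return DistributionSummary(
        total_enhancers=total,
        total_links=links,
        mean_genes_per_enhancer=round_half_away(links / total, 2),
        mean_enhancers_per_gene=(
            round_half_away(links / n_genes, 2) if n_genes else None
        ),
    )


def catalog_summary(
    catalog: Union[EnhancerCatalog, CatalogSummaryTable],
) -> Tuple[int, int]:
    """Total enhancer count and count-weighted mean length (whole bp).

    Accepts either a live catalog (per-source means computed from intervals)
    or a pre-summarized per-source table.
    """
    if isinstance(catalog, EnhancerCatalog):
        if not len(catalog):
            raise ValidationError("catalog is empty")
        rows: List[Tuple[str, int, float]] = []
        for src in catalog.sources():
            lens = [e.length for e in catalog.enhancers if e.source == src]
            rows.append((src, len(lens), sum(lens) / len(lens)))
    else:
        rows = catalog.rows
    total = sum(n for _, n, _ in rows)
    if total == 0:
        raise ValidationError("summary table has zero enhancers")
    weighted = sum(n * m for _, n, m in rows) / total
    return total, int(round_half_away(weighted))


def per_assay_means(linkdb: LinkDB) -> pd.DataFrame:
    """Mean genes per enhancer and mean enhancers per gene, by supporting assay.

    For each assay, the link set restricts to links with at least one evidence
    record of that assay; a link therefore contributes to every assay that
    supports it. Assays absent from the DB are omitted.
    """
    rows = []
    for assay in ASSAYS:
        pairs = [p for p in linkdb.links if assay in linkdb.assays_of(p)]
        if not pairs:
            continue
        df = pd.DataFrame(pairs, columns=["enhancer_id", "gene_id"])
        genes_per_enh = df.groupby("enhancer_id")["gene_id"].nunique().mean()
        enh_per_gene = df.groupby("gene_id")["enhancer_id"].nunique().mean()
        rows.append(
            (
                assay,
                round_half_away(float(genes_per_enh), 2),
                round_half_away(float(enh_per_gene), 2),
            )
        )
    return pd.DataFrame(
        rows, columns=["assay", "mean_genes_per_enhancer", "mean_enhancers_per_gene"]
    )


def bin_tissue_counts(
    supports: Sequence[LinkSupport], width: int = 5, merge_top: bool = True
) -> List[str]:
    """Bin per-link tissue counts into [1-5], [6-10], ... groups.

    With ``merge_top``, observations above the upper edge of the last bin that
    is full (i.e. whose range is entirely <= the observed maximum) are merged
    into that bin — e.g. a single 71 with bins up to [66-70] is labelled
    "66-70".
    """
    if width < 1:
        raise ParameterError("bin width must be >= 1")
    counts = [s.n_tissues for s in supports]
    if any(c < 1 for c in counts):
        raise ValidationError("tissue counts must be >= 1")
    mx = max(counts, default=0)
    # upper edge of the last *complete* bin at or below the maximum
    n_full = mx // width
    labels = []
    for c in counts:
        b = (c - 1) // width  # bin index
        if merge_top and n_full >= 1 and b >= n_full:
            b = n_full - 1
        lo, hi = b * width + 1, (b + 1) * width
        labels.append(f"{lo}-{hi}")
    return labels


def assay_tissue_association(
    supports: Sequence[LinkSupport], width: int = 5, binned_pearson: bool = False
) -> AssociationResult:
    """Association between tissue breadth and assay breadth over links.

    Chi-squared test of independence (Pearson statistic, no continuity
    correction, no pooling) on the binned-tissue-count x assay-count
    contingency table, plus the Pearson correlation between the raw
    (unbinned, unless ``binned_pearson``) tissue counts and assay counts.
    """
    if len(supports) < 2:
        raise ValidationError("need at least 2 links")
    tissues = [s.n_tissues for s in supports]
    assays = [s.n_assays for s in supports]
    labels = bin_tissue_counts(supports, width=width)
    table = pd.crosstab(pd.Series(labels, name="tissue_bin"), pd.Series(assays, name="n_assays"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError(
            "degenerate contingency table: need >= 2 distinct values on each axis"
        )
    chi2, p, df, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
    if binned_pearson:
        x = [int(l.split("-")[0]) for l in labels]
    else:
        x = tissues
    r, rp = sps.pearsonr(x, assays)
    return AssociationResult(chi2=float(chi2), df=int(df), p=float(p), pearson_r=float(r), pearson_p=float(rp))


def export_gene_enhancer_counts(linkdb: LinkDB, path) -> pd.DataFrame:
    """Write (gene_id, n_linked_enhancers) sorted by gene — input for external
    gene-set enrichment."""
    per_gene: Dict[str, set] = {}
    for enh, gene in linkdb.links:
        per_gene.setdefault(gene, set()).add(enh)
    df = pd.DataFrame(
        sorted((g, len(es)) for g, es in per_gene.items()),
        columns=["gene_id", "n_linked_enhancers"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
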