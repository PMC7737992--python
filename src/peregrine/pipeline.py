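"""End-to-end convenience: files in, aggregated LinkDB out."""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence

from .enhancer_assembly import EnhancerCatalog, assemble_catalog
from .evidence_store import LinkDB, aggregate
from .io_formats import (
    read_chiapet_bedpe,
    read_enhancer_bed,
    read_eqtl_table,
    read_gene_models,
    read_hier_tad_table,
    read_tad_bed,
)
from .linkers import (
    condition_tad_links,
    derive_promoters,
    link_chiapet,
    link_eqtl,
    link_hier_tad,
    link_tad,
)
from .records import GeneModel, SourcedEnhancerRecord

__all__ = ["build_catalog_from_files", "build_linkdb"]

DEFAULT_THRESHOLDS = {
    "chiapet_alpha": 0.05,
    "chiapet_min_frac": 0.5,
    "eqtl_alpha": 0.05,
    "htad_fdr_max": 0.01,
    "tad_min_frac": 0.9,
}


def build_catalog_from_files(source_paths: Mapping[str, str]) -> EnhancerCatalog:
    """Assemble a catalog from {source_label: bed_path} inputs."""
    records: List[SourcedEnhancerRecord] = []
    for source, path in source_paths.items():
        records.extend(read_enhancer_bed(path, source))
    return assemble_catalog(records)


def build_linkdb(
    catalog: EnhancerCatalog,
    genes: Sequence[GeneModel],
    chiapet_path: Optional[str] = None,
    eqtl_path: Optional[str] = None,
    hier_tad_path: Optional[str] = None,
    tad_path: Optional[str] = None,
    thresholds: Optional[Dict[str, float]] = None,
) -> LinkDB:
    """Run every linker whose input file is present, condition the same-TAD
    candidates on the rest, and aggregate."""
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    promoters = derive_promoters(genes)

    other = []
    if chiapet_path:
        other += link_chiapet(
            read_chiapet_bedpe(chiapet_path),
            catalog,
            promoters,
            alpha=th["chiapet_alpha"],
            t=th["chiapet_min_frac"],
        )
    if eqtl_path:
        other += link_eqtl(read_eqtl_table(eqtl_path), catalog, genes, alpha=th["eqtl_alpha"])
    if hier_tad_path:
        other += link_hier_tad(
            read_hier_tad_table(hier_tad_path),
            catalog,
            fdr_max=th["htad_fdr_max"],
            t=th["tad_min_frac"],
            genes=genes,
        )

    candidates = list(other)
    if tad_path:
        tad_cand = link_tad(read_tad_bed(tad_path), catalog, promoters, t=th["tad_min_frac"])
        candidates += condition_tad_links(tad_cand, other)

    coords = {e.enhancer_id: e.interval for e in catalog.enhancers}
    return aggregate(candidates, coords=coords, provenance={"thresholds": th})
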