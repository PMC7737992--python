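"""Seeded synthetic scenarios and an exhaustive-rule oracle.

A scenario is a miniature genome laid out in non-interacting 100-kb blocks:
each planted enhancer-gene link lives in its own block, with evidence records
constructed to *pass* every rule of the corresponding assay (significant
p-values, reciprocal >= 50% anchor overlaps, non-exonic in-enhancer variants,
>= 90% containments). Decoy records each fail exactly one rule — a 49% anchor
overlap, a p-value exactly at the 0.05 boundary, an exonic variant, an 89%
containment, an FDR exactly at 0.01, a same-TAD pair with no other support,
and a variant whose target gene is non-coding — so the expected link set is
exactly the planted one.

The block layout keeps anchors, TADs and regions from straddling unrelated
entities, so the truth table is exact by construction; the
:func:`oracle_links` function independently recomputes the expected link
database by brute-force all-pairs application of the rules (no interval
index, thresholds hard-coded as integer comparisons) for equivalence testing
against the pipeline.

All randomness flows from a single ``numpy`` generator keyed by the seed;
sub-generators draw in a fixed order (genome layout, then per-block evidence,
then decoys), so regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .genomic_core import GenomicInterval, StrandedPoint
from .records import (
    ChiaPetPair,
    EqtlRecord,
    EvidenceRecord,
    GeneModel,
    HierTadRecord,
    SourcedEnhancerRecord,
    TadRecord,
)

__all__ = ["ScenarioConfig", "Scenario", "generate_scenario", "write_scenario", "oracle_links"]

BLOCK_BP = 100_000

DECOY_CLASSES = (
    "chiapet_sub50_overlap",
    "chiapet_boundary_p",
    "eqtl_exonic",
    "eqtl_boundary_p",
    "eqtl_noncoding_gene",
    "htad_89_containment",
    "htad_boundary_fdr",
    "tad_only_pair",
)

_CELL_TYPES = ("K562", "MCF7", "HCT116")
_TISSUES = ("Liver", "Lung", "Whole_Blood", "Brain_Cortex", "Muscle_Skeletal")
_TAD_CELLS = ("GM12878", "IMR90", "HUVEC")
_SOURCES = ("ENCODE", "Ensembl", "FANTOM", "VISTA")


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults give a small many-block genome with a dozen planted links whose
    assay sets are drawn uniformly from the admissible combinations (same-TAD
    evidence only ever alongside another assay), one decoy of every class, and
    a handful of unlinked genes and enhancers as background.
    """

    seed: int = 0
    n_links: int = 12
    n_extra_genes: int = 4
    n_extra_enhancers: int = 8
    decoy_classes: Tuple[str, ...] = DECOY_CLASSES
    tad_probability: float = 0.5  # chance a planted link also gets same-TAD evidence
    chrom: str = "chrS"


@dataclass
class Scenario:
    """In-memory synthetic inputs plus the planted truth."""

    config: ScenarioConfig
    genome: List[Tuple[str, int]]
    enhancer_records: Dict[str, List[SourcedEnhancerRecord]]  # source -> records
    genes: List[GeneModel]
    chiapet: List[ChiaPetPair]
    eqtls: List[EqtlRecord]
    hier_tads: List[HierTadRecord]
    tads: List[TadRecord]
    truth: Dict[Tuple[str, str], FrozenSet[str]]  # (enhancer_id, gene_id) -> assays


def _expected_ids(records_by_source: Dict[str, List[SourcedEnhancerRecord]]) -> Dict[int, str]:
    """Catalog IDs under the assembly contract, keyed by id() of the record.

    ENCODE records keep native IDs; others get sequential numeric strings in
    (chrom, start, end, source) order starting at "1".
    """
    out: Dict[int, str] = {}
    others = []
    for source, records in records_by_source.items():
        for r in records:
            if source == "ENCODE":
                out[id(r)] = r.native_id
            else:
                others.append(r)
    others.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.source))
    for i, r in enumerate(others, start=1):
        out[id(r)] = str(i)
    return out


def _make_gene(chrom: str, block_start: int, strand: str, gene_id: str, coding: bool = True) -> GeneModel:
    t = block_start + 60_000
    if strand == "+":
        exons = (
            GenomicInterval(chrom, t, t + 200),
            GenomicInterval(chrom, t + 1_000, t + 1_400),
        )
    else:
        exons = (
            GenomicInterval(chrom, t - 199, t + 1),
            GenomicInterval(chrom, t - 1_400, t - 1_000),
        )
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tss=StrandedPoint(chrom, t, strand),
        exons=exons,
        coding=coding,
    )


def _promoter_interval(gene: GeneModel) -> GenomicInterval:
    t = gene.tss.pos
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, max(0, t - 600), t + 1)
    return GenomicInterval(gene.chrom, t, t + 601)


def _pad(iv: GenomicInterval, rng: np.random.Generator, max_pad: int = 400) -> GenomicInterval:
    left = int(rng.integers(0, max_pad + 1))
    right = int(rng.integers(0, max_pad + 1))
    return GenomicInterval(iv.chrom, max(0, iv.start - left), iv.end + right)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Build the synthetic inputs and truth table for one seeded scenario."""
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom

    n_decoys = len(config.decoy_classes)
    n_blocks = config.n_links + n_decoys + config.n_extra_genes + config.n_extra_enhancers
    genome = [(chrom, n_blocks * BLOCK_BP)]

    by_source: Dict[str, List[SourcedEnhancerRecord]] = {s: [] for s in _SOURCES}
    genes: List[GeneModel] = []
    chiapet: List[ChiaPetPair] = []
    eqtls: List[EqtlRecord] = []
    hier_tads: List[HierTadRecord] = []
    tads: List[TadRecord] = []
    truth: Dict[Tuple[str, str], FrozenSet[str]] = {}

    encode_counter = 1

    def new_enhancer(block_start: int, length: Optional[int] = None) -> SourcedEnhancerRecord:
        nonlocal encode_counter
        length = int(rng.integers(300, 1_201)) if length is None else length
        start = block_start + 20_000
        iv = GenomicInterval(chrom, start, start + length)
        source = _SOURCES[int(rng.integers(0, len(_SOURCES)))]
        native = None
        if source == "ENCODE":
            native = f"EH37E{encode_counter:07d}"
            encode_counter += 1
        rec = SourcedEnhancerRecord(iv, source, native)
        by_source[source].append(rec)
        return rec

    # --- planted links, one block each -----------------------------------
    assay_pool = (
        frozenset({"CHIAPET"}),
        frozenset({"EQTL"}),
        frozenset({"HTAD"}),
        frozenset({"CHIAPET", "EQTL"}),
        frozenset({"EQTL", "HTAD"}),
        frozenset({"CHIAPET", "HTAD"}),
        frozenset({"CHIAPET", "EQTL", "HTAD"}),
    )
    planted: List[Tuple[SourcedEnhancerRecord, GeneModel, FrozenSet[str]]] = []
    for i in range(config.n_links):
        block = i * BLOCK_BP
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        gene = _make_gene(chrom, block, strand, f"GENE{i + 1:03d}")
        genes.append(gene)
        enh = new_enhancer(block)
        assays = assay_pool[int(rng.integers(0, len(assay_pool)))]
        if rng.random() < config.tad_probability:
            assays = assays | {"TAD"}
        planted.append((enh, gene, assays))

        prom = _promoter_interval(gene)
        if "CHIAPET" in assays:
            a_e = _pad(enh.interval, rng)
            a_p = _pad(prom, rng)
            p = float(rng.uniform(0.0005, 0.045))
            cell = _CELL_TYPES[int(rng.integers(0, len(_CELL_TYPES)))]
            if rng.integers(0, 2) == 0:
                chiapet.append(ChiaPetPair(a_e, a_p, p, cell))
            else:
                chiapet.append(ChiaPetPair(a_p, a_e, p, cell))
        if "EQTL" in assays:
            pos = int(rng.integers(enh.interval.start, enh.interval.end))
            eqtls.append(
                EqtlRecord(
                    variant_id=f"rs{900000 + i}",
                    position=StrandedPoint(chrom, pos),
                    gene_id=gene.gene_id,
                    tissue=_TISSUES[int(rng.integers(0, len(_TISSUES)))],
                    p_value=float(rng.uniform(1e-8, 0.045)),
                )
            )
        if "HTAD" in assays:
            region = _pad(enh.interval, rng, max_pad=2_000)
            hier_tads.append(
                HierTadRecord(
                    region=region,
                    gene_id=gene.gene_id,
                    fdr=float(rng.uniform(1e-6, 0.009)),
                    cell_type=_CELL_TYPES[int(rng.integers(0, len(_CELL_TYPES)))],
                )
            )
        if "TAD" in assays:
            tads.append(
                TadRecord(
                    GenomicInterval(chrom, block + 10_000, block + 70_000),
                    _TAD_CELLS[int(rng.integers(0, len(_TAD_CELLS)))],
                )
            )

    # --- decoys, one block each, each failing exactly one rule ------------
    decoy_base = config.n_links
    for j, decoy in enumerate(config.decoy_classes):
        block = (decoy_base + j) * BLOCK_BP
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        gene = _make_gene(
            chrom, block, strand, f"DGENE{j + 1:02d}", coding=(decoy != "eqtl_noncoding_gene")
        )
        genes.append(gene)
        prom = _promoter_interval(gene)

        if decoy == "chiapet_sub50_overlap":
            enh = new_enhancer(block, length=1_000)
            e = enh.interval
            # 490/1000 = 0.49 of the enhancer; 490/1490 of the anchor: both < 0.5
            anchor_e = GenomicInterval(chrom, e.start - 1_000, e.start + 490)
            anchor_p = _pad(prom, rng)
            chiapet.append(ChiaPetPair(anchor_e, anchor_p, 0.01, _CELL_TYPES[0]))
        elif decoy == "chiapet_boundary_p":
            enh = new_enhancer(block)
            chiapet.append(
                ChiaPetPair(_pad(enh.interval, rng), _pad(prom, rng), 0.05, _CELL_TYPES[1])
            )
        elif decoy == "eqtl_exonic":
            # enhancer placed over the gene's first exon; variant in both
            exon = gene.exons[0]
            iv = GenomicInterval(chrom, exon.start - 100, exon.end + 100)
            rec = SourcedEnhancerRecord(iv, "FANTOM", None)
            by_source["FANTOM"].append(rec)
            pos = int(rng.integers(exon.start, exon.end))
            eqtls.append(
                EqtlRecord(f"rs{800000 + j}", StrandedPoint(chrom, pos), gene.gene_id, _TISSUES[0], 0.001)
            )
        elif decoy == "eqtl_boundary_p":
            enh = new_enhancer(block)
            pos = int(rng.integers(enh.interval.start, enh.interval.end))
            eqtls.append(
                EqtlRecord(f"rs{800000 + j}", StrandedPoint(chrom, pos), gene.gene_id, _TISSUES[1], 0.05)
            )
        elif decoy == "eqtl_noncoding_gene":
            enh = new_enhancer(block)
            pos = int(rng.integers(enh.interval.start, enh.interval.end))
            eqtls.append(
                EqtlRecord(f"rs{800000 + j}", StrandedPoint(chrom, pos), gene.gene_id, _TISSUES[2], 0.001)
            )
        elif decoy == "htad_89_containment":
            enh = new_enhancer(block, length=1_000)
            e = enh.interval
            # region covers 890 of the 1000 enhancer bases: 0.89 < 0.90
            region = GenomicInterval(chrom, e.start + 110, e.end + 4_000)
            hier_tads.append(HierTadRecord(region, gene.gene_id, 0.001, _CELL_TYPES[2]))
        elif decoy == "htad_boundary_fdr":
            enh = new_enhancer(block)
            region = _pad(enh.interval, rng, max_pad=2_000)
            hier_tads.append(HierTadRecord(region, gene.gene_id, 0.01, _CELL_TYPES[0]))
        elif decoy == "tad_only_pair":
            enh = new_enhancer(block)
            tads.append(
                TadRecord(GenomicInterval(chrom, block + 10_000, block + 70_000), _TAD_CELLS[0])
            )
        else:  # pragma: no cover
            raise ValueError(f"unknown decoy class {decoy!r}")

    # --- unlinked background genes and enhancers --------------------------
    base = decoy_base + n_decoys
    for k in range(config.n_extra_genes):
        block = (base + k) * BLOCK_BP
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        genes.append(_make_gene(chrom, block, strand, f"XGENE{k + 1:02d}"))
    base += config.n_extra_genes
    for k in range(config.n_extra_enhancers):
        new_enhancer((base + k) * BLOCK_BP)

    ids = _expected_ids(by_source)
    for enh, gene, assays in planted:
        truth[(ids[id(enh)], gene.gene_id)] = assays

    return Scenario(
        config=config,
        genome=genome,
        enhancer_records=by_source,
        genes=genes,
        chiapet=chiapet,
        eqtls=eqtls,
        hier_tads=hier_tads,
        tads=tads,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# On-disk form


def write_scenario(scenario: Scenario, out_dir) -> Dict[str, Path]:
    """Write the scenario as the pipeline's external file formats.

    Produces one enhancer BED per source, a gene-model TSV, a ChIA-PET BEDPE,
    an eQTL TSV, a promoter-interaction TSV, a TAD BED, and the truth table.
    Output is byte-deterministic for a given config.
    """
    from .io_formats import write_gene_models_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    for source, records in scenario.enhancer_records.items():
        p = out / f"enhancers_{source.lower()}.bed"
        with open(p, "w", encoding="utf-8") as fh:
            for r in records:
                iv = r.interval
                if r.native_id:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.native_id}\n")
                else:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        paths[f"enhancers_{source}"] = p

    paths["genes"] = out / "genes.tsv"
    write_gene_models_tsv(scenario.genes, paths["genes"])

    paths["chiapet"] = out / "chiapet.bedpe"
    with open(paths["chiapet"], "w", encoding="utf-8") as fh:
        for c in scenario.chiapet:
            fh.write(
                f"{c.anchor1.chrom}\t{c.anchor1.start}\t{c.anchor1.end}\t"
                f"{c.anchor2.chrom}\t{c.anchor2.start}\t{c.anchor2.end}\t"
                f"{c.p_value!r}\t{c.cell_type}\n"
            )

    paths["eqtl"] = out / "eqtl.tsv"
    with open(paths["eqtl"], "w", encoding="utf-8") as fh:
        fh.write("tissue\tvariant_id\tchrom\tpos\tgene_id\tp_value\n")
        for q in scenario.eqtls:
            fh.write(
                f"{q.tissue}\t{q.variant_id}\t{q.position.chrom}\t{q.position.pos + 1}\t"
                f"{q.gene_id}\t{q.p_value!r}\n"
            )

    paths["hier_tad"] = out / "hier_tad.tsv"
    with open(paths["hier_tad"], "w", encoding="utf-8") as fh:
        for h in scenario.hier_tads:
            fh.write(
                f"{h.region.chrom}\t{h.region.start}\t{h.region.end}\t{h.gene_id}\t"
                f"{h.fdr!r}\t{h.cell_type}\n"
            )

    paths["tad"] = out / "tad.bed"
    with open(paths["tad"], "w", encoding="utf-8") as fh:
        for t in scenario.tads:
            fh.write(f"{t.region.chrom}\t{t.region.start}\t{t.region.end}\t{t.cell_type}\n")

    paths["truth"] = out / "truth.tsv"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("enhancer_id\tgene_id\tassays\n")
        for (eid, gid) in sorted(scenario.truth):
            fh.write(f"{eid}\t{gid}\t{','.join(sorted(scenario.truth[(eid, gid)]))}\n")

    return paths


# ---------------------------------------------------------------------------
# Exhaustive-rule oracle


def oracle_links(scenario: Scenario):
    """Recompute the expected LinkDB by brute-force all-pairs rule application.

    Independent of the pipeline's machinery: no interval index, promoters and
    overlap fractions computed inline, thresholds hard-coded as exact integer
    comparisons (ov*2 >= len for 50%, ov*10 >= 9*len for 90%, strict p < 0.05
    and FDR < 0.01).
    """
    from .evidence_store import LinkDB

    # catalog IDs under the assembly contract
    flat: List[Tuple[str, SourcedEnhancerRecord]] = []
    ids = _expected_ids(scenario.enhancer_records)
    for source, records in scenario.enhancer_records.items():
        for r in records:
            flat.append((ids[id(r)], r))

    genes = {g.gene_id: g for g in scenario.genes}
    coding = {gid: g for gid, g in genes.items() if g.coding}
    promoters = {gid: _promoter_interval(g) for gid, g in coding.items()}

    def ov(a: GenomicInterval, b: GenomicInterval) -> int:
        if a.chrom != b.chrom:
            return 0
        return max(0, min(a.end, b.end) - max(a.start, b.start))

    def recip50(a: GenomicInterval, b: GenomicInterval) -> bool:
        o = ov(a, b)
        return o * 2 >= a.length or o * 2 >= b.length

    def contained90(a: GenomicInterval, region: GenomicInterval) -> bool:
        return ov(a, region) * 10 >= 9 * a.length

    evidence: Dict[Tuple[str, str], Set[EvidenceRecord]] = {}

    def add(eid: str, gid: str, ev: EvidenceRecord) -> None:
        evidence.setdefault((eid, gid), set()).add(ev)

    # ChIA-PET: min-p per (enhancer, gene, cell type) across pairs/orientations
    best: Dict[Tuple[str, str, str], float] = {}
    for pair in scenario.chiapet:
        if not (pair.p_value < 0.05):
            continue
        for a_e, a_p in ((pair.anchor1, pair.anchor2), (pair.anchor2, pair.anchor1)):
            for eid, rec in flat:
                if not recip50(rec.interval, a_e):
                    continue
                for gid, prom in promoters.items():
                    if recip50(prom, a_p):
                        key = (eid, gid, pair.cell_type)
                        if key not in best or pair.p_value < best[key]:
                            best[key] = pair.p_value
    for (eid, gid, cell), p in best.items():
        add(eid, gid, EvidenceRecord("CHIAPET", cell, "p_value", p))

    # eQTL
    for q in scenario.eqtls:
        if not (q.p_value < 0.05):
            continue
        gene = coding.get(q.gene_id)
        if gene is None:
            continue
        if any(
            ex.chrom == q.position.chrom and ex.start <= q.position.pos < ex.end
            for ex in gene.exons
        ):
            continue
        for eid, rec in flat:
            iv = rec.interval
            if iv.chrom == q.position.chrom and iv.start <= q.position.pos < iv.end:
                add(
                    eid,
                    gene.gene_id,
                    EvidenceRecord("EQTL", q.tissue, "p_value", q.p_value, q.variant_id),
                )

    # Hierarchical TAD
    for call in scenario.hier_tads:
        if not (call.fdr < 0.01):
            continue
        if call.gene_id not in coding:
            continue
        for eid, rec in flat:
            if contained90(rec.interval, call.region):
                add(eid, call.gene_id, EvidenceRecord("HTAD", call.cell_type, "fdr", call.fdr))

    # Linear TAD, conditioned on the pairs found above
    supported = set(evidence.keys())
    for tad in scenario.tads:
        enh_in = [eid for eid, rec in flat if contained90(rec.interval, tad.region)]
        genes_in = [gid for gid, prom in promoters.items() if contained90(prom, tad.region)]
        for eid in enh_in:
            for gid in genes_in:
                if (eid, gid) in supported:
                    add(eid, gid, EvidenceRecord("TAD", tad.cell_type, "none"))

    coords = {eid: rec.interval for eid, rec in flat}
    return LinkDB.from_evidence(evidence, coords={e: coords[e] for e, _ in evidence})
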