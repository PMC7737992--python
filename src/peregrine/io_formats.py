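"""Readers and writers for every external file the pipeline touches.

Dialects are explicit and policy-free: coordinate conversion (1-based inputs
such as GTEx positions and VCF POS become 0-based half-open) happens here and
only here, while significance filtering is left to the linkers. All tabular
formats are UTF-8, tab-separated, with ``#`` comment lines; BED-like files
additionally ignore ``track`` lines.
"""

from __future__ import annotations

import gzip
import io
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .genomic_core import GenomicInterval, StrandedPoint, ValidationError
from .records import (
    ChiaPetPair,
    EqtlRecord,
    GeneModel,
    HierTadRecord,
    SourcedEnhancerRecord,
    TadRecord,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

LINK_TABLE_COLUMNS = [
    "enhancer_id",
    "enhancer_chrom",
    "enhancer_start",
    "enhancer_end",
    "gene_id",
    "assay",
    "tissue",
    "score_type",
    "score",
    "eqtl_id",
]


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _data_lines(path: PathLike):
    """Yield (line_number, stripped_line) skipping comments/track/blank lines."""
    with _open_text(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield i, line


class FormatError(ValidationError):
    """A file failed to parse; the message names the offending line."""


def _parse_coord(token: str, path: PathLike, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: unparseable {what} {token!r}") from None


def read_enhancer_bed(path: PathLike, source_label: str) -> List[SourcedEnhancerRecord]:
    """Read a BED-like enhancer file (chrom, start, end[, native_id]).

    Coordinates are taken verbatim as 0-based half-open. The optional fourth
    column is kept as the record's native ID (ENCODE cCRE style); extra
    columns are ignored.
    """
    records: List[SourcedEnhancerRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        chrom = fields[0]
        start = _parse_coord(fields[1], path, lineno, "start")
        end = _parse_coord(fields[2], path, lineno, "end")
        try:
            interval = GenomicInterval(chrom, start, end)
        except ValidationError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        native_id = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else None
        records.append(SourcedEnhancerRecord(interval, source_label, native_id))
    if not records:
        log.warning("no enhancer records read from %s", path)
    return records


def read_tad_bed(path: PathLike, cell_type: Optional[str] = None) -> List[TadRecord]:
    """Read TAD boundary intervals from BED; cell type from column 4 or the argument."""
    records: List[TadRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        try:
            interval = GenomicInterval(
                fields[0],
                _parse_coord(fields[1], path, lineno, "start"),
                _parse_coord(fields[2], path, lineno, "end"),
            )
        except ValidationError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        ct = fields[3] if len(fields) >= 4 and fields[3] else cell_type
        if ct is None:
            raise FormatError(f"{path}:{lineno}: no cell type in column 4 and none supplied")
        records.append(TadRecord(interval, ct))
    if not records:
        log.warning("no TAD records read from %s", path)
    return records


def read_chiapet_bedpe(path: PathLike) -> List[ChiaPetPair]:
    """Read interaction pairs as BEDPE-like TSV.

    Columns: chrom1 start1 end1 chrom2 start2 end2 p_value cell_type.
    """
    pairs: List[ChiaPetPair] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 8:
            raise FormatError(f"{path}:{lineno}: expected 8 tab-separated columns")
        try:
            a1 = GenomicInterval(
                fields[0],
                _parse_coord(fields[1], path, lineno, "start1"),
                _parse_coord(fields[2], path, lineno, "end1"),
            )
            a2 = GenomicInterval(
                fields[3],
                _parse_coord(fields[4], path, lineno, "start2"),
                _parse_coord(fields[5], path, lineno, "end2"),
            )
            pairs.append(ChiaPetPair(a1, a2, float(fields[6]), fields[7]))
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    if not pairs:
        log.warning("no ChIA-PET pairs read from %s", path)
    return pairs


DEFAULT_EQTL_COLUMNS = {
    "tissue": "tissue",
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos_1based": "pos",
    "gene_id": "gene_id",
    "p_value": "p_value",
}


def read_eqtl_table(
    path: PathLike, columns: Optional[Dict[str, str]] = None
) -> List[EqtlRecord]:
    """Read a GTEx-style eQTL TSV.

    ``columns`` maps the logical fields (tissue, variant_id, chrom, pos_1based,
    gene_id, p_value) to the header names actually present, so either the
    variant-gene-pairs or the significant-pairs flavour can be consumed.
    Positions are 1-based in the file and converted to 0-based here.
    """
    colmap = dict(DEFAULT_EQTL_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    records: List[EqtlRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        pos1 = int(d[colmap["pos_1based"]])
        records.append(
            EqtlRecord(
                variant_id=d[colmap["variant_id"]],
                position=StrandedPoint(d[colmap["chrom"]], pos1 - 1),
                gene_id=d[colmap["gene_id"]],
                tissue=d[colmap["tissue"]],
                p_value=float(d[colmap["p_value"]]),
            )
        )
    if not records:
        log.warning("no eQTL records read from %s", path)
    return records


def read_hier_tad_table(path: PathLike) -> List[HierTadRecord]:
    """Read promoter-interacting region calls (PSYCHIC-style).

    Columns: chrom start end gene_id fdr cell_type (0-based half-open region).
    """
    records: List[HierTadRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 tab-separated columns")
        try:
            region = GenomicInterval(
                fields[0],
                _parse_coord(fields[1], path, lineno, "start"),
                _parse_coord(fields[2], path, lineno, "end"),
            )
            records.append(HierTadRecord(region, fields[3], float(fields[4]), fields[5]))
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


# ---------------------------------------------------------------------------
# Gene models


def _parse_exon_spec(spec: str, chrom: str, path: PathLike, lineno: int):
    """Exon list as semicolon-separated 1-based inclusive spans, e.g. '101-200;301-400'."""
    exons = []
    for token in spec.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            s, e = token.split("-")
            exons.append(GenomicInterval(chrom, int(s) - 1, int(e)))
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}:{lineno}: bad exon span {token!r} ({exc})") from None
    return tuple(exons)


def read_gene_models_tsv(path: PathLike) -> List[GeneModel]:
    """Read the minimal gene-model TSV.

    Columns: gene_id, symbol, chrom, strand, tss_1based, exons, coding.
    ``exons`` holds 1-based inclusive spans ('101-200;301-400'); ``coding`` is
    1/0. The TSS is converted to a 0-based position.
    """
    genes: List[GeneModel] = []
    header: Optional[List[str]] = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None and fields[0] == "gene_id":
            header = fields
            continue
        if len(fields) < 7:
            raise FormatError(f"{path}:{lineno}: expected 7 tab-separated columns")
        gene_id, symbol, chrom, strand, tss1, exon_spec, coding = fields[:7]
        try:
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=symbol or None,
                    chrom=chrom,
                    strand=strand,
                    tss=StrandedPoint(chrom, int(tss1) - 1, strand),
                    exons=_parse_exon_spec(exon_spec, chrom, path, lineno),
                    coding=coding in ("1", "true", "True"),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return genes


_CODING_BIOTYPES = {"protein_coding"}


def read_gene_models_gtf(path: PathLike) -> List[GeneModel]:
    """Read gene models from a GTF subset carrying ``gene`` and ``exon`` features.

    The TSS is taken from the gene feature's 5'-most coordinate on its strand;
    coding status from the ``gene_biotype``/``gene_type`` attribute.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: List[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("gene_id", [g.id])[0]
        biotype = (
            g.attributes.get("gene_biotype", g.attributes.get("gene_type", ["protein_coding"]))
        )[0]
        strand = g.strand if g.strand in ("+", "-") else "+"
        exons = tuple(
            GenomicInterval(e.seqid, e.start - 1, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
            if e.attributes.get("gene_id", [None])[0] in (gene_id, None)
        )
        if not exons:
            exons = (GenomicInterval(g.seqid, g.start - 1, g.end),)
        tss0 = g.start - 1 if strand == "+" else g.end - 1
        symbol = g.attributes.get("gene_name", [None])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=symbol,
                chrom=g.seqid,
                strand=strand,
                tss=StrandedPoint(g.seqid, tss0, strand),
                exons=exons,
                coding=biotype in _CODING_BIOTYPES,
            )
        )
    return genes


def read_gene_models(path: PathLike) -> List[GeneModel]:
    """Dispatch on extension: .gtf/.gff -> GTF reader, otherwise the TSV dialect."""
    suffixes = {s.lower() for s in Path(path).suffixes}
    if {".gtf", ".gff", ".gff3"} & suffixes:
        return read_gene_models_gtf(path)
    return read_gene_models_tsv(path)


def write_gene_models_tsv(genes: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tsymbol\tchrom\tstrand\ttss_1based\texons\tcoding\n")
        for g in genes:
            exon_spec = ";".join(f"{e.start + 1}-{e.end}" for e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.symbol or ''}\t{g.chrom}\t{g.strand}\t"
                f"{g.tss.pos + 1}\t{exon_spec}\t{1 if g.coding else 0}\n"
            )


# ---------------------------------------------------------------------------
# VCF


def read_vcf_positions(path: PathLike) -> List[Tuple[str, StrandedPoint]]:
    """Read (variant_id, 0-based position) from a VCF; genotypes are ignored.

    Variants without an ID are keyed ``chrom_pos`` (1-based pos, GTEx style).
    """
    from cyvcf2 import VCF

    out: List[Tuple[str, StrandedPoint]] = []
    for v in VCF(str(path)):
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        out.append((vid, StrandedPoint(v.CHROM, v.POS - 1)))
    return out


# ---------------------------------------------------------------------------
# Link tables (bulk-download analog)


def write_link_table(linkdb, path: PathLike) -> None:
    """Write a LinkDB as the flat evidence-per-row TSV bulk format.

    One row per evidence record; rows ordered by (enhancer_id, gene_id, assay,
    tissue, score, eqtl_id) so output is byte-deterministic.
    """
    rows = []
    for (enh, gene) in sorted(linkdb.links):
        iv = linkdb.coords.get(enh)
        for ev in linkdb.evidence[(enh, gene)]:
            rows.append(
                (
                    enh,
                    iv.chrom if iv else "",
                    str(iv.start) if iv else "",
                    str(iv.end) if iv else "",
                    gene,
                    ev.assay,
                    ev.tissue,
                    ev.score_type,
                    "" if ev.score is None else repr(ev.score),
                    ev.eqtl_id or "",
                )
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(LINK_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_link_table(path: PathLike):
    """Read a link-table TSV back into a LinkDB (inverse of :func:`write_link_table`)."""
    from .evidence_store import LinkDB
    from .records import ASSAYS, EvidenceRecord

    evidence: Dict[Tuple[str, str], list] = {}
    coords: Dict[str, GenomicInterval] = {}
    header: Optional[List[str]] = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < len(LINK_TABLE_COLUMNS):
            fields = fields + [""] * (len(LINK_TABLE_COLUMNS) - len(fields))
        if header is None and fields[0] == "enhancer_id":
            header = fields
            continue
        enh, chrom, start, end, gene, assay, tissue, score_type, score, eqtl_id = fields[
            : len(LINK_TABLE_COLUMNS)
        ]
        if assay not in ASSAYS:
            raise FormatError(f"{path}:{lineno}: unknown assay token {assay!r}")
        if chrom:
            coords[enh] = GenomicInterval(chrom, int(start), int(end))
        ev = EvidenceRecord(
            assay=assay,
            tissue=tissue,
            score_type=score_type,
            score=None if score == "" else float(score),
            eqtl_id=eqtl_id or None,
        )
        evidence.setdefault((enh, gene), []).append(ev)
    return LinkDB.from_evidence(evidence, coords=coords)


# ---------------------------------------------------------------------------
# Candidate-link tables (per-linker intermediate output)

CANDIDATE_COLUMNS = ["enhancer_id", "gene_id", "assay", "tissue", "score_type", "score", "eqtl_id"]


def write_candidates(candidates, path: PathLike) -> None:
    """Write one linker's candidate links as TSV (one evidence row per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            ev = c.evidence
            fh.write(
                f"{c.enhancer_id}\t{c.gene_id}\t{ev.assay}\t{ev.tissue}\t{ev.score_type}\t"
                f"{'' if ev.score is None else repr(ev.score)}\t{ev.eqtl_id or ''}\n"
            )


def read_candidates(path: PathLike):
    from .records import ASSAYS, CandidateLink, EvidenceRecord

    out = []
    header_seen = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < len(CANDIDATE_COLUMNS):
            fields = fields + [""] * (len(CANDIDATE_COLUMNS) - len(fields))
        if not header_seen and fields[0] == "enhancer_id":
            header_seen = True
            continue
        enh, gene, assay, tissue, score_type, score, eqtl_id = fields[: len(CANDIDATE_COLUMNS)]
        if assay not in ASSAYS:
            raise FormatError(f"{path}:{lineno}: unknown assay token {assay!r}")
        out.append(
            CandidateLink(
                enh,
                gene,
                EvidenceRecord(
                    assay=assay,
                    tissue=tissue,
                    score_type=score_type,
                    score=None if score == "" else float(score),
                    eqtl_id=eqtl_id or None,
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Catalog tables


def write_catalog_table(catalog, path: PathLike) -> None:
    """Persist an assembled enhancer catalog (one row per enhancer)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("enhancer_id\tchrom\tstart\tend\tsource\n")
        for entry in catalog.enhancers:
            iv = entry.interval
            fh.write(f"{entry.enhancer_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{entry.source}\n")


def read_catalog_table(path: PathLike):
    from .enhancer_assembly import CatalogEntry, EnhancerCatalog

    entries = []
    header_seen = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not header_seen and fields[0] == "enhancer_id":
            header_seen = True
            continue
        if len(fields) < 5:
            raise FormatError(f"{path}:{lineno}: expected 5 tab-separated columns")
        eid, chrom, start, end, source = fields[:5]
        entries.append(
            CatalogEntry(eid, GenomicInterval(chrom, int(start), int(end)), source)
        )
    return EnhancerCatalog(entries)
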