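"""Promoter definition and the four evidence linkers."""

import pytest

from peregrine.enhancer_assembly import assemble_catalog
from peregrine.genomic_core import GenomicInterval, StrandedPoint, ValidationError
from peregrine.linkers import (
    condition_tad_links,
    derive_promoter,
    derive_promoters,
    link_chiapet,
    link_eqtl,
    link_hier_tad,
    link_tad,
)
from peregrine.records import (
    CandidateLink,
    ChiaPetPair,
    EqtlRecord,
    EvidenceRecord,
    GeneModel,
    HierTadRecord,
    SourcedEnhancerRecord,
    TadRecord,
)


def gene(gene_id="G1", tss=10_000, strand="+", chrom="chr1", coding=True, exons=None):
    if exons is None:
        if strand == "+":
            exons = (GenomicInterval(chrom, tss, tss + 200),)
        else:
            exons = (GenomicInterval(chrom, tss - 199, tss + 1),)
    return GeneModel(gene_id, chrom, strand, StrandedPoint(chrom, tss, strand), exons, coding)


def catalog_of(*spans, chrom="chr1"):
    return assemble_catalog(
        [SourcedEnhancerRecord(GenomicInterval(chrom, s, e), "FANTOM") for s, e in spans]
    )


class TestPromoter:
    def test_plus_strand_window(self):
        w = derive_promoter(gene(tss=10_000, strand="+"))
        assert w.interval == GenomicInterval("chr1", 9_400, 10_001)
        assert w.interval.length == 601

    def test_minus_strand_window(self):
        w = derive_promoter(gene(tss=10_000, strand="-"))
        assert w.interval == GenomicInterval("chr1", 10_000, 10_601)
        assert w.interval.length == 601

    def test_clipped_at_chromosome_start(self, caplog):
        with caplog.at_level("WARNING"):
            w = derive_promoter(gene(tss=100, strand="+"))
        assert w.interval == GenomicInterval("chr1", 0, 101)
        assert "clipped" in caplog.text

    def test_window_contains_tss(self):
        for strand in "+-":
            g = gene(tss=5_000, strand=strand)
            w = derive_promoter(g)
            assert w.interval.start <= 5_000 < w.interval.end

    def test_coding_filter(self):
        proms = derive_promoters([gene("G1"), gene("G2", coding=False)])
        assert [p.gene_id for p in proms] == ["G1"]


class TestChiaPet:
    def setup_method(self):
        self.cat = catalog_of((1_000, 1_500))
        self.genes = [gene(tss=50_000)]
        self.proms = derive_promoters(self.genes)

    def pair(self, p=0.01, swap=False):
        a1 = GenomicInterval("chr1", 900, 1_600)  # contains the enhancer
        a2 = GenomicInterval("chr1", 49_000, 50_100)  # contains the promoter
        return ChiaPetPair(a2, a1, p, "K562") if swap else ChiaPetPair(a1, a2, p, "K562")

    def test_basic_link(self):
        (link,) = link_chiapet([self.pair()], self.cat, self.proms)
        assert (link.enhancer_id, link.gene_id) == ("1", "G1")
        assert link.evidence.assay == "CHIAPET" and link.evidence.score == 0.01

    def test_orientation_free(self):
        assert len(link_chiapet([self.pair(swap=True)], self.cat, self.proms)) == 1

    def test_boundary_p_excluded(self):
        assert link_chiapet([self.pair(p=0.05)], self.cat, self.proms) == []

    def test_cross_product_within_pair(self):
        cat = catalog_of((1_000, 1_500), (1_600, 2_000))
        genes = [gene("G1", 50_000), gene("G2", 52_000)]
        proms = derive_promoters(genes)
        pair = ChiaPetPair(
            GenomicInterval("chr1", 900, 2_100),
            GenomicInterval("chr1", 49_000, 53_000),
            0.001,
            "K562",
        )
        links = link_chiapet([pair], cat, proms)
        assert {(l.enhancer_id, l.gene_id) for l in links} == {
            ("1", "G1"), ("1", "G2"), ("2", "G1"), ("2", "G2")
        }

    def test_same_anchor_does_not_self_link(self):
        # enhancer and promoter both inside anchor1; anchor2 empty of both
        cat = catalog_of((49_000, 49_300))
        pair = ChiaPetPair(
            GenomicInterval("chr1", 48_000, 51_000),
            GenomicInterval("chr1", 200_000, 201_000),
            0.001,
            "K562",
        )
        assert link_chiapet([pair], cat, self.proms) == []

    def test_sub_threshold_overlap_rejected(self):
        # anchor covers 49% of the enhancer and <50% of itself
        cat = catalog_of((1_000, 2_000))
        a1 = GenomicInterval("chr1", 0, 1_490)
        a2 = GenomicInterval("chr1", 49_000, 50_100)
        assert link_chiapet([ChiaPetPair(a1, a2, 0.01, "K562")], cat, self.proms) == []

    def test_duplicates_collapse_to_min_p(self):
        links = link_chiapet([self.pair(p=0.04), self.pair(p=0.002)], self.cat, self.proms)
        assert len(links) == 1 and links[0].evidence.score == 0.002


class TestEqtl:
    def setup_method(self):
        self.cat = catalog_of((1_000, 1_500))
        self.genes = [gene(tss=50_000)]

    def q(self, pos=1_200, p=1e-6, gene_id="G1", tissue="Liver"):
        return EqtlRecord("rs1", StrandedPoint("chr1", pos), gene_id, tissue, p)

    def test_basic_link(self):
        (link,) = link_eqtl([self.q()], self.cat, self.genes)
        assert (link.enhancer_id, link.gene_id) == ("1", "G1")
        assert link.evidence.eqtl_id == "rs1"

    def test_exonic_position_excluded(self):
        # exon spans [50_000, 50_200); put an enhancer over it
        cat = catalog_of((49_900, 50_300))
        assert link_eqtl([self.q(pos=50_100)], cat, self.genes) == []

    def test_other_genes_exons_do_not_exclude(self):
        other = gene("G2", tss=1_100, exons=(GenomicInterval("chr1", 1_100, 1_300),))
        (link,) = link_eqtl([self.q(pos=1_200)], self.cat, self.genes + [other])
        assert link.gene_id == "G1"

    def test_boundary_p_excluded(self):
        assert link_eqtl([self.q(p=0.05)], self.cat, self.genes) == []

    def test_unknown_gene_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert link_eqtl([self.q(gene_id="NOPE")], self.cat, self.genes) == []
        assert "unknown gene" in caplog.text

    def test_noncoding_gene_never_linked(self):
        genes = [gene(coding=False)]
        assert link_eqtl([self.q()], self.cat, genes) == []

    def test_overlapping_enhancers_each_link(self):
        cat = catalog_of((1_000, 1_500), (1_100, 1_400))
        links = link_eqtl([self.q(pos=1_200)], cat, self.genes)
        assert len(links) == 2


class TestHierTad:
    def setup_method(self):
        self.cat = catalog_of((1_000, 2_000))

    def call(self, start=500, end=5_000, fdr=0.005):
        return HierTadRecord(GenomicInterval("chr1", start, end), "G1", fdr, "MCF7")

    def test_full_containment_links(self):
        (link,) = link_hier_tad([self.call()], self.cat)
        assert (link.enhancer_id, link.gene_id) == ("1", "G1")
        assert link.evidence.score_type == "fdr"

    def test_89_pct_containment_rejected(self):
        # region covers 890 of 1000 enhancer bases
        assert link_hier_tad([self.call(start=1_110)], self.cat) == []

    def test_90_pct_containment_inclusive(self):
        assert len(link_hier_tad([self.call(start=1_100)], self.cat)) == 1

    def test_boundary_fdr_excluded(self):
        assert link_hier_tad([self.call(fdr=0.01)], self.cat) == []

    def test_gene_filter_when_models_given(self):
        genes = [gene("G1", coding=False)]
        assert link_hier_tad([self.call()], self.cat, genes=genes) == []


class TestTadAndConditioning:
    def setup_method(self):
        self.cat = catalog_of((10_000, 11_000), (20_000, 21_000))
        self.genes = [gene("G1", 60_000), gene("G2", 62_000), gene("G3", 64_000)]
        self.proms = derive_promoters(self.genes)
        self.tad = TadRecord(GenomicInterval("chr1", 0, 70_000), "GM12878")

    def test_cross_product(self):
        cands = link_tad([self.tad], self.cat, self.proms)
        assert len(cands) == 6
        assert all(c.evidence.assay == "TAD" and c.evidence.score is None for c in cands)

    def test_enhancer_spanning_boundary_excluded(self):
        cat = catalog_of((69_500, 70_500))  # 50% in the TAD
        assert link_tad([self.tad], cat, self.proms) == []

    def test_promoter_90_pct_boundary_inclusive(self):
        # plus-strand promoter [59_400, 60_001); TAD covering exactly 90% of its 601 bases
        # 0.9*601 = 540.9 -> needs >= 540.9, i.e. 541 bases
        tad = TadRecord(GenomicInterval("chr1", 0, 59_400 + 541), "GM12878")
        cands = link_tad([tad], self.cat, derive_promoters([gene("G1", 60_000)]))
        assert {c.gene_id for c in cands} == {"G1"}

    def test_conditioning_retains_only_supported_pairs(self):
        cands = link_tad([self.tad], self.cat, self.proms)
        other = [
            CandidateLink("1", "G1", EvidenceRecord("EQTL", "Liver", "p_value", 0.001, "rs1")),
            CandidateLink("2", "G3", EvidenceRecord("CHIAPET", "K562", "p_value", 0.01)),
        ]
        kept = condition_tad_links(cands, other)
        assert {(c.enhancer_id, c.gene_id) for c in kept} == {("1", "G1"), ("2", "G3")}
        assert set(kept) <= set(cands)

    def test_conditioning_drops_unsupported(self):
        cands = [CandidateLink("1", "G2", EvidenceRecord("TAD", "GM12878", "none"))]
        other = [CandidateLink("1", "G1", EvidenceRecord("EQTL", "L", "p_value", 0.01, "rs1"))]
        assert condition_tad_links(cands, other) == []

    def test_tad_records_in_other_links_rejected(self):
        tad_ev = [CandidateLink("1", "G1", EvidenceRecord("TAD", "GM12878", "none"))]
        with pytest.raises(ValidationError):
            condition_tad_links(tad_ev, tad_ev)


class TestDeterminism:
    def test_linkers_are_order_stable(self, scenario_seed1):
        # same inputs, twice, identical ordered outputs
        cat = assemble_catalog(
            [r for recs in scenario_seed1.enhancer_records.values() for r in recs]
        )
        proms = derive_promoters(scenario_seed1.genes)
        a = link_chiapet(scenario_seed1.chiapet, cat, proms)
        b = link_chiapet(list(scenario_seed1.chiapet), cat, proms)
        assert a == b
        qa = link_eqtl(scenario_seed1.eqtls, cat, scenario_seed1.genes)
        qb = link_eqtl(scenario_seed1.eqtls, cat, scenario_seed1.genes)
        assert qa == qb
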