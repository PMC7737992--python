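"""Distribution tables, summary means, tissue binning, association statistics."""

import math
import random

import numpy as np
import pytest

from peregrine.evidence_store import LinkSupport, aggregate
from peregrine.genomic_core import ParameterError, ValidationError
from peregrine.records import CandidateLink, EvidenceRecord
from peregrine.summary_stats import (
    CatalogSummaryTable,
    TargetDistribution,
    assay_tissue_association,
    bin_tissue_counts,
    catalog_summary,
    distribution_summaries,
    export_gene_enhancer_counts,
    per_assay_means,
    round_half_away,
    target_distribution,
)
from peregrine.tables import load_catalog_summary, load_target_distribution


def db_of(*pairs):
    return aggregate(
        [
            CandidateLink(e, g, EvidenceRecord("EQTL", "Liver", "p_value", 0.01, "rs1"))
            for e, g in pairs
        ]
    )


class TestRounding:
    @pytest.mark.parametrize(
        "x,nd,expected", [(55.56, 0, 56), (95.81, 0, 96), (97.33, 0, 97), (0.5, 0, 1), (1.985, 2, 1.99)]
    )
    def test_half_away_from_zero(self, x, nd, expected):
        assert round_half_away(x, nd) == expected


class TestTargetDistribution:
    def test_histogram_from_links(self):
        dist = target_distribution(db_of(("E1", "G1"), ("E1", "G2"), ("E2", "G1")))
        assert dist.rows == [(1, 1), (2, 1)]

    def test_all_single_target(self):
        dist = target_distribution(db_of(("E1", "G1"), ("E2", "G1")))
        assert dist.rows == [(1, 2)]
        assert dist.cumulative_fractions() == [(1, 1.0)]

    def test_matches_group_by_oracle(self):
        rng = random.Random(5)
        pairs = {(f"E{rng.randint(1, 8)}", f"G{rng.randint(1, 8)}") for _ in range(40)}
        dist = target_distribution(db_of(*pairs))
        per_enh = {}
        for e, g in pairs:
            per_enh.setdefault(e, set()).add(g)
        expected = {}
        for genes in per_enh.values():
            expected[len(genes)] = expected.get(len(genes), 0) + 1
        assert dict(dist.rows) == expected

    def test_cumulative_monotone_ending_at_one(self):
        dist = TargetDistribution([(1, 5), (2, 3), (4, 2)])
        fracs = [f for _, f in dist.cumulative_fractions()]
        assert fracs == sorted(fracs) and fracs[-1] == pytest.approx(1.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            TargetDistribution([(2, 5), (1, 3)])
        with pytest.raises(ValidationError):
            TargetDistribution([(1, -1)])


class TestDistributionSummaries:
    def test_simple_arithmetic(self):
        s = distribution_summaries(TargetDistribution([(1, 2), (3, 2)]))
        assert (s.total_enhancers, s.total_links, s.mean_genes_per_enhancer) == (4, 8, 2.00)

    def test_consistency_with_linkdb(self):
        db = db_of(("E1", "G1"), ("E1", "G2"), ("E2", "G1"), ("E3", "G3"))
        dist = target_distribution(db)
        s = distribution_summaries(dist)
        assert s.total_links == len(db)

    def test_empty_distribution_errors(self):
        with pytest.raises(ValidationError):
            distribution_summaries(TargetDistribution([]))

    def test_packaged_distribution_totals(self):
        dist, n_genes = load_target_distribution()
        s = distribution_summaries(dist, n_genes=n_genes)
        assert s.total_enhancers == 449_627
        assert s.total_links == 890_402
        assert s.mean_genes_per_enhancer == 1.98
        assert s.mean_enhancers_per_gene == 50.47
        assert s.pct_with_k_or_fewer(dist, 1) == 56
        assert s.pct_with_k_or_fewer(dist, 5) == 96
        assert s.pct_with_k_or_fewer(dist, 6) == 97


class TestCatalogSummary:
    def test_packaged_catalog_totals(self):
        total, wmean = catalog_summary(load_catalog_summary())
        assert total == 1_085_794
        assert wmean == 422

    def test_single_source(self):
        total, wmean = catalog_summary(CatalogSummaryTable([("other", 10, 100.0)]))
        assert (total, wmean) == (10, 100)

    def test_live_catalog(self, built_seed1):
        catalog = built_seed1[0]
        total, wmean = catalog_summary(catalog)
        assert total == len(catalog)
        lens = [e.length for e in catalog.enhancers]
        assert wmean == round_half_away(sum(lens) / len(lens))


class TestPerAssayMeans:
    def test_basic_means(self):
        cands = [
            CandidateLink("E1", "G1", EvidenceRecord("EQTL", "L", "p_value", 0.01, "rs1")),
            CandidateLink("E1", "G2", EvidenceRecord("EQTL", "L", "p_value", 0.01, "rs2")),
        ]
        df = per_assay_means(aggregate(cands))
        row = df[df.assay == "EQTL"].iloc[0]
        assert row.mean_genes_per_enhancer == 2.00
        assert row.mean_enhancers_per_gene == 1.00

    def test_absent_assay_omitted(self):
        df = per_assay_means(db_of(("E1", "G1")))
        assert list(df.assay) == ["EQTL"]

    def test_matches_group_by_oracle(self, built_seed1):
        db = built_seed1[2]
        df = per_assay_means(db).set_index("assay")
        for assay in df.index:
            pairs = [p for p in db.links if assay in db.assays_of(p)]
            per_enh, per_gene = {}, {}
            for e, g in pairs:
                per_enh.setdefault(e, set()).add(g)
                per_gene.setdefault(g, set()).add(e)
            mg = np.mean([len(v) for v in per_enh.values()])
            me = np.mean([len(v) for v in per_gene.values()])
            assert df.loc[assay].mean_genes_per_enhancer == round_half_away(mg, 2)
            assert df.loc[assay].mean_enhancers_per_gene == round_half_away(me, 2)


def supports_of(counts):
    return [LinkSupport((f"E{i}", "G"), a, t) for i, (t, a) in enumerate(counts)]


class TestTissueBinning:
    def test_bin_edges(self):
        sup = supports_of([(5, 1), (6, 1), (1, 1), (10, 1)])
        assert bin_tissue_counts(sup) == ["1-5", "6-10", "1-5", "6-10"]

    def test_overflow_merges_into_top_bin(self):
        counts = [(i, 1) for i in range(1, 71)] + [(71, 2)]
        labels = bin_tissue_counts(supports_of(counts))
        assert labels[-1] == "66-70" and labels[-2] == "66-70"

    def test_all_equal_single_bin(self):
        assert set(bin_tissue_counts(supports_of([(3, 1)] * 5))) == {"1-5"}

    def test_width_validation(self):
        with pytest.raises(ParameterError):
            bin_tissue_counts(supports_of([(1, 1)]), width=0)


class TestAssociation:
    def test_proportional_table_gives_zero_chi2(self):
        # assay count independent of tissue bin: chi2 == 0
        sup = supports_of([(5, 1), (5, 2), (10, 1), (10, 2)] * 5)
        res = assay_tissue_association(sup)
        assert res.chi2 == pytest.approx(0.0)

    def test_perfect_correlation(self):
        sup = supports_of([(1, 1), (7, 2), (13, 3), (19, 4)] * 3)
        res = assay_tissue_association(sup)
        assert res.pearson_r == pytest.approx(1.0)

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(12)
        tissues = rng.integers(1, 31, size=300)
        assays = np.clip((tissues / 10 + rng.normal(0, 1, size=300)).astype(int), 1, 4)
        sup = supports_of(list(zip(tissues.tolist(), assays.tolist())))
        res = assay_tissue_association(sup)

        # chi-squared: sum (O-E)^2 / E over the binned contingency table
        labels = bin_tissue_counts(sup)
        rows = sorted(set(labels))
        cols = sorted(set(assays.tolist()))
        obs = np.zeros((len(rows), len(cols)))
        for lab, a in zip(labels, assays.tolist()):
            obs[rows.index(lab), cols.index(a)] += 1
        expected = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert res.chi2 == pytest.approx(chi2)
        assert res.df == (len(rows) - 1) * (len(cols) - 1)

        # Pearson r on the raw (unbinned) values
        x, y = tissues.astype(float), assays.astype(float)
        r = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.pearson_r == pytest.approx(r)
        assert -1.0 <= res.pearson_r <= 1.0 and res.chi2 >= 0

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValidationError):
            assay_tissue_association(supports_of([(1, 1), (2, 1)]))


class TestExport:
    def test_counts_per_gene(self, tmp_path):
        df = export_gene_enhancer_counts(db_of(("E1", "G1"), ("E2", "G1")), tmp_path / "g.tsv")
        assert df.values.tolist() == [["G1", 2]]
        assert (tmp_path / "g.tsv").read_text().splitlines()[0] == "gene_id\tn_linked_enhancers"

    def test_matches_group_by_oracle(self, built_seed1):
        db = built_seed1[2]
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            df = export_gene_enhancer_counts(db, os.path.join(d, "g.tsv"))
        expected = {}
        for e, g in db.links:
            expected.setdefault(g, set()).add(e)
        assert dict(zip(df.gene_id, df.n_linked_enhancers)) == {
            g: len(v) for g, v in expected.items()
        }
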