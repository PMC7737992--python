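# Methods

## The problem

Enhancers are short, strand-independent cis-regulatory DNA elements that
upregulate one or more target genes, often at a distance and often skipping
the nearest gene. Which gene(s) a given enhancer regulates is mostly unknown,
yet that mapping is what turns a non-coding GWAS hit into a testable gene
hypothesis. This package reconstructs a multi-assay enhancer–gene link
pipeline: it assembles a catalog of enhancer elements from several public
sources, links them to protein-coding genes with four kinds of experimental
evidence, and aggregates the per-tissue evidence into a queryable link
database.

## The catalog

Enhancer calls from up to four sources (ENCODE cCREs, Ensembl, FANTOM,
VISTA) are pooled **without any filtering or merging**: coordinate-identical
elements from two sources stay two catalog entries, because each source's
calling pipeline is treated as an independent assertion that the region is an
enhancer. ENCODE records keep their native alphanumeric cCRE IDs
(`EH37E…`); every other record receives a sequential numeric string ID
assigned in (chrom, start, end, source) order starting at "1". Whether the
original project numbered per source or globally is not derivable from the
data; global sequential numbering was chosen for determinism.

Overlap bookkeeping uses a minimum threshold of 1 bp. Book-ended intervals
(`[0,10)` and `[10,20)`) share zero bases and never merge. Clustering is the
connected-component closure of the pairwise ≥1 bp overlap relation
(transitive: a chain of partial overlaps is one cluster); a cluster's merged
region is its coordinate union, which is contiguous by connectivity. The
cluster operation is idempotent and conserves the set of covered bases.

## Coordinates and overlap predicates

All internal coordinates are 0-based half-open (BED convention); 1-based
inputs (GTEx positions, VCF POS) are shifted exactly once, at the I/O
boundary. Three predicates drive all linking:

* **reciprocal-OR at t**: true when ≥ t of *either* interval is covered by
  the other. Used at t = 0.5 for ChIA-PET anchors, so a short enhancer fully
  inside a broad anchor qualifies, and so does a broad enhancer engulfing a
  narrow anchor.
* **one-directional containment at t**: true when ≥ t of the first interval
  lies inside the region. Used at t = 0.9 for TAD and promoter-interacting
  region containment.
* **point-in**: half-open membership of a single base (eQTL positions,
  variant queries).

Geometric thresholds are inclusive (≥) — "at least 50%", "at least 90%".
They are evaluated in exact integer arithmetic by cross-multiplication
(`overlap·q ≥ p·length` for t = p/q, with t parsed via its decimal string),
so a 90%-covered 601-bp promoter is decided correctly where binary floating
point would not. Significance cutoffs are **strict** (p < 0.05,
FDR < 0.01): "significant at the α = 0.05 level" is read conventionally as
p < α. Both boundary conventions are fixed, tested, and overridable through
function parameters.

## Promoter definition

A gene's promoter is its TSS plus the 600 bp immediately **upstream** of it:
601 bp total, containing the TSS base. On the plus strand with TSS at
0-based t the window is `[t−600, t+1)`; on the minus strand `[t, t+601)`.
Strand-awareness is a design choice — "preceding" is read relative to the
direction of transcription; the alternative (always left of the TSS
coordinate) is not used. Windows are clipped at position 0 with a warning.
Only protein-coding genes get promoters or links.

## The four linkers

* **ChIA-PET** (RNA-Pol-II interaction pairs with p-values, per cell type).
  For each pair with p < 0.05, each anchor is screened for enhancers
  (reciprocal-OR, 0.5) and its partner anchor for promoters (same rule);
  every qualifying enhancer × promoter combination becomes a link. Both
  anchor orientations are screened; an enhancer and a promoter inside the
  *same* anchor do not link through that anchor alone (self-ligation says
  nothing about looping). Duplicate (enhancer, gene, cell-type) candidates
  collapse keeping the smallest p.
* **eQTL** (tissue-specific variant–gene associations, 1-based positions).
  Variants with p < 0.05 whose position falls inside an enhancer link that
  enhancer to the variant's target gene — unless the position lies in an
  exon of that same target gene, in which case the association is more
  parsimoniously explained by the coding sequence and the record is
  excluded. The exclusion uses the exons of the *associated* gene only.
  No multiple-testing correction is added on top of the input p-values.
* **Hierarchical TAD** (within-TAD promoter-interacting regions, per cell
  type, with FDR). For calls with FDR < 0.01, every enhancer ≥ 90% contained
  in the region links to the named gene.
* **Linear TAD** (domain boundaries per cell type). Enhancers ≥ 90%
  contained in a TAD cross with genes whose promoters are ≥ 90% contained in
  the same TAD — but same-TAD co-residence alone is weak evidence, so these
  are candidates only, retained solely for (enhancer, gene) pairs already
  produced by one of the other three linkers (tissue labels need not match).
  A link can therefore never be supported by TAD evidence alone.

Aggregation unions all candidates, deduplicates evidence on the exact
(assay, tissue, score-type, score, eQTL-ID) tuple, and orders everything
deterministically, so the database is insensitive to input order.

## Summary statistics

Per-link support counts distinct assays (1–4) and distinct pooled
tissue/cell-type labels (exact trimmed strings; no ontology mapping). The
genes-per-enhancer distribution, its cumulative fractions, per-assay means
(a link counts once per supporting assay, so per-assay columns may sum to
more than the total), and gene-level enhancer counts are recomputed from
the database with ordinary group-bys. Tissue counts are binned in groups of
5 ([1–5], [6–10], …); observations beyond the last complete bin merge into
it. The association between tissue breadth and assay breadth is tested with
the Pearson chi-squared statistic on the binned contingency table (no
continuity correction, no pooling of sparse cells) and with the Pearson
correlation on the **unbinned** counts (the binned variant is available
behind a flag; which of the two the original analysis used is not stated).

Percent summaries round half-away-from-zero to whole percent; ratio means
to 2 decimals; mean lengths to whole bp — matching the precision at which
such tables are conventionally printed.

## Packaged published tables

Two tiny machine-readable tables ship with the package: the per-source
catalog summary (counts and mean lengths for ENCODE/Ensembl/FANTOM/VISTA)
and the 34-row genes-per-enhancer distribution of the full-scale link set,
with the linked-gene total (17,643) carried as a header comment. From these
the statistics layer reproduces the headline numbers of the full-scale
build: 1,085,794 enhancers of count-weighted mean length 422 bp; 449,627
linked enhancers; 890,402 links; 1.98 mean genes per enhancer; 50.47 mean
enhancers per gene; 56% / 96% / 97% of enhancers with ≤1 / ≤5 / ≤6 targets.
(The published total appears both as 890,403 and 890,402 in different
places; the distribution's column sum gives 890,402, and no reconciliation
of the off-by-one is attempted.)

## Synthetic scenarios and the oracle

Real-scale inputs require large downloads, so testing runs on seeded
synthetic scenarios. A scenario is a miniature genome laid out in
non-interacting 100-kb blocks, one planted link per block: the block's
enhancer (300–1200 bp, random source) and gene (TSS at a fixed block
offset, random strand, two exons) receive evidence records that *pass*
every rule for a randomly drawn assay subset — padded anchors with
p ∈ (0.0005, 0.045), in-enhancer non-exonic variants, ≥90%-containing
regions with FDR < 0.009, and (with probability 0.5) a TAD spanning both
elements. Decoy blocks each fail exactly one rule: a 49% anchor overlap, a
ChIA-PET p of exactly 0.05, an exonic eQTL, an eQTL p of exactly 0.05, an
eQTL to a non-coding gene, an 89% containment, an FDR of exactly 0.01, and
a same-TAD pair with no other support. The block spacing guarantees no
accidental cross-block geometry, so the truth table is exact by
construction. Defaults: 12 planted links, the full 8-class decoy panel, 4
unlinked genes and 8 unlinked enhancers as background.

An exhaustive-rule **oracle** independently recomputes the expected link
database from the same inputs: all-pairs scans with inline interval
arithmetic, thresholds hard-coded as integer comparisons, no interval index
and no shared linker code. The core guarantee — asserted over dozens of
seeds — is that the pipeline's database equals the oracle's exactly,
recovers exactly the planted truth, and excludes every decoy.

What the synthetic genome does **not** emulate: realistic enhancer length
and spacing distributions, overlapping gene models, chained/nested TADs,
linkage disequilibrium between variants, or assay-specific noise structure.
Passing tests therefore demonstrate that the *rules* are implemented
exactly, not that the rules are biologically optimal, and scenario-scale
statistics are not comparable to full-scale ones.

## Full-scale validations (not run here)

Several published quantities depend on the original full-scale ENCODE,
GTEx, PSYCHIC, HACER and GeneHancer downloads and are therefore documented
as optional full-scale validations rather than desk-checked results: the
source-overlap matrix, per-assay link totals, assay-combination Venn
counts, the HACER (24.8% / 97.6%) and GeneHancer (42.5% / 83.0%) catalog
comparisons, the 19.30 mean tissues per link, the tissue–assay correlation
of 0.39 (reported only with p < 2.2e-16, a software display floor, so no
chi-squared statistic value is recoverable), and the worked example mapping
variant rs143969848 to enhancer EH37E0652188 and its three target genes.
Given the original files, the same module surface computes each of these
(`source_overlap_matrix`, `per_assay_means`, `assay_combination_counts`,
`compare_catalogs`, `assay_tissue_association`, `query_variants`); the test
suite mirrors the variant worked example on a synthetic analog.

## Numerical and degenerate-input choices

* Threshold fractions are parsed from their decimal representation, so a
  caller's `0.9` means exactly 9/10 in the integer comparisons.
* Empty inputs: empty files yield empty lists with a warning; an empty
  distribution or catalog summary raises; the association test requires at
  least two distinct values on each axis.
* Evidence scores round-trip through text via `repr`, so read(write(db))
  reproduces the database exactly.
* Scenario generation draws every random quantity from a single seeded
  generator in a fixed order; identical seeds give byte-identical files.
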