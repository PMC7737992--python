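"""Loaders for the packaged published summary tables.

Two small machine-readable tables ship with the package so the headline
statistics of the full-scale build can be recomputed without downloading any
of the original source datasets:

* ``catalog_summary_by_source.tsv`` — per-source enhancer counts and mean
  element lengths of the assembled catalog.
* ``targets_per_enhancer_distribution.tsv`` — the genes-per-enhancer
  histogram of the full link set, plus the number of linked protein-coding
  genes (as a header comment), which the histogram alone does not determine.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional, Tuple

from .summary_stats import CatalogSummaryTable, TargetDistribution

CATALOG_SUMMARY_RESOURCE = "catalog_summary_by_source.tsv"
TARGET_DISTRIBUTION_RESOURCE = "targets_per_enhancer_distribution.tsv"


def _read_resource_text(name: str) -> str:
    return (resources.files("peregrine") / "data" / name).read_text(encoding="utf-8")


def _read_path_or_resource(path, resource: str) -> str:
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            return fh.read()
    return _read_resource_text(resource)


def load_catalog_summary(path=None) -> CatalogSummaryTable:
    """The per-source catalog summary (packaged copy unless a path is given)."""
    text = _read_path_or_resource(path, CATALOG_SUMMARY_RESOURCE)
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("source\t"):
            continue
        source, n, mean_len = line.split("\t")
        rows.append((source, int(n), float(mean_len)))
    return CatalogSummaryTable(rows)


def load_target_distribution(path=None) -> Tuple[TargetDistribution, Optional[int]]:
    """The genes-per-enhancer distribution and the linked-gene total.

    Returns ``(distribution, n_linked_genes)``; the gene total comes from a
    ``# linked_genes: N`` header comment and is ``None`` when absent.
    """
    text = _read_path_or_resource(path, TARGET_DISTRIBUTION_RESOURCE)
    rows = []
    n_genes: Optional[int] = None
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.startswith("linked_genes:"):
                n_genes = int(stripped.split(":", 1)[1].strip())
            continue
        if not line or line.startswith("n_target_genes\t"):
            continue
        k, n = line.split("\t")
        rows.append((int(k), int(n)))
    return TargetDistribution(rows), n_genes
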