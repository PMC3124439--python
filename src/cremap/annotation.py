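"""Functional-category over-representation per cluster.

Categories (FunCat roles or GO terms, as flat term sets) are tested for
over-representation in a gene cluster with the exact hypergeometric
upper tail: drawing the cluster's ``n`` genes from a universe of ``N``
of which ``K`` carry the category, the p-value is ``P(X >= k)`` for the
``k`` carriers observed in the cluster.  GO-style analyses additionally
apply BH FDR adjustment across the tested categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .stats import bh_adjust


@dataclass
class AnnotationCatalog:
    """Gene -> category map with its universe.

    ``universe`` defaults to the annotated genes (a category analysis
    "among annotated genes"); pass an explicit gene list to test
    against the whole genome instead.
    """

    annotated: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set(self.annotated)
        stray = set(self.annotated) - self.universe
        if stray:
            raise ValueError(f"annotated genes outside the universe: {sorted(stray)[:5]}")

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        namespace: str | None = None,
        universe=None,
    ) -> "AnnotationCatalog":
        """Build from a long TSV-style table (gene_id, category_id[, namespace])."""
        if namespace is not None and "namespace" in table.columns:
            table = table.loc[table["namespace"] == namespace]
        annotated: dict[str, set[str]] = {}
        for gene, cat in zip(table["gene_id"], table["category_id"]):
            annotated.setdefault(gene, set()).add(cat)
        return cls(annotated, set(universe) if universe is not None else set())

    @property
    def category_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for cats in self.annotated.values():
            for c in cats:
                sizes[c] = sizes.get(c, 0) + 1
        return sizes


def hypergeom_enrich(
    cluster_genes,
    catalog: AnnotationCatalog,
    mode: str = "funcat",
) -> pd.DataFrame:
    """Per-category enrichment of a cluster against the catalog universe.

    Only categories present in the cluster (k >= 1) are tested.  Returns
    a DataFrame with ``category, k, n, K, N, ratio, p`` (and ``p_adj``
    in ``go`` mode), sorted by p.  ``ratio`` is observed/expected,
    ``(k/n) / (K/N)``.
    """
    if mode not in ("funcat", "go"):
        raise ValueError("mode must be 'funcat' or 'go'")
    N = len(catalog.universe)
    if len(set(cluster_genes)) > N:
        raise ValueError("cluster larger than universe")
    cluster = set(cluster_genes) & catalog.universe
    stray = set(cluster_genes) - catalog.universe
    n = len(cluster)
    sizes = catalog.category_sizes
    counts: dict[str, int] = {}
    for g in cluster:
        for c in catalog.annotated.get(g, ()):
            counts[c] = counts.get(c, 0) + 1
    rows = []
    for cat, k in sorted(counts.items()):
        K = sizes[cat]
        if k > K or K > N:
            raise ValueError(f"inconsistent counts for category {cat!r}")
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "category": cat, "k": k, "n": n, "K": K, "N": N,
                "ratio": (k / n) / (K / N), "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=["category", "k", "n", "K", "N", "ratio", "p"])
    if mode == "go" and len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out.attrs["unannotated_cluster_genes"] = sorted(stray)
    return out.sort_values("p", ignore_index=True)
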