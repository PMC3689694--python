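"""Hypergeometric over-representation analysis with BH correction.

A generic, open stand-in for proprietary pathway tools: each category is
tested for over-representation of a gene list within a stated universe via
the upper-tail hypergeometric distribution, with Benjamini-Hochberg FDR
across categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Category -> gene-id sets, restricted to a non-empty universe."""

    categories: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")

    @classmethod
    def from_mapping(cls, categories: dict, universe) -> "GeneSetCollection":
        uni = frozenset(universe)
        restricted = {
            name: frozenset(genes) & uni for name, genes in categories.items()
        }
        return cls(categories=restricted, universe=uni)


def read_gene_sets(path, universe) -> GeneSetCollection:
    """Read category/gene pairs from a two-column TSV or a GMT file."""
    categories: dict[str, set[str]] = {}
    with open(path) as handle:
        first = handle.readline()
        handle.seek(0)
        is_gmt = len(first.rstrip("\n").split("\t")) > 2 or str(path).endswith(".gmt")
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if is_gmt:
                name, genes = parts[0], parts[2:]
            else:
                name, genes = parts[0], [parts[1]]
            if name == "category" and not is_gmt:
                continue  # header row
            categories.setdefault(name, set()).update(g for g in genes if g)
    return GeneSetCollection.from_mapping(categories, universe)


def hypergeometric_enrichment(
    gene_list, collection: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of a gene list against each category.

    Genes outside the universe are dropped with a warning.  Returns rows
    sorted by p with columns category, k, K, n, N, p, fdr.
    """
    genes = set(gene_list)
    outside = genes - collection.universe
    if outside:
        logger.warning("dropped %d list genes outside the universe", len(outside))
        genes &= collection.universe
    big_n = len(collection.universe)
    n = len(genes)
    rows = []
    for name, members in sorted(collection.categories.items()):
        big_k = len(members)
        k = len(genes & members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        rows.append({"category": name, "k": k, "K": big_k, "n": n, "N": big_n, "p": min(p, 1.0)})
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame.assign(fdr=pd.Series(dtype=float))
    frame["fdr"] = multipletests(frame["p"], method="fdr_bh")[1]
    return frame.sort_values("p", kind="stable").reset_index(drop=True)
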