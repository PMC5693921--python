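"""Over-representation statistics: hypergeometric tests, binding and network summaries.

Conventions: the hypergeometric test is upper-tailed and includes the
observed overlap, P(X >= k); percent and fold values are rounded to one
decimal only at the reporting boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeom_upper_tail",
    "lncrna_de_enrichment",
    "pathway_enrichment",
    "binding_fold_enrichment",
    "interaction_coverage",
    "percent_of",
    "read_gmt",
]


def percent_of(k: int, n: int, ndigits: int = 1) -> float:
    """Reporting helper: k as a percentage of n, rounded (e.g. 16 of 320 -> 5.0)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round(100.0 * k / n, ndigits)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K category, n draws)."""
    if not (0 <= k <= min(K, n) <= N) or n > N or K > N:
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def lncrna_de_enrichment(
    associations: dict[str, set[str]] | pd.DataFrame,
    de_genes,
    nonde_genes,
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Test each lncRNA's associated genes for enrichment in the DE set.

    The universe is the union of DE and non-DE genes; each lncRNA's
    associated genes are intersected with it.  lncRNAs with no associated
    gene in the universe are excluded (the test is undefined) with a log
    entry.  Returns one row per testable lncRNA with overlap counts, the
    upper-tail hypergeometric p, its BH adjustment across lncRNAs, and a
    ``flagged`` column (adjusted p < alpha).
    """
    de_genes, nonde_genes = set(de_genes), set(nonde_genes)
    universe = de_genes | nonde_genes
    if not universe:
        raise ValueError("empty universe: no DE or non-DE genes")
    if isinstance(associations, pd.DataFrame):
        flagged = associations[associations["flagged"]]
        associations = {
            lnc: set(grp["gene"]) for lnc, grp in flagged.groupby("lncrna")
        }
    rows = []
    for lnc, genes in sorted(associations.items()):
        in_universe = set(genes) & universe
        if not in_universe:
            logger.info("lncRNA %s has no associated genes in universe; skipped", lnc)
            continue
        k = len(in_universe & de_genes)
        rows.append(
            {
                "lncrna": lnc,
                "k": k,
                "K": len(de_genes),
                "n": len(in_universe),
                "N": len(universe),
                "p_value": hypergeom_upper_tail(
                    k, len(de_genes), len(in_universe), len(universe)
                ),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["lncrna", "k", "K", "n", "N", "p_value", "adjusted_p", "flagged"]
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    out["flagged"] = out["adjusted_p"] < alpha
    return out


def pathway_enrichment(
    query_genes,
    collection: dict[str, set[str]],
    universe,
    alpha: float = 0.05,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene list per gene set.

    Gene sets are intersected with the universe; sets reduced below
    ``min_set_size`` are skipped (logged).  BH adjustment is across sets.
    """
    universe = set(universe)
    query = set(query_genes) & universe
    if not query:
        raise ValueError("empty query after universe intersection")
    rows = []
    for name, members in sorted(collection.items()):
        members = set(members) & universe
        if len(members) < min_set_size:
            logger.info("gene set %s reduced below %d genes; skipped", name, min_set_size)
            continue
        k = len(members & query)
        rows.append(
            {
                "gene_set": name,
                "k": k,
                "K": len(members),
                "n": len(query),
                "N": len(universe),
                "p_value": hypergeom_upper_tail(
                    k, len(members), len(query), len(universe)
                ),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
        out["flagged"] = out["adjusted_p"] < alpha
    return out


def binding_fold_enrichment(
    n_bound: int, n_total: int, background_fraction: float
) -> tuple[float, float]:
    """Percent of genes bound and fold enrichment over a genome-wide background.

    Returns (percent_bound, fold), both rounded to one decimal for reporting;
    e.g. 22 bound of 30 genes against a 28.1% background gives (73.3, 2.6).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_bound <= n_total:
        raise ValueError("n_bound must lie in [0, n_total]")
    if not 0 < background_fraction <= 1:
        raise ValueError("background_fraction must lie in (0, 1]")
    percent = 100.0 * n_bound / n_total
    fold = percent / (100.0 * background_fraction)
    return percent_of(n_bound, n_total), round(fold, 1)


def interaction_coverage(genes, edges) -> tuple[int, int, int]:
    """Within-set protein-interaction coverage of a gene list.

    Edges are undirected gene-id pairs; self-loops are ignored and each
    unordered pair is counted once.  Returns (number of genes with at least
    one within-set interaction, that number as a rounded percent of the gene
    list, number of distinct within-set interactions).
    """
    gene_set = set(genes)
    if not gene_set:
        return 0, 0, 0
    within = set()
    for a, b in edges:
        if a == b or a not in gene_set or b not in gene_set:
            continue
        within.add((a, b) if a <= b else (b, a))
    touched = {g for pair in within for g in pair}
    percent = int(round(100.0 * len(touched) / len(gene_set)))
    return len(touched), percent, len(within)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file (name, description, member genes...)."""
    collection: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        collection[fields[0]] = {g for g in fields[2:] if g}
    return collection
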