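"""Gene-set over-representation: one-sided hypergeometric tail with
Benjamini-Hochberg adjustment.

For a query of n genes drawn from a universe of N, a term covering K
universe genes, and k genes in the query-term intersection, the p-value is
the exact upper tail P[X >= k] of the hypergeometric distribution,

    p = sum_{j=k}^{min(K, n)} C(K, j) C(N-K, n-j) / C(N, n),

computed by scipy's log-gamma implementation (no normal approximation).
The universe defaults to the union of all genes in the gene-set collection
when the caller does not supply one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "enrich", "common_terms"]


@dataclass
class EnrichmentResult:
    term: str
    k: int  # query ∩ term
    K: int  # term size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p: float
    p_adj: float = 1.0
    enriched: bool = False


def enrich(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
    padj_threshold: float = 0.001,
) -> list[EnrichmentResult]:
    """Over-representation of each term in the query, BH-adjusted.

    Query genes outside the universe are dropped with a warning; each term
    is intersected with the universe before testing.
    """
    sets = {term: {g.upper() for g in genes} for term, genes in gene_sets.items()}
    if universe is None:
        universe_set: set[str] = set().union(*sets.values()) if sets else set()
    else:
        universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValueError("universe is empty")
    q = {g.upper() for g in query}
    dropped = q - universe_set
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
    q &= universe_set
    N, n = len(universe_set), len(q)

    results: list[EnrichmentResult] = []
    for term in sorted(sets):
        term_genes = sets[term] & universe_set
        K = len(term_genes)
        k = len(q & term_genes)
        # upper tail P[X >= k]; k = 0 gives p = 1 exactly
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        results.append(EnrichmentResult(term=term, k=k, K=K, n=n, N=N, p=p))
    if results:
        _, p_adj, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, q_val in zip(results, p_adj):
            r.p_adj = float(q_val)
            r.enriched = r.p_adj < padj_threshold
    return results


def common_terms(
    enrich_a: Sequence[EnrichmentResult],
    enrich_b: Sequence[EnrichmentResult],
) -> list[tuple[str, float, float]]:
    """Terms enriched in both analyses, with both adjusted p-values.

    Used to intersect interactome and targetome enrichments, highlighting
    processes a factor both binds near and physically associates with.
    """
    a = {r.term: r.p_adj for r in enrich_a if r.enriched}
    b = {r.term: r.p_adj for r in enrich_b if r.enriched}
    return [(t, a[t], b[t]) for t in sorted(set(a) & set(b))]
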