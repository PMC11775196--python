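"""Gene-set over-representation of an interactome, and terms shared with a
targetome enrichment.

Uses a toy annotation of 60 genes in six sets; the query deliberately
concentrates in one complex so a single term comes out enriched.
"""

from nfiomics.enrichment import common_terms, enrich

universe = [f"G{i:02d}" for i in range(60)]
gene_sets = {f"SET{j}": universe[j * 10 : (j + 1) * 10] for j in range(6)}

interactome_query = universe[0:8] + universe[20:22]   # 8 of 10 genes from SET0
targetome_query = universe[2:10] + universe[30:32]    # 8 of 10 genes from SET0

ia = enrich(interactome_query, gene_sets, padj_threshold=0.05)
ta = enrich(targetome_query, gene_sets, padj_threshold=0.05)

print("interactome enrichment (hypergeometric upper tail, BH-adjusted):")
for r in sorted(ia, key=lambda r: r.p):
    flag = "*" if r.enriched else " "
    print(f" {flag} {r.term}: k={r.k}/K={r.K} in query of n={r.n} from N={r.N}, "
          f"p={r.p:.2e}, p_adj={r.p_adj:.2e}")
print("k is the query/term intersection; * marks terms below the adjusted-p cut.")

shared = common_terms(ia, ta)
print("\nterms enriched in both interactome and targetome:")
for term, pa, pb in shared:
    print(f"  {term}: p_adj {pa:.2e} (interactome) / {pb:.2e} (targetome)")
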