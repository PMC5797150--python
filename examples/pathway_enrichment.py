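"""Hypergeometric over-representation with BH control and coverage.

A query protein set is tested against a small pathway collection; a pathway
is significant when its BH-adjusted p-value is below 0.1 AND the query
covers more than 10% of its members.
"""

from polyphenome import PathwayGeneSet, category_summary, enrich

universe = [f"G{i:03d}" for i in range(60)]
gene_sets = [
    PathwayGeneSet("PW0", "xenobiotic metabolism", frozenset(universe[:12]),
                   "Metabolism", "Xenobiotics Biodegradation"),
    PathwayGeneSet("PW1", "insulin signalling", frozenset(universe[12:40]),
                   "Human Diseases", "Endocrine and Metabolic Diseases"),
    PathwayGeneSet("PW2", "cardiac contraction", frozenset(universe[40:]),
                   "Human Diseases", "Cardiovascular Diseases"),
]
query = universe[:10]  # 10 of PW0's 12 members

results = enrich(query, gene_sets, universe=universe, query_label="flavonoids")
print(f"{'pathway':6s} {'k/K':>6s} {'p_raw':>10s} {'p_bh':>10s} {'coverage':>9s}  significant")
for r in results:
    print(f"{r.pathway_id:6s} {r.k:>2d}/{r.K:<3d} {r.p_raw:>10.3g} {r.p_bh:>10.3g} "
          f"{r.coverage:>9.2f}  {r.significant}")

summary = category_summary(results, gene_sets)
for cat, row in summary.items():
    print(f"{cat}: {row['percent_enriched']:.0f}% of {row['n_pathways']} pathway(s) enriched")
# 'CMD' is the cardiometabolic roll-up: the union of the cardiovascular and
# endocrine/metabolic disease subcategories.
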