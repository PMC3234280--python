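"""Hypergeometric over-representation of a feature class in gene sets.

Builds a toy universe of 60 analyzable genes, a feature class of 10, and two
gene sets — one enriched for the class, one not — and prints the exact
hypergeometric tail p-values with BH correction.
"""

from tsog import GeneSetCollection, hypergeometric_enrichment
from tsog.enrichment import enrichment_to_frame

universe = [f"G{i:03d}" for i in range(60)]
feature_class = universe[:10]

gene_sets = GeneSetCollection({
    "cell_cycle": ("enriched set", frozenset(universe[:8] + universe[40:44])),
    "adhesion": ("background set", frozenset(universe[30:42])),
})

records = hypergeometric_enrichment(feature_class, gene_sets, universe,
                                    fdr_level=0.05)
print(enrichment_to_frame(records).to_string(index=False))
# 'cell_cycle' holds 8 of the 10 class genes against a 12/60 universe share:
# P(X >= 8) under Hypergeometric(N=60, K=12, n=10) is tiny, while 'adhesion'
# contains none of them and scores p = 1.
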