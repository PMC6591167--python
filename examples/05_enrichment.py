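"""Hypergeometric enrichment of a gene set against a GMT-style collection.

The modified (DAVID-style) p-value substitutes x-1 and n1-1 into the
hypergeometric tail, which makes single-gene overlaps never significant.
"""

import numpy as np

from dnbkit import enrich, fisher_p, fisher_p_modified

print("classic  p(N=10, n1=5, n2=5, x=5) =", round(fisher_p(10, 5, 5, 5), 6))
print("modified p(N=10, n1=5, n2=5, x=5) =", round(fisher_p_modified(10, 5, 5, 5), 6))
print("modified p for a single-gene overlap:", fisher_p_modified(1000, 50, 30, 1))

rng = np.random.default_rng(0)
universe = [f"G{i:04d}" for i in range(2000)]
target = set(universe[:50])
collection = {"relevant_pathway": set(universe[:40]) | set(rng.choice(universe[50:], 20, replace=False))}
for k in range(20):
    collection[f"unrelated_set_{k:02d}"] = set(rng.choice(universe, 60, replace=False))

table = enrich(target, collection, universe_size=2000)
print("\ntop enriched sets (filter: modified p <= 0.05, overlap >= 2):")
print(table[["name", "n2", "x", "p_modified", "rank"]].to_string(index=False))
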