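"""Exploratory structure: PCA + parallel analysis, gene clustering,
the DNB-contrast dissimilarity and the fluctuation map."""

from dnbkit import (
    SyntheticConfig,
    cluster_genes,
    dnb_dissimilarity,
    fluctuation_map,
    generate_dataset,
    parallel_analysis,
)

config = SyntheticConfig(
    n_genes=300, n_dnb=30, n_deg_clusters=2, deg_cluster_size=25,
    deg_onset_week=4, replicates=8, seed=9,
)
dataset, truth = generate_dataset(config)

# how many PCs exceed the 95th percentile of within-gene shuffled data?
pa = parallel_analysis(dataset, n_shuffles=100, seed=0)
print("meaningful principal components:", pa.n_meaningful)
print("leading eigenvalues:", pa.eigenvalues[:4].round(2))
print("their shuffled 95th percentiles:", pa.null_percentiles[:4].round(2))

# average-linkage clustering of the planted DE genes at 1-r dissimilarity 0.5:
# the up- and down-shifted clusters separate
clusters = cluster_genes(dataset.values.loc[truth.all_deg_gene_ids], cutoff=0.5)
print("cluster sizes (descending):", clusters.sizes)

# genes tightly correlated in the 5-week case slice but not in the control
# slice get small dissimilarity 1 - |r| + |r'| (used for t-SNE layout)
d = dnb_dissimilarity(
    dataset.condition_slice("case", 5), dataset.condition_slice("control", 5)
)
import numpy as np

module = truth.dnb_gene_ids
within = d.loc[module, module].to_numpy()
off_diagonal = within[~np.eye(len(module), dtype=bool)]
print(f"mean dissimilarity within the planted module: {off_diagonal.mean():.2f}")
print(f"overall mean dissimilarity: {d.to_numpy().mean():.2f}")

# per-condition SD of the module genes: the fluctuation hot-spot sits at
# (case, week 5)
fluct = fluctuation_map(dataset, truth.dnb_gene_ids)
print("condition with the largest mean SD:", fluct.mean(axis=0).idxmax())
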