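"""Exploratory views of the dataset: PCA with parallel analysis,
correlation-based gene clustering, the DNB-contrast dissimilarity for 2-D
embedding, and the spatio-temporal fluctuation map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .datasets import ConditionSlice, ExpressionDataset

__all__ = [
    "PCAResult",
    "ClusterResult",
    "pca",
    "parallel_analysis",
    "cluster_genes",
    "dnb_dissimilarity",
    "tsne_embed",
    "fluctuation_map",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    eigenvalues: np.ndarray  # sample-covariance eigenvalues, non-increasing
    explained_variance_ratio: np.ndarray
    n_meaningful: int | None = None
    null_percentiles: np.ndarray | None = None


def pca(dataset: ExpressionDataset) -> PCAResult:
    """Mean-centered PCA over samples (genes are features).

    Eigenvalues are those of the sample covariance matrix (K-1
    denominator), equivalently squared singular values of the centered
    samples x genes matrix divided by (n_samples - 1).
    """
    if dataset.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    model = PCA()
    scores = model.fit_transform(dataset.values.to_numpy().T)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=dataset.values.columns, columns=cols),
        eigenvalues=model.explained_variance_,
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def _eigenvalues(matrix_genes_by_samples: np.ndarray) -> np.ndarray:
    x = matrix_genes_by_samples.T
    x = x - x.mean(axis=0, keepdims=True)
    s = np.linalg.svd(x, compute_uv=False)
    return s**2 / (x.shape[0] - 1)


def shuffle_within_genes(arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each gene's values across samples, independently per gene."""
    idx = rng.permuted(np.tile(np.arange(arr.shape[1]), (arr.shape[0], 1)), axis=1)
    return np.take_along_axis(arr, idx, axis=1)


def parallel_analysis(
    dataset: ExpressionDataset,
    n_shuffles: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> PCAResult:
    """Estimate the number of meaningful PCs by a shuffling null.

    Each gene's values are permuted across samples independently (this
    destroys inter-gene correlation while preserving every gene's value
    multiset); eigenvalues of each shuffled matrix are collected and the
    requested percentile taken per eigenvalue rank.  The number of
    original eigenvalues exceeding their rank-matched null percentile is
    reported as ``n_meaningful``.
    """
    if n_shuffles < 10:
        raise ValueError("parallel analysis needs at least 10 shuffles")
    result = pca(dataset)
    arr = dataset.values.to_numpy()
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, len(result.eigenvalues)))
    for b in range(n_shuffles):
        ev = _eigenvalues(shuffle_within_genes(arr, rng))
        null[b] = ev[: null.shape[1]]
    perc = np.percentile(null, percentile, axis=0)
    result.null_percentiles = perc
    result.n_meaningful = int((result.eigenvalues > perc).sum())
    return result


@dataclass
class ClusterResult:
    labels: pd.Series  # gene -> cluster id (1 = largest)
    sizes: list  # cluster sizes, descending
    linkage: np.ndarray
    zscored: pd.DataFrame


def cluster_genes(values: pd.DataFrame, cutoff: float = 0.5) -> ClusterResult:
    """Average-linkage clustering of genes under the 1 - r dissimilarity.

    Rows are z-scored first (the dynamic range of expression is large);
    flat clusters are cut at the given inter-cluster dissimilarity and
    relabeled so that cluster 1 is the largest.
    """
    if values.shape[0] < 2:
        raise ValueError("clustering needs at least 2 genes")
    sds = values.std(axis=1, ddof=1)
    if (sds == 0).any():
        bad = list(values.index[sds == 0])[:5]
        raise ValueError(f"zero-variance genes cannot be z-scored: {bad}")
    z = values.sub(values.mean(axis=1), axis=0).div(sds, axis=0)
    r = np.corrcoef(z.to_numpy())
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cutoff, criterion="distance")
    order = pd.Series(raw).value_counts().index  # descending by size
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=values.index, name="cluster")
    sizes = labels.value_counts().sort_index().tolist()
    return ClusterResult(labels=labels, sizes=sorted(sizes, reverse=True), linkage=link, zscored=z)


def dnb_dissimilarity(case: ConditionSlice, control: ConditionSlice) -> pd.DataFrame:
    """Gene-gene dissimilarity d_ij = 1 - |r_ij(case)| + |r'_ij(control)|.

    Genes tightly correlated in the case condition but not in the control
    are close (d -> 0); d ranges over [0, 2] and the diagonal is 1 by the
    formula (it is zeroed before embedding).
    """
    if case.n_samples < 3 or control.n_samples < 3:
        raise ValueError("dissimilarity needs >= 3 samples per slice")
    if not case.gene_ids.equals(control.gene_ids):
        raise ValueError("slices must share the same gene universe")
    ra = np.abs(np.corrcoef(case.values.to_numpy()))
    rb = np.abs(np.corrcoef(control.values.to_numpy()))
    d = np.clip(1.0 - ra + rb, 0.0, 2.0)
    return pd.DataFrame(d, index=case.gene_ids, columns=case.gene_ids)


def tsne_embed(
    dissimilarity: pd.DataFrame,
    perplexity: float = 100.0,
    early_exaggeration: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D t-SNE of a precomputed dissimilarity (self-terms zeroed).

    Axes are not individually interpretable: the embedding objective is
    invariant under rotations and reflections of the plane.
    """
    from sklearn.manifold import TSNE

    d = dissimilarity.to_numpy().copy()
    np.fill_diagonal(d, 0.0)
    perplexity = min(perplexity, (d.shape[0] - 1) / 3.0)
    model = TSNE(
        n_components=2,
        metric="precomputed",
        perplexity=perplexity,
        early_exaggeration=early_exaggeration,
        init="random",
        random_state=seed,
    )
    coords = model.fit_transform(d)
    return pd.DataFrame(coords, index=dissimilarity.index, columns=["dim1", "dim2"])


def fluctuation_map(dataset: ExpressionDataset, gene_ids) -> pd.DataFrame:
    """Per-gene sample SD in every (group, week) slice, for heatmap export."""
    gene_ids = list(gene_ids)
    cols = {}
    for Z in dataset.iter_conditions():
        cols[(Z.group, Z.week)] = Z.restrict(gene_ids).sds()
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["group", "week"])
    return table
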