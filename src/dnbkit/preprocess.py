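"""Probe-level intensities -> normalized log2 gene-level matrix.

Pipeline order: probes without a gene-symbol annotation are removed and
multi-probe genes are collapsed by the per-sample arithmetic mean of raw
intensities; each sample column is then divided by its 2% trimmed mean
(the mean after discarding the lowest 2% and highest 2% of values); the
normalized values are base-2 log-transformed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, ProbeDataset

__all__ = [
    "collapse_probes",
    "trimmed_mean_normalize",
    "log2_transform",
    "preprocess",
    "read_series_matrix",
]


def collapse_probes(probes: ProbeDataset) -> pd.DataFrame:
    """Drop unannotated probes and average multi-probe genes.

    Returns a raw-intensity genes x samples frame keyed by gene symbol,
    gene rows sorted lexicographically for reproducible indices.
    """
    annotated = probes.annotation[probes.annotation != ""]
    if annotated.empty:
        raise ValueError("no annotated probes: collapsing would produce an empty matrix")
    sub = probes.values.loc[annotated.index]
    collapsed = sub.groupby(annotated).mean()
    return collapsed.sort_index()


def _trimmed_mean(column: np.ndarray, trim_frac: float) -> float:
    # trim count per side = floor(trim_frac * n), applied per observation
    n = column.size
    k = math.floor(trim_frac * n)
    ordered = np.sort(column)
    kept = ordered[k : n - k] if k > 0 else ordered
    return float(kept.mean())


def trimmed_mean_normalize(matrix: pd.DataFrame, trim_frac: float = 0.02) -> pd.DataFrame:
    """Divide each sample column by its trimmed mean."""
    arr = matrix.to_numpy(dtype=float)
    factors = np.array([_trimmed_mean(arr[:, j], trim_frac) for j in range(arr.shape[1])])
    bad = np.nonzero(factors <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive trimmed mean in sample(s) {list(matrix.columns[bad])}"
        )
    return matrix / factors


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise base-2 logarithm; every entry must be positive."""
    arr = matrix.to_numpy(dtype=float)
    bad = np.argwhere(arr <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value at gene {matrix.index[i]!r}, sample "
            f"{matrix.columns[j]!r}: log2 undefined"
        )
    return pd.DataFrame(np.log2(arr), index=matrix.index, columns=matrix.columns)


def preprocess(probes: ProbeDataset, trim_frac: float = 0.02) -> ExpressionDataset:
    """Collapse -> trimmed-mean normalize -> log2."""
    collapsed = collapse_probes(probes)
    normalized = trimmed_mean_normalize(collapsed, trim_frac)
    values = log2_transform(normalized)
    return ExpressionDataset(values, probes.sample_meta.copy())


def read_series_matrix(path, sample_meta: pd.DataFrame, annotation: pd.Series) -> ProbeDataset:
    """Read the data-table block of a GEO series-matrix text file.

    Only the ``!series_matrix_table_begin`` .. ``!series_matrix_table_end``
    block is parsed (probe ids in the first column, sample accessions in
    the header row); metadata lines are ignored.  The caller supplies the
    sample metadata and probe annotation, which GEO stores separately.
    """
    rows, header, inside = [], None, False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if not inside or not line:
                continue
            parts = [p.strip('"') for p in line.split("\t")]
            if header is None:
                header = parts[1:]
            else:
                rows.append((parts[0], [float(x) for x in parts[1:]]))
    if header is None:
        raise ValueError(f"no series-matrix table found in {path}")
    values = pd.DataFrame(
        [r[1] for r in rows], index=[r[0] for r in rows], columns=header
    )
    return ProbeDataset(values, annotation, sample_meta)
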