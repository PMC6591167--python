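"""Core data containers for time-course, two-group expression data.

The pipeline's universe is a log2-normalized genes x samples matrix with
per-sample (group, week) labels.  All condition-restricted statistics
(means, standard deviations, correlations) are computed on a
:class:`ConditionSlice`, the submatrix of samples sharing one
(group, week) label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "ProbeDataset",
    "ConditionSlice",
]


def _ordered_unique(values: Sequence) -> list:
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


@dataclass
class ConditionSlice:
    """Expression submatrix for one (group, week) condition.

    Parameters
    ----------
    values
        genes x samples log2 expression, restricted to the condition.
    group, week
        Condition labels.
    """

    values: pd.DataFrame
    group: object
    week: object

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def means(self) -> pd.Series:
        return self.values.mean(axis=1)

    def sds(self) -> pd.Series:
        """Per-gene sample standard deviation (K-1 denominator)."""
        return self.values.std(axis=1, ddof=1)

    def drop_sample(self, sample_id: str) -> "ConditionSlice":
        return ConditionSlice(
            self.values.drop(columns=sample_id), self.group, self.week
        )

    def restrict(self, gene_ids) -> "ConditionSlice":
        return ConditionSlice(self.values.loc[list(gene_ids)], self.group, self.week)


@dataclass
class ExpressionDataset:
    """Log2-normalized genes x samples matrix with sample metadata.

    ``sample_meta`` is indexed by sample id and carries ``group`` and
    ``week`` columns; every column of ``values`` must have a metadata row.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        missing = self.values.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.sample_meta = self.sample_meta.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list:
        return _ordered_unique(self.sample_meta["group"])

    @property
    def weeks(self) -> list:
        return _ordered_unique(self.sample_meta["week"])

    def condition_slice(self, group, week) -> ConditionSlice:
        mask = (self.sample_meta["group"] == group) & (
            self.sample_meta["week"] == week
        )
        ids = self.sample_meta.index[mask]
        if len(ids) == 0:
            raise KeyError(f"no samples for condition (group={group}, week={week})")
        return ConditionSlice(self.values[ids], group, week)

    def iter_conditions(self) -> Iterator[ConditionSlice]:
        for group in self.groups:
            for week in self.weeks:
                yield self.condition_slice(group, week)

    # ------------------------------------------------------------------ I/O
    def to_files(self, matrix_path, meta_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        self.sample_meta.to_csv(meta_path, index_label="sample_id")

    @classmethod
    def from_files(cls, matrix_path, meta_path) -> "ExpressionDataset":
        matrix_path, meta_path = Path(matrix_path), Path(meta_path)
        if not matrix_path.exists():
            raise FileNotFoundError(f"expression matrix not found: {matrix_path}")
        if not meta_path.exists():
            raise FileNotFoundError(f"sample metadata not found: {meta_path}")
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, index_col=0)
        return cls(values, meta)


@dataclass
class ProbeDataset:
    """Raw probe-level intensities plus probe -> gene-symbol annotation.

    ``annotation`` maps probe id to gene symbol; an empty string (or NaN)
    means the probe carries no gene annotation and is dropped during
    preprocessing.
    """

    values: pd.DataFrame
    annotation: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("probe ids must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("probe intensities must be finite")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("probe intensities must be non-negative")
        missing = self.values.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        self.annotation = self.annotation.reindex(self.values.index).fillna("")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def to_files(self, matrix_path, annotation_path, meta_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
        self.annotation.rename("gene_symbol").to_csv(
            annotation_path, sep="\t", index_label="probe_id"
        )
        self.sample_meta.to_csv(meta_path, index_label="sample_id")

    @classmethod
    def from_files(cls, matrix_path, annotation_path, meta_path) -> "ProbeDataset":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        ann = pd.read_csv(
            annotation_path, sep="\t", index_col=0, keep_default_na=False
        )["gene_symbol"]
        meta = pd.read_csv(meta_path, index_col=0)
        return cls(values, ann, meta)
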