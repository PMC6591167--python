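"""Differentially expressed genes per time point.

A gene is a DEG at a given week when it passes BOTH filters against the
control group at that week:

* fold change — the absolute difference of the log2 group means exceeds a
  threshold (default 1, i.e. more than a two-fold change on the raw
  scale; the boundary itself is excluded), and
* testing — a two-tailed Welch t-test on the log2 values is rejected
  after Benjamini-Hochberg adjustment at level q (default 0.05).

The per-week sets, their union and the gene x week incidence pattern are
collected in :class:`DEGResult`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import ConditionSlice, ExpressionDataset

__all__ = [
    "DEGResult",
    "fold_change_candidates",
    "welch_test",
    "bh_reject",
    "extract_degs",
]


@dataclass
class DEGResult:
    per_week: dict  # week -> per-gene stats table
    sets: dict  # week -> sorted DEG gene list
    union: list  # sorted union of all per-week sets
    incidence: pd.DataFrame  # union genes x weeks, boolean

    def counts(self) -> dict:
        return {week: len(genes) for week, genes in self.sets.items()}


def fold_change_candidates(
    X: ConditionSlice, Y: ConditionSlice, fc_log2: float = 1.0
) -> pd.Index:
    """Genes whose log2 group means differ by strictly more than ``fc_log2``."""
    if not X.gene_ids.equals(Y.gene_ids):
        raise ValueError("condition slices must share the same gene universe")
    diff = (X.means() - Y.means()).abs()
    return X.gene_ids[diff.to_numpy() > fc_log2]


def welch_test(x, y) -> tuple[float, float]:
    """Two-tailed Welch t-test (unequal variances, Welch-Satterthwaite df).

    Both groups constant and equal returns (0, 1) so the gene universe
    stays stable; a zero-df configuration (fewer than 2 values per group)
    is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch test needs at least 2 values per group")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return np.inf if x.mean() > y.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def bh_reject(pvals, q: float = 0.05) -> np.ndarray:
    """Standard Benjamini-Hochberg step-up rejections at FDR level q."""
    pvals = np.asarray(pvals, dtype=float)
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(pvals, alpha=q, method="fdr_bh")[0]


def _welch_vectorized(xmat: np.ndarray, ymat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t, p = stats.ttest_ind(xmat, ymat, axis=1, equal_var=False)
    # degenerate rows (zero variance in both groups): scipy yields nan
    vx = xmat.var(axis=1, ddof=1)
    vy = ymat.var(axis=1, ddof=1)
    degenerate = (vx == 0) & (vy == 0)
    if degenerate.any():
        equal = degenerate & (xmat.mean(axis=1) == ymat.mean(axis=1))
        unequal = degenerate & ~equal
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        sign = np.sign(xmat.mean(axis=1) - ymat.mean(axis=1))
        t = np.where(unequal, sign * np.inf, t)
        p = np.where(unequal, 0.0, p)
    return t, p


def extract_degs(
    dataset: ExpressionDataset,
    q: float = 0.05,
    fc_log2: float = 1.0,
    case_group=None,
    control_group=None,
) -> DEGResult:
    """Per-week DEG extraction: fold-change candidates ∩ BH-rejected Welch tests.

    BH adjustment is applied per week across genes.  Groups default to the
    first (case) and second (control) labels in the dataset metadata.
    """
    groups = dataset.groups
    if case_group is None:
        case_group = groups[0]
    if control_group is None:
        control_group = groups[1]

    per_week, sets = {}, {}
    for week in dataset.weeks:
        X = dataset.condition_slice(case_group, week)
        Y = dataset.condition_slice(control_group, week)
        diff = X.means() - Y.means()
        t, p = _welch_vectorized(X.values.to_numpy(), Y.values.to_numpy())
        rejected = bh_reject(p, q)
        fc_hit = diff.abs().to_numpy() > fc_log2
        deg = fc_hit & rejected
        table = pd.DataFrame(
            {
                "mean_diff_log2": diff,
                "welch_t": t,
                "p_value": p,
                "fc_candidate": fc_hit,
                "rejected": rejected,
                "deg": deg,
            },
            index=dataset.gene_ids,
        )
        per_week[week] = table
        genes = sorted(dataset.gene_ids[deg])
        sets[week] = genes
        assert set(genes) == (set(dataset.gene_ids[fc_hit]) & set(dataset.gene_ids[rejected]))

    union = sorted(set().union(*sets.values())) if sets else []
    incidence = pd.DataFrame(
        {week: [g in set(sets[week]) for g in union] for week in dataset.weeks},
        index=union,
        dtype=bool,
    )
    return DEGResult(per_week=per_week, sets=sets, union=union, incidence=incidence)
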