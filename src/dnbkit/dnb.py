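"""Dynamical-network-biomarker selection and early-warning scores.

A DNB is a small gene group that, just before a critical transition
(healthy -> disease), collectively shows unusually large fluctuations and
strong mutual correlations.  Given a case condition X (K samples), a
control condition Y (L samples) and the full gene universe S0, candidates
are selected in three steps:

1. rank all genes by the SD ratio v1_i = s_i(X)/s_i(Y) and keep the top
   theta1 % as S1 (genes with large increases in fluctuation);
2. within S1, rank by the summed change of absolute correlation strength
   v2_i = sum_{j in S1} (|r_ij(X)| - |r_ij(Y)|) and keep the top theta2 %
   as S2 (genes that became strongly correlated within the module);
3. within S1, rank by the same sum taken over genes OUTSIDE S1,
   v3_i = sum_{j in S0 \\ S1} (|r_ij(X)| - |r_ij(Y)|), and mark the top
   theta3 % as S3 (non-specific correlation gainers).

The DNB candidate set is S* = S2 \\ S3.  Its early-warning behavior is
scored per condition slice Z (M samples) by the average SD
I_s = mean_i s_i(Z) and the average correlation strength
I_r = mean_{i<j} |r_ij(Z)| - c(M), where c(M) is the expected |Pearson r|
of two independent standard-normal samples of size M (the small-sample
null bias; c(4) = 0.50, c(5) = 4/(3*pi) ~ 0.42).

All SDs and correlations use the K-1 denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import special, stats

from .datasets import ConditionSlice, ExpressionDataset

__all__ = [
    "DNBSelection",
    "DNBScoreSeries",
    "variance_ratio",
    "top_fraction",
    "correlation_gain_within",
    "nonspecific_gain_outside",
    "select_dnb",
    "correction_term",
    "correction_term_mc",
    "score_is",
    "score_ir",
    "score_series",
    "sweep_parameters",
    "leave_one_out",
    "control_swap",
    "relative_recovery_rate",
]


# --------------------------------------------------------------- primitives
def _abs_corr(rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """|Pearson r| between each row of ``rows_a`` and each row of ``rows_b``.

    Constant rows have undefined correlation; their entries are set to 0
    so they contribute nothing to the correlation-gain sums.
    """
    k = rows_a.shape[1]
    za = rows_a - rows_a.mean(axis=1, keepdims=True)
    zb = rows_b - rows_b.mean(axis=1, keepdims=True)
    sa = np.sqrt((za**2).sum(axis=1))
    sb = np.sqrt((zb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (za @ zb.T) / np.outer(sa, sb)
    r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
    return np.minimum(np.abs(r), 1.0)


def variance_ratio(X: ConditionSlice, Y: ConditionSlice) -> tuple[pd.Series, pd.Index]:
    """Per-gene SD ratio s_i(X)/s_i(Y), with degenerate genes excluded.

    Returns ``(v1, excluded)`` where ``excluded`` lists genes with zero
    sample SD in X or Y, for which the ratio is undefined or degenerate.
    """
    if not X.gene_ids.equals(Y.gene_ids):
        raise ValueError("slices must share the same gene universe")
    sx, sy = X.sds(), Y.sds()
    bad = (sx == 0) | (sy == 0)
    v1 = (sx[~bad] / sy[~bad]).rename("v1")
    return v1, X.gene_ids[bad]


def top_fraction(scores: pd.Series, theta: float) -> pd.Index:
    """Indices of the highest theta % scores.

    The selected count is ``max(1, floor(theta/100 * n))``; ties at the
    cutoff are broken by ascending gene-id order so selections are
    deterministic.  Returned index is sorted by gene id.
    """
    if not 0 < theta <= 100:
        raise ValueError("theta must lie in (0, 100]")
    n_sel = max(1, math.floor(theta / 100.0 * len(scores)))
    ordered = scores.sort_index().sort_values(ascending=False, kind="stable")
    return pd.Index(sorted(ordered.index[:n_sel]))


def correlation_gain_within(
    X: ConditionSlice, Y: ConditionSlice, s1: pd.Index
) -> pd.Series:
    """v2_i = sum over j in S1 of (|r_ij(X)| - |r_ij(Y)|), i in S1.

    The self-term is included as written in the defining sum; it
    contributes 0 because |r_ii| = 1 in both conditions.
    """
    if len(s1) < 2:
        raise ValueError("S1 must contain at least 2 genes")
    ax = _abs_corr(X.restrict(s1).values.to_numpy(), X.restrict(s1).values.to_numpy())
    ay = _abs_corr(Y.restrict(s1).values.to_numpy(), Y.restrict(s1).values.to_numpy())
    return pd.Series((ax - ay).sum(axis=1), index=s1, name="v2")


def nonspecific_gain_outside(
    X: ConditionSlice, Y: ConditionSlice, s1: pd.Index
) -> pd.Series:
    """v3_i = sum over j outside S1 of (|r_ij(X)| - |r_ij(Y)|), i in S1."""
    outside = X.gene_ids.difference(s1)
    if len(outside) == 0:
        raise ValueError("S0 \\ S1 is empty: no outside genes to sum over")
    ax = _abs_corr(
        X.restrict(s1).values.to_numpy(), X.restrict(outside).values.to_numpy()
    )
    ay = _abs_corr(
        Y.restrict(s1).values.to_numpy(), Y.restrict(outside).values.to_numpy()
    )
    return pd.Series((ax - ay).sum(axis=1), index=s1, name="v3")


# ---------------------------------------------------------------- selection
@dataclass
class DNBSelection:
    """Nested index sets of the three-step selection with their statistics."""

    s0: pd.Index
    s1: pd.Index
    s2: pd.Index
    s3: pd.Index
    s_star: pd.Index
    v1: pd.Series
    v2: pd.Series
    v3: pd.Series
    thetas: tuple
    excluded: pd.Index  # zero-SD genes left out of the v1 ranking

    def __post_init__(self) -> None:
        assert self.s1.isin(self.s0).all()
        assert self.s2.isin(self.s1).all() and self.s3.isin(self.s1).all()
        assert self.s_star.equals(self.s2.difference(self.s3))

    @property
    def is_empty(self) -> bool:
        return len(self.s_star) == 0

    def summary(self) -> dict:
        return {
            "theta1": self.thetas[0],
            "theta2": self.thetas[1],
            "theta3": self.thetas[2],
            "n_s0": len(self.s0),
            "n_s1": len(self.s1),
            "n_s2": len(self.s2),
            "n_s3": len(self.s3),
            "n_s_star": len(self.s_star),
            "n_excluded": len(self.excluded),
        }


def select_dnb(
    X: ConditionSlice,
    Y: ConditionSlice,
    theta1: float = 10.0,
    theta2: float = 50.0,
    theta3: float = 80.0,
) -> DNBSelection:
    """Run the three-step selection; an empty S* is a valid outcome."""
    if X.n_samples < 3 or Y.n_samples < 3:
        raise ValueError("correlation-based selection needs >= 3 samples per slice")
    v1, excluded = variance_ratio(X, Y)
    s1 = top_fraction(v1, theta1)
    v2 = correlation_gain_within(X, Y, s1)
    v3 = nonspecific_gain_outside(X, Y, s1)
    s2 = top_fraction(v2, theta2)
    s3 = top_fraction(v3, theta3)
    return DNBSelection(
        s0=X.gene_ids,
        s1=s1,
        s2=s2,
        s3=s3,
        s_star=s2.difference(s3),
        v1=v1,
        v2=v2,
        v3=v3,
        thetas=(theta1, theta2, theta3),
        excluded=excluded,
    )


# ------------------------------------------------------------------- scores
def correction_term(m: int) -> float:
    """E|r| for two independent standard-normal samples of size m.

    The null density of Pearson r is proportional to
    (1 - r^2)^((m-4)/2) on [-1, 1]; integrating |r| against it gives
    c(m) = 2 / ((m-2) * B(1/2, (m-2)/2)).  c(4) = 1/2 exactly and
    c(5) = 4/(3*pi); c decreases to 0 as m grows.
    """
    if m < 3:
        raise ValueError("correction term requires sample size >= 3")
    return float(2.0 / ((m - 2) * special.beta(0.5, (m - 2) / 2.0)))


def correction_term_mc(m: int, n_pairs: int = 1_000_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of c(m): mean |r| over independent normal pairs."""
    rng = np.random.default_rng(seed)
    total, done, chunk = 0.0, 0, 200_000
    while done < n_pairs:
        b = min(chunk, n_pairs - done)
        x = rng.standard_normal((b, m))
        y = rng.standard_normal((b, m))
        x = x - x.mean(axis=1, keepdims=True)
        y = y - y.mean(axis=1, keepdims=True)
        r = (x * y).sum(axis=1) / np.sqrt((x**2).sum(axis=1) * (y**2).sum(axis=1))
        total += np.abs(r).sum()
        done += b
    return total / n_pairs


def score_is(Z: ConditionSlice, s_star) -> float:
    """I_s: average sample SD of the candidate genes in slice Z."""
    s_star = pd.Index(s_star)
    if len(s_star) == 0:
        raise ValueError("S* is empty")
    return float(Z.restrict(s_star).sds().mean())


def score_ir(Z: ConditionSlice, s_star, correction: float | None = None) -> float:
    """I_r: average |pairwise r| of the candidate genes minus c(M)."""
    s_star = pd.Index(s_star)
    if len(s_star) < 2:
        raise ValueError("I_r needs at least 2 genes")
    if Z.n_samples < 3:
        raise ValueError("I_r needs at least 3 samples")
    c = correction_term(Z.n_samples) if correction is None else correction
    a = _abs_corr(Z.restrict(s_star).values.to_numpy(), Z.restrict(s_star).values.to_numpy())
    iu = np.triu_indices(len(s_star), k=1)
    return float(a[iu].mean() - c)


@dataclass
class DNBScoreSeries:
    """I_s / I_r per (group, week) condition — the early-warning curves."""

    table: pd.DataFrame  # MultiIndex (group, week); columns I_s, I_r, M, c

    def for_group(self, group) -> pd.DataFrame:
        return self.table.loc[group]

    def peak_week(self, group, score: str = "I_s"):
        return self.for_group(group)[score].idxmax()


def score_series(dataset: ExpressionDataset, s_star) -> DNBScoreSeries:
    """Evaluate I_s and I_r on every (group, week) slice of the dataset."""
    rows = []
    for Z in dataset.iter_conditions():
        c = correction_term(Z.n_samples)
        rows.append(
            {
                "group": Z.group,
                "week": Z.week,
                "I_s": score_is(Z, s_star),
                "I_r": score_ir(Z, s_star, correction=c),
                "M": Z.n_samples,
                "c": c,
            }
        )
    table = pd.DataFrame(rows).set_index(["group", "week"])
    return DNBScoreSeries(table)


# -------------------------------------------------------------- diagnostics
def _sharpness(series: pd.Series, target_week) -> float:
    """(score at target - best other week) / (spread across weeks)."""
    spread = series.max() - series.min()
    if spread == 0 or target_week not in series.index:
        return float("nan")
    others = series.drop(index=target_week)
    return float((series[target_week] - others.max()) / spread)


def sweep_parameters(
    X: ConditionSlice,
    Y: ConditionSlice,
    dataset: ExpressionDataset,
    theta1_grid,
    theta2_grid,
    theta3_grid,
    target_week,
    group=None,
) -> pd.DataFrame:
    """Score every theta-triple by peak sharpness at the target week.

    For each triple the selection is re-run and I_s/I_r series computed on
    the given group (default: the case group the X slice belongs to); the
    triple's sharpness is the smaller of the two per-score sharpness
    values, so a triple must peak in BOTH statistics to rank high.
    Triples with an empty or singleton S* get NaN sharpness and rank last.
    """
    group = X.group if group is None else group
    rows = []
    for t1, t2, t3 in product(theta1_grid, theta2_grid, theta3_grid):
        sel = select_dnb(X, Y, t1, t2, t3)
        if len(sel.s_star) < 2:
            sharp = float("nan")
        else:
            series = score_series(dataset, sel.s_star).for_group(group)
            sharp = min(
                _sharpness(series["I_s"], target_week),
                _sharpness(series["I_r"], target_week),
            )
        rows.append(
            {
                "theta1": t1,
                "theta2": t2,
                "theta3": t3,
                "n_s_star": len(sel.s_star),
                "sharpness": sharp,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        "sharpness", ascending=False, na_position="last", kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def leave_one_out(
    X: ConditionSlice,
    Y: ConditionSlice,
    thetas: tuple = (10.0, 50.0, 80.0),
    reference_set=None,
) -> dict:
    """Reproducibility of the selection under single-sample deletion.

    Each sample of X, then each of Y, is removed in turn; the selection is
    re-run on the remaining samples and the overlap of the re-selected S*
    with the reference set recorded.  Returns mean, SEM and the per-drop
    overlap sizes.
    """
    if X.n_samples < 4 or Y.n_samples < 4:
        raise ValueError("leave-one-out needs >= 4 samples per slice")
    if reference_set is None:
        reference_set = select_dnb(X, Y, *thetas).s_star
    reference = set(reference_set)

    overlaps, labels = [], []
    for sample in X.values.columns:
        sel = select_dnb(X.drop_sample(sample), Y, *thetas)
        overlaps.append(len(reference & set(sel.s_star)))
        labels.append(sample)
    for sample in Y.values.columns:
        sel = select_dnb(X, Y.drop_sample(sample), *thetas)
        overlaps.append(len(reference & set(sel.s_star)))
        labels.append(sample)

    arr = np.asarray(overlaps, dtype=float)
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return {
        "mean_overlap": float(arr.mean()),
        "sem_overlap": sem,
        "overlaps": dict(zip(labels, overlaps)),
        "reference_size": len(reference),
    }


def control_swap(
    X: ConditionSlice,
    alt_control: ConditionSlice,
    thetas: tuple = (10.0, 50.0, 80.0),
    reference_set=None,
) -> dict:
    """Re-select with an alternative control slice and test the overlap.

    Returns the alternative S*, its overlap with the reference set, and a
    classic one-tailed Fisher exact p-value (hypergeometric upper tail)
    for observing at least that overlap given the gene universe size.
    """
    sel = select_dnb(X, alt_control, *thetas)
    alt = set(sel.s_star)
    reference = set(reference_set) if reference_set is not None else set()
    x = len(alt & reference)
    n_universe = len(X.gene_ids)
    p = float(stats.hypergeom.sf(x - 1, n_universe, len(reference), len(alt))) if alt and reference else 1.0
    return {
        "alt_s_star": sorted(alt),
        "n_alt": len(alt),
        "overlap": x,
        "fisher_p": p,
        "selection": sel,
    }


def relative_recovery_rate(Z: ConditionSlice, s_star) -> float:
    """Proxy for the recovery rate from perturbations (critical slowing down).

    Near a transition the recovery rate is approximately inversely
    proportional to the largest eigenvalue of the sample covariance of the
    state variables; the returned value is 1 / lambda_max of the
    S*-restricted slice covariance (arbitrary common scale across slices).
    """
    s_star = pd.Index(s_star)
    if len(s_star) < 2 or Z.n_samples < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")
    cov = np.cov(Z.restrict(s_star).values.to_numpy(), ddof=1)
    lam = float(np.linalg.eigvalsh(cov)[-1])
    if lam <= 0:
        raise ValueError("degenerate covariance: largest eigenvalue is not positive")
    return 1.0 / lam
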