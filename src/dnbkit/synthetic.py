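"""Synthetic time-course expression data with planted ground truth.

The generator emulates the shape of a two-strain, five-week obesity-model
microarray study: a case strain and a control strain profiled weekly with a
handful of biological replicates per condition.  Three kinds of structure
can be planted, each recorded in :class:`SyntheticTruth`:

* a **DNB module** — a gene set that, in the case group at one
  "pre-disease" week only, shows jointly inflated variance and strong
  mutual correlation.  A single shared latent factor per sample gives an
  equicorrelated module: with total peak variance ``(sd_ratio * noise_sd)^2``
  split as a fraction ``target_abs_corr`` of common-factor variance and
  ``1 - target_abs_corr`` of idiosyncratic variance, the population
  pairwise correlation equals ``target_abs_corr`` and the population SD
  equals ``sd_ratio`` times baseline.
* **differential-expression clusters** — gene blocks whose case-group mean
  shifts by ``deg_effect`` log2 units from a configurable onset week.
* **probe-level redundancy** — each gene expanded into >=1 probes on the
  raw intensity scale, plus a fraction of unannotated probes, to exercise
  the preprocessing stage.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, ProbeDataset

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_dataset", "generate_probe_dataset"]


@dataclass
class SyntheticConfig:
    """Study design and effect sizes for the generator.

    Defaults mirror a compact version of the emulated study design: two
    groups, weekly time points 3..7 with the planted module active at week
    5, and 5 replicates per condition.
    """

    n_genes: int = 500
    n_dnb: int = 50
    groups: Sequence[str] = ("case", "control")
    weeks: Sequence[int] = (3, 4, 5, 6, 7)
    replicates: int | Mapping = 5
    peak_week: int = 5
    sd_ratio: float = 3.0
    target_abs_corr: float = 0.6
    n_deg_clusters: int = 3
    deg_cluster_size: int = 20
    deg_effect: float = 2.0
    deg_onset_week: int = 5
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    array_scale_sd: float = 0.2
    probe_redundancy: float = 1.0
    probe_offset_sd: float = 0.0
    probe_noise: float = 0.0
    unannotated_frac: float = 0.0
    seed: int = 0

    def n_replicates(self, group, week) -> int:
        if isinstance(self.replicates, Mapping):
            return int(self.replicates[(group, week)])
        return int(self.replicates)

    def validate(self) -> None:
        if self.n_dnb >= self.n_genes:
            raise ValueError("n_dnb must be smaller than n_genes")
        if not 0.0 <= self.target_abs_corr < 1.0:
            raise ValueError("target_abs_corr must be in [0, 1)")
        if self.sd_ratio < 1.0:
            raise ValueError("sd_ratio must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        # the common-factor SD sqrt(rho)*sd_ratio*noise_sd may not exceed
        # the total peak SD; with rho < 1 this always holds, so the check
        # guards the boundary rho -> 1 where the module degenerates
        if self.target_abs_corr * self.sd_ratio**2 > self.sd_ratio**2:
            raise ValueError("target_abs_corr and sd_ratio jointly infeasible")
        if self.peak_week not in tuple(self.weeks):
            raise ValueError("peak_week must be one of the configured weeks")
        n_planted = self.n_dnb + self.n_deg_clusters * self.deg_cluster_size
        if n_planted > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        if self.probe_redundancy < 1.0:
            raise ValueError("probe_redundancy must be >= 1")
        if not 0.0 <= self.unannotated_frac < 1.0:
            raise ValueError("unannotated_frac must be in [0, 1)")
        for group in self.groups:
            for week in self.weeks:
                if self.n_replicates(group, week) < 3:
                    raise ValueError("every condition needs >= 3 replicates")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, for parameter-recovery tests."""

    dnb_gene_ids: list
    deg_gene_ids: list  # one list per planted cluster
    deg_signs: list  # +1 / -1 mean-shift direction per cluster
    peak_week: object
    factor_loadings: dict  # gene id -> latent-factor coefficient b_i
    unannotated_probe_ids: list = field(default_factory=list)

    @property
    def all_deg_gene_ids(self) -> list:
        return [g for cluster in self.deg_gene_ids for g in cluster]

    def to_dict(self) -> dict:
        return asdict(self)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_dataset(config: SyntheticConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Draw a gene-level log2 dataset with planted structure.

    Returns the dataset together with the :class:`SyntheticTruth` record
    of which genes were planted and with what effect parameters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = _gene_ids(G)

    # planted positions: DNB module first, then DE clusters, disjoint
    perm = rng.permutation(G)
    dnb_idx = np.sort(perm[: config.n_dnb])
    offset = config.n_dnb
    deg_idx = []
    for _ in range(config.n_deg_clusters):
        deg_idx.append(np.sort(perm[offset : offset + config.deg_cluster_size]))
        offset += config.deg_cluster_size

    mu = rng.normal(config.baseline_mean, config.baseline_sd, G)
    total_sd = config.sd_ratio * config.noise_sd
    b = np.sqrt(config.target_abs_corr) * total_sd
    resid_sd = np.sqrt(1.0 - config.target_abs_corr) * total_sd
    deg_signs = [1 if k % 2 == 0 else -1 for k in range(config.n_deg_clusters)]
    week_order = {w: i for i, w in enumerate(config.weeks)}
    onset_rank = week_order.get(config.deg_onset_week, len(config.weeks))

    blocks, meta_rows = [], []
    for group in config.groups:
        for week in config.weeks:
            n = config.n_replicates(group, week)
            block = mu[:, None] + rng.normal(0.0, config.noise_sd, (G, n))
            if group == config.groups[0]:
                if week == config.peak_week:
                    f = rng.normal(0.0, 1.0, n)
                    block[dnb_idx] = (
                        mu[dnb_idx, None]
                        + b * f[None, :]
                        + rng.normal(0.0, resid_sd, (len(dnb_idx), n))
                    )
                if week_order[week] >= onset_rank:
                    for sign, idx in zip(deg_signs, deg_idx):
                        block[idx] += sign * config.deg_effect
            blocks.append(block)
            meta_rows += [
                {"sample_id": f"{group}_w{week}_r{k + 1}", "group": group, "week": week}
                for k in range(n)
            ]

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    values = pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=meta.index)
    truth = SyntheticTruth(
        dnb_gene_ids=[gene_ids[i] for i in dnb_idx],
        deg_gene_ids=[[gene_ids[i] for i in idx] for idx in deg_idx],
        deg_signs=deg_signs,
        peak_week=config.peak_week,
        factor_loadings={gene_ids[i]: float(b) for i in dnb_idx},
    )
    return ExpressionDataset(values, meta), truth


def generate_probe_dataset(config: SyntheticConfig) -> tuple[ProbeDataset, SyntheticTruth]:
    """Expand a gene-level draw into raw-scale probe intensities.

    Each gene becomes >=1 probes (``probe_redundancy`` is the mean count);
    probe values are the raw gene intensity times a per-sample array scale
    factor and a per-probe multiplicative offset, with optional
    multiplicative noise.  A fraction ``unannotated_frac`` of all probes
    carries no gene symbol.  Collapsing, trimmed-mean normalization and
    log2 transform recover the gene-level dataset up to probe noise.
    """
    config.validate()
    dataset, truth = generate_dataset(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    raw = np.power(2.0, dataset.values.to_numpy())
    n_samples = raw.shape[1]
    scale = np.power(2.0, rng.normal(0.0, config.array_scale_sd, n_samples))
    raw = raw * scale[None, :]

    counts = 1 + rng.poisson(config.probe_redundancy - 1.0, dataset.n_genes)
    rows, symbols = [], []
    for g, gene in enumerate(dataset.gene_ids):
        for _ in range(counts[g]):
            offset = np.power(2.0, rng.normal(0.0, config.probe_offset_sd))
            row = raw[g] * offset
            if config.probe_noise > 0:
                row = row * (1.0 + rng.normal(0.0, config.probe_noise, n_samples))
            rows.append(np.maximum(row, 1e-9))
            symbols.append(gene)

    n_annot = len(rows)
    n_unannot = int(round(config.unannotated_frac / (1.0 - config.unannotated_frac) * n_annot))
    for _ in range(n_unannot):
        base = np.power(2.0, rng.normal(config.baseline_mean, config.baseline_sd))
        row = base * scale * np.power(2.0, rng.normal(0.0, config.noise_sd, n_samples))
        rows.append(row)
        symbols.append("")

    order = rng.permutation(len(rows))
    width = len(str(len(rows)))
    probe_ids = [f"P{i:0{width}d}" for i in range(1, len(rows) + 1)]
    values = pd.DataFrame(
        np.vstack([rows[i] for i in order]),
        index=probe_ids,
        columns=dataset.values.columns,
    )
    annotation = pd.Series([symbols[i] for i in order], index=probe_ids)
    truth.unannotated_probe_ids = list(annotation.index[annotation == ""])
    return ProbeDataset(values, annotation, dataset.sample_meta.copy()), truth
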