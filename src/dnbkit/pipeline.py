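"""End-to-end orchestration: simulate (or load) -> preprocess -> DEG ->
DNB selection and scores -> exploratory views -> enrichment.

A run is described by a flat :class:`RunConfig` (constructible from a
YAML file); all stage outputs land in the output directory alongside a
machine-readable ``summary.json`` that records parameters, seeds and the
headline numbers.  Runs are idempotent for a fixed seed.
"""

from __future__ import annotations

import json
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import deg as deg_mod
from . import dnb as dnb_mod
from . import exploratory
from .datasets import ExpressionDataset
from .enrichment import enrich, read_gmt
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class RunConfig:
    outdir: str = "dnb_run"
    seed: int = 0
    # input: either synthetic (default) or paths to an expression matrix + metadata
    matrix_path: str | None = None
    meta_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    # analysis parameters (defaults follow the pipeline's presets)
    theta1: float = 10.0
    theta2: float = 50.0
    theta3: float = 80.0
    deg_q: float = 0.05
    fc_log2: float = 1.0
    cluster_cutoff: float = 0.5
    pa_shuffles: int = 100
    pa_percentile: float = 95.0
    case_week: int | str | None = None  # default: synthetic peak week / last week
    control_week: int | str | None = None  # default: same as case_week
    gmt_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("input")
def _load_input(config: RunConfig):
    if config.matrix_path is not None:
        if config.meta_path is None:
            raise ValueError("meta_path is required when matrix_path is given")
        dataset = ExpressionDataset.from_files(config.matrix_path, config.meta_path)
        return dataset, None
    syn = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
    return generate_dataset(syn)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run summary (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    dataset, truth = _load_input(config)
    dataset.to_files(outdir / "expression.tsv", outdir / "sample_meta.csv")
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2, default=str))

    case_group, control_group = dataset.groups[0], dataset.groups[1]
    case_week = config.case_week
    if case_week is None:
        case_week = truth.peak_week if truth is not None else dataset.weeks[-1]
    control_week = config.control_week if config.control_week is not None else case_week

    # differential expression per week
    degs = _stage("deg")(deg_mod.extract_degs)(
        dataset, q=config.deg_q, fc_log2=config.fc_log2,
        case_group=case_group, control_group=control_group,
    )
    for week, table in degs.per_week.items():
        table.to_csv(outdir / f"deg_week{week}.tsv", sep="\t")
    degs.incidence.astype(int).to_csv(outdir / "deg_incidence.tsv", sep="\t")

    # DNB selection and early-warning scores
    X = dataset.condition_slice(case_group, case_week)
    Y = dataset.condition_slice(control_group, control_week)
    selection = _stage("dnb")(dnb_mod.select_dnb)(
        X, Y, config.theta1, config.theta2, config.theta3
    )
    (outdir / "dnb_genes.tsv").write_text(
        "gene_id\n" + "".join(f"{g}\n" for g in selection.s_star)
    )
    summary_scores = None
    if len(selection.s_star) >= 2:
        series = _stage("dnb")(dnb_mod.score_series)(dataset, selection.s_star)
        series.table.to_csv(outdir / "dnb_scores.tsv", sep="\t")
        summary_scores = {
            "peak_week_Is": series.peak_week(case_group, "I_s"),
            "peak_week_Ir": series.peak_week(case_group, "I_r"),
        }
        fluct = exploratory.fluctuation_map(dataset, selection.s_star)
        fluct.to_csv(outdir / "fluctuation_map.tsv", sep="\t")

    # exploratory: PCA + parallel analysis; clustering of the DEG union
    pa = _stage("exploratory")(exploratory.parallel_analysis)(
        dataset, n_shuffles=config.pa_shuffles,
        percentile=config.pa_percentile, seed=config.seed,
    )
    pa.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    cluster_sizes = None
    if len(degs.union) >= 2:
        clusters = _stage("exploratory")(exploratory.cluster_genes)(
            dataset.values.loc[degs.union], cutoff=config.cluster_cutoff
        )
        clusters.labels.to_csv(outdir / "deg_clusters.tsv", sep="\t")
        cluster_sizes = clusters.sizes[:5]

    # enrichment of the selected genes, when a collection is supplied
    enrichment_top = None
    if config.gmt_path is not None:
        collection = _stage("enrichment")(read_gmt)(config.gmt_path)
        table = _stage("enrichment")(enrich)(
            set(selection.s_star), collection, universe_size=dataset.n_genes
        )
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        enrichment_top = table["name"].tolist()

    summary = {
        "seed": config.seed,
        "parameters": {
            "theta": [config.theta1, config.theta2, config.theta3],
            "deg_q": config.deg_q,
            "fc_log2": config.fc_log2,
            "cluster_cutoff": config.cluster_cutoff,
            "pa_shuffles": config.pa_shuffles,
            "pa_percentile": config.pa_percentile,
            "case_week": case_week,
            "control_week": control_week,
        },
        "n_genes": dataset.n_genes,
        "n_samples": dataset.n_samples,
        "selection": selection.summary(),
        "dnb_genes": list(selection.s_star),
        "deg_counts": {str(k): v for k, v in degs.counts().items()},
        "deg_union_size": len(degs.union),
        "scores": summary_scores,
        "n_meaningful_pcs": pa.n_meaningful,
        "top_cluster_sizes": cluster_sizes,
        "enrichment_top": enrichment_top,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
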