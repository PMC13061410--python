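"""End-to-end orchestration: QC -> exclusion -> connectivity -> statistics.

The pipeline ties the stages together exactly in analysis order: per-run
motion censoring, any-run retention exclusion, per-run masked Fisher-z
connectivity averaged across runs, edge-wise partial-correlation maps per
cognitive score, and the exploratory per-edge group contrasts.  A manifest
records parameters, seed, library versions, and subject counts at every
stage boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import AssocSpec, run_edgewise
from .connectivity import average_runs, connectivity_from_run, edge_vector
from .contrasts import run_contrasts
from .motion import (
    DEFAULT_HALF_WIDTH,
    DEFAULT_HEAD_RADIUS_MM,
    DEFAULT_MIN_RETENTION,
    DEFAULT_THRESHOLD_MM,
    censor_run,
)

log = logging.getLogger("fcedge")


@dataclass
class PipelineConfig:
    """Parameters of one pipeline invocation."""

    bold_dir: str = ""
    motion_dir: str = ""
    phenotype_file: str = ""
    out_dir: str = "fcedge_out"
    threshold_mm: float = DEFAULT_THRESHOLD_MM
    min_retention: float = DEFAULT_MIN_RETENTION
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
    half_width: int = DEFAULT_HALF_WIDTH
    scores: tuple = ("score",)
    covariates: tuple = ("mean_motion", "age", "sex", "tbv")
    group_col: str = "group"
    alpha: float = 0.05
    q_threshold: float = 0.05
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.scores = tuple(cfg.scores)
        cfg.covariates = tuple(cfg.covariates)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def qc_cohort(runs: dict, threshold_mm=DEFAULT_THRESHOLD_MM,
              min_retention=DEFAULT_MIN_RETENTION,
              head_radius_mm=DEFAULT_HEAD_RADIUS_MM,
              half_width=DEFAULT_HALF_WIDTH):
    """Per-run censoring for every subject.

    Returns ``(qc_table, censor_results)``; a subject is excluded when any
    of its runs falls below the retention floor.
    """
    rows = []
    results = {}
    for sid, subj_runs in runs.items():
        results[sid] = []
        for run in subj_runs:
            res = censor_run(
                run.motion, threshold_mm=threshold_mm,
                min_retention=min_retention, head_radius_mm=head_radius_mm,
                half_width=half_width,
            )
            results[sid].append(res)
            rows.append(
                {
                    "subject_id": sid,
                    "run_id": run.run_id,
                    "mean_motion_mm": res.mean_motion_mm,
                    "n_censored": res.n_censored,
                    "retention_fraction": res.retention_fraction,
                    "excluded": res.excluded,
                }
            )
    return pd.DataFrame(rows), results


def subject_mean_motion(qc_table: pd.DataFrame) -> pd.Series:
    """Mean head motion covariate: per-subject mean over runs (pre-censor)."""
    return qc_table.groupby("subject_id")["mean_motion_mm"].mean()


def excluded_subjects(qc_table: pd.DataFrame) -> list:
    return sorted(qc_table.loc[qc_table["excluded"], "subject_id"].unique())


def cohort_edge_table(runs: dict, censor_results: dict) -> pd.DataFrame:
    """Subjects x edges Fisher-z table from censored runs (z-space run mean)."""
    rows = {}
    labels = None
    for sid, subj_runs in runs.items():
        mats, kept = [], []
        for run, res in zip(subj_runs, censor_results[sid]):
            mats.append(
                connectivity_from_run(run.data, res.keep_mask, labels=run.labels)
            )
            kept.append(int(res.keep_mask.sum()))
        cm = average_runs(mats, subject_id=sid, labels=subj_runs[0].labels,
                          n_volumes_used=tuple(kept))
        ev = edge_vector(cm)
        labels = ev.labels
        rows[sid] = ev.values
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(labels)).rename_axis(
        "subject_id"
    )


@dataclass
class PipelineResult:
    qc_table: pd.DataFrame
    edges: pd.DataFrame
    edgewise: dict
    contrasts: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_pipeline(runs: dict, phenotypes: pd.DataFrame,
                 config: PipelineConfig) -> PipelineResult:
    """Run QC, exclusion, connectivity and both statistical analyses.

    ``runs`` maps subject id to its ParcellatedRun list; ``phenotypes`` has
    one row per subject.  Validates the config against the phenotype table
    before any computation.
    """
    pheno = phenotypes.copy()
    missing = [
        c for c in (*config.scores, config.group_col)
        if c not in pheno.columns
    ]
    missing += [
        c for c in config.covariates
        if c not in pheno.columns and c != "mean_motion"
    ]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(set(missing))}")

    n_initial = len(runs)
    log.info("QC stage: %d subjects", n_initial)
    qc_table, censor_results = qc_cohort(
        runs, config.threshold_mm, config.min_retention,
        config.head_radius_mm, config.half_width,
    )
    dropped = excluded_subjects(qc_table)
    analyzed = {sid: r for sid, r in runs.items() if sid not in set(dropped)}
    log.info("excluded %d subject(s) for motion; %d remain", len(dropped),
             len(analyzed))
    if not analyzed:
        raise ValueError("all subjects excluded by motion QC")

    mm = subject_mean_motion(qc_table)
    pheno = pheno.set_index("subject_id") if "subject_id" in pheno.columns else pheno
    pheno = pheno.assign(mean_motion=mm).reset_index()

    edges = cohort_edge_table(analyzed, censor_results)

    spec_kw = dict(covariate_names=config.covariates, alpha=config.alpha,
                   q_threshold=config.q_threshold)
    edgewise = {
        score: run_edgewise(edges, pheno, AssocSpec(score_name=score, **spec_kw))
        for score in config.scores
    }
    contrasts = run_contrasts(
        edges, pheno, AssocSpec(score_name=config.scores[0], **spec_kw),
        group_col=config.group_col,
    )

    manifest = {
        "fcedge_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_subjects_initial": n_initial,
        "n_subjects_excluded": len(dropped),
        "excluded_subjects": dropped,
        "n_subjects_analyzed": len(analyzed),
        "n_edges": edges.shape[1],
        "edgewise_n": {s: t.n for s, t in edgewise.items()},
    }
    return PipelineResult(qc_table=qc_table, edges=edges, edgewise=edgewise,
                          contrasts=contrasts, manifest=manifest)


def write_results(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.qc_table.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    result.edges.to_csv(out / "edges.tsv", sep="\t")
    for score, tab in result.edgewise.items():
        tab.table.to_csv(out / f"{score}_edgewise.tsv", sep="\t", index=False)
    result.contrasts.to_csv(out / "contrasts.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
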