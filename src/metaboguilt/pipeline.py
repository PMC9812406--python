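"""End-to-end orchestration: simulate/load -> QC -> detrend -> profiles ->
similarity -> classification, with every intermediate persisted as tidy
CSV/JSON/Newick and a deterministic summary."""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .guilt import nominate_candidates, permutation_pvalue, roc_auc, set_distance_scores
from .normalization import filter_outlier_samples, lowess_detrend
from .profiles import log2_fold_change_profiles, significant_changes
from .similarity import correlation_matrix, manhattan_distance_matrix, ward_cluster
from .synthetic import generate_dataset

__all__ = ["run_pipeline", "load_intensity_csv"]

_DTYPES = {
    "timepoint_min": float,
    "replicate": int,
    "injection_index": int,
    "od600": float,
    "intensity": float,
}


def load_intensity_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return table.astype({k: v for k, v in _DTYPES.items() if k in table})


class StageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order, writing artifacts into ``outdir``.

    Returns the summary dict (also written to ``summary.json``).  Stage
    failures are re-raised as :class:`StageError` naming the stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.resolved.yaml")

    # --- inputs -----------------------------------------------------------
    try:
        if config.simulate:
            table, annotation, truth = generate_dataset(config.simulation)
            table.to_csv(out / "intensity.csv", index=False)
            annotation.to_csv(out / "annotation.csv", index=False)
            truth.to_json(out / "truth.json")
        else:
            if not config.intensity_csv or not config.annotation_csv:
                raise ValueError(
                    "intensity_csv and annotation_csv are required when simulate=False"
                )
            table = load_intensity_csv(config.intensity_csv)
            annotation = pd.read_csv(config.annotation_csv)
    except Exception as exc:  # noqa: BLE001
        raise StageError("input", exc) from exc

    positives = set(
        annotation.loc[annotation["class"] == config.positive_class, "mutant"]
    )
    if len(positives) < 2:
        raise StageError(
            "input",
            ValueError(
                f"AnnotationTable provides {len(positives)} mutants of class "
                f"{config.positive_class!r}; need >= 2"
            ),
        )

    # --- normalization ----------------------------------------------------
    try:
        table, report = filter_outlier_samples(table, k_mad=config.k_mad)
        report.to_json(out / "outlier_report.json")
        for cov in config.detrend_covariates:
            table = lowess_detrend(
                table,
                covariate=cov,
                span=config.lowess_span,
                iterations=config.lowess_iterations,
            )
        table.to_csv(out / "normalized.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("normalization", exc) from exc

    # --- profiles ---------------------------------------------------------
    try:
        profiles = log2_fold_change_profiles(
            table,
            reference_mutant=config.reference_mutant,
            welch=config.welch,
            mean_of_ratios=config.mean_of_ratios,
        )
        profiles.to_csv(out / "profiles.csv", index=False)
        calls, counts = significant_changes(
            profiles, fc_cut=config.fc_cut, p_cut=config.p_cut
        )
        counts.to_csv(out / "significant_counts.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("profiles", exc) from exc

    # --- similarity + classification per timepoint ------------------------
    timepoints = sorted(profiles["timepoint_min"].unique())
    auc_by_tp: dict[str, float] = {}
    p_by_tp: dict[str, float] = {}
    threshold_by_tp: dict[str, float | None] = {}
    score_frames = []
    candidates_by_tp: dict[str, list[str]] = {}
    try:
        for tp in timepoints:
            tag = f"t{tp:g}"
            corr = correlation_matrix(profiles, tp)
            corr.to_csv(out / f"correlation_{tag}.csv")
            dist = manhattan_distance_matrix(
                corr, include_self=config.include_self_in_distance
            )
            dist.to_csv(out / f"distance_{tag}.csv")
            tree = ward_cluster(dist)
            (out / f"tree_{tag}.newick").write_text(tree.to_newick() + "\n")
            tree.to_json(out / f"tree_{tag}.json")

            pos_here = positives & set(dist.index)
            scores = set_distance_scores(dist, pos_here, summary=config.summary)
            perm = permutation_pvalue(
                dist,
                pos_here,
                B=config.n_randomizations,
                seed=config.permutation_seed,
            )
            roc = roc_auc(scores, target_fpr=config.target_fpr)
            roc.points.to_csv(out / f"roc_{tag}.csv", index=False)
            scored, cands = nominate_candidates(scores, roc)
            scored.insert(1, "timepoint_min", tp)
            score_frames.append(scored)
            candidates_by_tp[tag] = cands
            auc_by_tp[tag] = roc.auc
            p_by_tp[tag] = perm.p_value
            threshold_by_tp[tag] = roc.threshold_at_target_fpr
    except Exception as exc:  # noqa: BLE001
        raise StageError("similarity", exc) from exc

    score_table = pd.concat(score_frames, ignore_index=True)
    score_table.to_csv(out / "scores.csv", index=False)
    aggregate = sorted({c for cands in candidates_by_tp.values() for c in cands})
    pd.DataFrame({"mutant": aggregate}).to_csv(out / "candidates.csv", index=False)

    summary = {
        "package_version": __version__,
        "python_version": sys.version.split()[0],
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "n_samples_kept": int(table["sample_id"].nunique()),
        "n_samples_excluded": len(report.excluded),
        "timepoints_min": [float(t) for t in timepoints],
        "auc": auc_by_tp,
        "permutation_p": p_by_tp,
        "permutation_B": config.n_randomizations,
        "permutation_seed": config.permutation_seed,
        "threshold_at_target_fpr": threshold_by_tp,
        "target_fpr": config.target_fpr,
        "candidates_by_timepoint": candidates_by_tp,
        "candidates_aggregate": aggregate,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    return summary
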