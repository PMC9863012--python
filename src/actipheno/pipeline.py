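"""End-to-end orchestration: recordings -> features -> selection -> model
search -> aggregated, direction-annotated importance rankings.

Every stage logs its counts (features kept, cliques found, models retained)
and the same counts are returned in the result bundle — they are the primary
debugging surface of the funnel.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as mdl
from . import selection, shapley
from .config import RunConfig
from .features import extract_cohort_features
from .io import write_feature_table
from .synthetic import CohortSpec, iter_cohort
from .types import FeatureTable, Group, RawRecording

log = logging.getLogger(__name__)

DEFAULT_TASKS = (Group.CTF, Group.PSF)


def run_pipeline(config: RunConfig | None = None,
                 cohort_spec: CohortSpec | None = None,
                 recordings: list[RawRecording] | None = None,
                 tasks: tuple[Group, ...] = DEFAULT_TASKS,
                 algorithms: tuple[str, ...] = mdl.ALGORITHMS,
                 out_dir: str | Path | None = None) -> dict:
    """Run every stage and return a result bundle.

    Exactly one of ``cohort_spec`` (synthesize recordings) or ``recordings``
    must be provided. The bundle holds the feature tables, retained model
    results, per-(algorithm, task) and pooled per-task importance rankings,
    and a stage-count dictionary.
    """
    cfg = config or RunConfig()
    if (cohort_spec is None) == (recordings is None):
        raise ValueError("provide exactly one of cohort_spec or recordings")
    truth = None
    if cohort_spec is not None:
        cfg.validate(cohort_spec.sampling_rate)
        truth = {}
        recordings = iter_cohort(cohort_spec, truth)  # streamed, one at a time
    else:
        cfg.validate(recordings[0].sampling_rate)

    table, baseline = extract_cohort_features(recordings, cfg)
    normalized, flagged = selection.standard_normalize(table)
    baseline_norm, _ = selection.standard_normalize(baseline)

    seed_rng = np.random.default_rng(cfg.rng_seed)
    seeds = {t: int(seed_rng.integers(2 ** 31)) for t in tasks}
    model_seed = int(seed_rng.integers(2 ** 31))
    shap_seed = int(seed_rng.integers(2 ** 31))

    combos_per_task: dict[Group, list[selection.FeatureCombination]] = {}
    counts: dict = {"flagged_constant_features": len(flagged)}
    for task in tasks:
        combos, c = selection.select_combinations(
            normalized, task, alpha=cfg.welch_alpha,
            corr_threshold=cfg.corr_edge_threshold,
            min_clique_size=cfg.min_clique_size,
            n_combinations=cfg.n_combinations, seed=seeds[task])
        combos_per_task[task] = combos
        counts[f"selection_{task.value}"] = c

    results = mdl.run_search(normalized, combos_per_task, cfg, seed=model_seed,
                             algorithms=algorithms)
    baselines = mdl.baseline_results(baseline_norm, tasks, cfg, seed=model_seed,
                                     algorithms=algorithms)
    retained = mdl.filter_above_baseline(results, baselines)
    counts["models_total"] = len(results)
    counts["models_retained"] = len(retained)

    task_frames = {t.value: mdl.task_arrays(normalized, t)[0] for t in tasks}
    rankings: dict[str, dict[str, pd.DataFrame]] = {}
    attributions: dict[str, dict[str, pd.DataFrame]] = {}
    for task in tasks:
        rankings[task.value] = {}
        attributions[task.value] = {}
        task_results = [r for r in retained if r.task == task.value]
        per_alg_mats = {}
        for alg in algorithms:
            alg_results = [r for r in task_results if r.algorithm == alg]
            if not alg_results:
                log.info("no retained %s models for task %s", alg, task.value)
                continue
            mats = shapley.explain_models(alg_results, task_frames,
                                          max_exact=cfg.shap_exact_max_features,
                                          seed=shap_seed,
                                          background_size=cfg.shap_background_size)
            agg = shapley.aggregate_attributions(mats)
            per_alg_mats[alg] = agg
            rankings[task.value][alg] = shapley.rank_features(
                agg, task_frames[task.value], cfg.direction_corr_cut)
            attributions[task.value][alg] = agg
        if per_alg_mats:
            universe = sorted({c for a in per_alg_mats.values() for c in a.columns})
            pooled = pd.DataFrame(0.0, index=task_frames[task.value].index,
                                  columns=universe)
            for agg in per_alg_mats.values():
                pooled[agg.columns] = pooled[agg.columns] + agg
            rankings[task.value]["combined"] = shapley.rank_features(
                pooled, task_frames[task.value], cfg.direction_corr_cut)
            attributions[task.value]["combined"] = pooled

    bundle = {
        "config": cfg, "feature_table": table, "baseline_table": baseline,
        "normalized": normalized, "combinations": combos_per_task,
        "results": results, "baselines": baselines, "retained": retained,
        "rankings": rankings, "attributions": attributions,
        "counts": counts, "ground_truth": truth,
    }
    if out_dir is not None:
        _write_artifacts(bundle, Path(out_dir))
    return bundle


def _write_artifacts(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_feature_table(bundle["feature_table"], out_dir / "features.tsv")
    metrics = {
        "counts": bundle["counts"],
        "baselines": {f"{a}_{t}": {"accuracy": r.accuracy, "precision": r.precision,
                                   "recall": r.recall}
                      for (a, t), r in bundle["baselines"].items()},
        "retained": [{"algorithm": r.algorithm, "task": r.task,
                      "combination": r.combination_id, "accuracy": r.accuracy,
                      "precision": r.precision, "recall": r.recall}
                     for r in bundle["retained"]],
    }
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    for task, per_alg in bundle["rankings"].items():
        for alg, df in per_alg.items():
            df.to_csv(out_dir / f"ranking_{task}_{alg}.tsv", sep="\t", index=False)
    if bundle["ground_truth"] is not None:
        def _default(o):
            return str(o)
        (out_dir / "ground_truth.json").write_text(
            json.dumps(bundle["ground_truth"], indent=2, default=_default))
    log.info("artifacts written to %s", out_dir)
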