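"""Classifier evaluation harness.

Three fixed-hyperparameter classifier families (logistic regression, random
forest, and histogram gradient boosting standing in for LightGBM) evaluated
with stratified 10-fold cross-validation. Out-of-fold predictions are pooled
into a single confusion matrix with the propensity class positive:

    accuracy  = (TP + TN) / total
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

Models are retained when their accuracy strictly exceeds the 3-feature
baseline of the same (algorithm, task) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .config import RunConfig
from .selection import FeatureCombination
from .types import FeatureTable, Group

log = logging.getLogger(__name__)

ALGORITHMS = ("LGR", "RF", "LGB")


def make_classifier(algorithm: str, config: RunConfig, seed: int):
    cfg = config
    if algorithm == "LGR":
        return LogisticRegression(C=cfg.lgr_c, max_iter=2000)
    if algorithm == "RF":
        return RandomForestClassifier(n_estimators=cfg.rf_n_estimators,
                                      max_features="sqrt", random_state=seed)
    if algorithm == "LGB":
        return HistGradientBoostingClassifier(
            max_iter=cfg.gbm_max_iter, max_depth=cfg.gbm_max_depth,
            min_samples_leaf=cfg.gbm_min_samples_leaf, random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class ModelResult:
    """Pooled CV metrics plus a full-data refit for explanation."""

    algorithm: str
    task: str
    combination_id: int
    features: tuple[str, ...]
    accuracy: float
    precision: float
    recall: float
    y_true: np.ndarray
    y_pred: np.ndarray
    model: object = field(repr=False, default=None)


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray
                             ) -> tuple[float, float, float]:
    """Accuracy / precision / recall from pooled binary predictions (1 = positive)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    accuracy = (tp + tn) / len(y_true)
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return accuracy, precision, recall


def cross_validate(algorithm: str, X: np.ndarray, y: np.ndarray,
                   config: RunConfig | None = None, seed: int = 0,
                   task: str = "", combination_id: int = -1,
                   features: tuple[str, ...] = ()) -> ModelResult:
    """Stratified k-fold CV with seed-controlled shuffling; metrics from the
    pooled out-of-fold confusion matrix; the returned model is refit on all
    rows for downstream attribution."""
    cfg = config or RunConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("y must contain both classes")
    counts = np.bincount(y)
    folds = min(cfg.cv_folds, counts[counts > 0].min())
    if folds < cfg.cv_folds:
        log.info("reducing folds from %d to %d (smallest class size)",
                 cfg.cv_folds, folds)
    skf = StratifiedKFold(n_splits=int(folds), shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    for train, test in skf.split(X, y):
        clf = make_classifier(algorithm, cfg, seed)
        clf.fit(X[train], y[train])
        y_pred[test] = clf.predict(X[test])
    acc, prec, rec = metrics_from_predictions(y, y_pred)
    final = make_classifier(algorithm, cfg, seed)
    final.fit(X, y)
    return ModelResult(algorithm=algorithm, task=task, combination_id=combination_id,
                       features=tuple(features), accuracy=acc, precision=prec,
                       recall=rec, y_true=y, y_pred=y_pred, model=final)


def task_arrays(table: FeatureTable, positive: Group, control: Group = Group.C
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Subject rows and 0/1 labels (propensity class positive) for one task."""
    mask = table.labels.isin([positive, control])
    frame = table.frame[mask]
    y = (table.labels[mask] == positive).to_numpy().astype(int)
    return frame, y


def plan_search(algorithms: tuple[str, ...], tasks: tuple[Group, ...],
                combinations_per_task: dict[Group, list[FeatureCombination]]
                ) -> list[tuple[str, Group, int]]:
    """The bookkeeping of the search: one job per algorithm x task x combination."""
    return [(alg, task, i)
            for alg in algorithms
            for task in tasks
            for i in range(len(combinations_per_task[task]))]


def run_search(table: FeatureTable,
               combinations_per_task: dict[Group, list[FeatureCombination]],
               config: RunConfig | None = None, seed: int = 0,
               algorithms: tuple[str, ...] = ALGORITHMS,
               control: Group = Group.C) -> list[ModelResult]:
    """Cross-validate every (algorithm x task x combination)."""
    cfg = config or RunConfig()
    results: list[ModelResult] = []
    for alg in algorithms:
        for task, combos in combinations_per_task.items():
            frame, y = task_arrays(table, task, control)
            for i, combo in enumerate(combos):
                X = frame[list(combo.features)].to_numpy()
                results.append(cross_validate(
                    alg, X, y, cfg, seed=seed, task=task.value,
                    combination_id=i, features=combo.features))
    log.info("search: %d models (%d algorithms x %d tasks x combinations)",
             len(results), len(algorithms), len(combinations_per_task))
    return results


def baseline_results(baseline_table: FeatureTable, tasks: tuple[Group, ...],
                     config: RunConfig | None = None, seed: int = 0,
                     algorithms: tuple[str, ...] = ALGORITHMS,
                     control: Group = Group.C) -> dict[tuple[str, str], ModelResult]:
    """The 3-feature baseline per (algorithm, task)."""
    cfg = config or RunConfig()
    out: dict[tuple[str, str], ModelResult] = {}
    for alg in algorithms:
        for task in tasks:
            frame, y = task_arrays(baseline_table, task, control)
            out[(alg, task.value)] = cross_validate(
                alg, frame.to_numpy(), y, cfg, seed=seed, task=task.value,
                combination_id=-1, features=tuple(frame.columns))
    return out


def filter_above_baseline(results: list[ModelResult],
                          baselines: dict[tuple[str, str], ModelResult]
                          ) -> list[ModelResult]:
    """Keep models whose accuracy strictly exceeds their (algorithm, task)
    baseline accuracy."""
    retained = []
    for r in results:
        key = (r.algorithm, r.task)
        if key not in baselines:
            raise KeyError(f"missing baseline for {key}")
        if r.accuracy > baselines[key].accuracy:
            retained.append(r)
    log.info("retained %d of %d models above their baselines",
             len(retained), len(results))
    return retained
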