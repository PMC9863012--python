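"""Shapley attributions and their cross-model aggregation.

The attribution of feature i for subject x is the Shapley value of the
coalition game v(S) = E_b[f(x_S, b_{~S})], the model's expected output when
the features in S take the subject's values and the rest are replaced by a
background row (the model's own training rows). For combinations of up to 12
features the full coalition lattice is enumerated exactly, which satisfies
local accuracy to machine precision: sum_i phi_i + v(empty) = f(x). Larger
sets fall back to a permutation-sampling estimator.

Following the analysis this package reproduces, attributions of all retained
models of one (algorithm, task) pair are summed row-wise — same subject, same
feature — so that unstable, sign-flipping contributions cancel, and features
are ranked by the mean absolute summed attribution. Each ranked feature gets
a direction: '+' when high feature values push the model toward the
propensity class (positive value-attribution correlation), '-' for the
opposite, '?' when the correlation is weak.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class AttributionMatrix:
    """Per-(subject, feature) Shapley values for one model."""

    frame: pd.DataFrame
    base_value: float

    def local_accuracy_residual(self, predictions: np.ndarray) -> np.ndarray:
        """f(x) - (sum_i phi_i + base) per subject; ~0 for exact attributions."""
        return np.asarray(predictions, dtype=float) - (
            self.frame.sum(axis=1).to_numpy() + self.base_value)


def _predict_fn(model):
    if callable(model) and not hasattr(model, "predict"):
        return model
    if hasattr(model, "predict_proba"):
        return lambda X: model.predict_proba(X)[:, 1]
    return model.predict


def exact_shapley(model, X: np.ndarray, background: np.ndarray,
                  chunk_rows: int = 600_000) -> tuple[np.ndarray, float]:
    """Exact Shapley values by full coalition enumeration.

    Returns (phi, base) with phi of shape (n_subjects, n_features).
    """
    predict = _predict_fn(model)
    X = np.asarray(X, dtype=float)
    B = np.asarray(background, dtype=float)
    n, k = X.shape
    m = len(B)
    n_subsets = 1 << k
    masks = ((np.arange(n_subsets)[:, None] >> np.arange(k)) & 1).astype(bool)
    sizes = masks.sum(axis=1)
    fact = [math.factorial(i) for i in range(k + 1)]
    weight_by_size = np.array(
        [fact[s] * fact[k - 1 - s] / fact[k] for s in range(k)])

    rows_per_subject = n_subsets * m
    chunk = max(1, chunk_rows // rows_per_subject)
    v = np.empty((n, n_subsets))
    for c0 in range(0, n, chunk):
        Xc = X[c0:c0 + chunk]
        z = np.where(masks[None, :, None, :], Xc[:, None, None, :],
                     B[None, None, :, :])
        preds = predict(z.reshape(-1, k)).reshape(len(Xc), n_subsets, m)
        v[c0:c0 + chunk] = preds.mean(axis=2)

    phi = np.zeros((n, k))
    for i in range(k):
        without = np.flatnonzero(~masks[:, i])
        with_i = without + (1 << i)
        w = weight_by_size[sizes[without]]
        phi[:, i] = ((v[:, with_i] - v[:, without]) * w[None, :]).sum(axis=1)
    base = float(v[0, 0])  # E_b f(b), independent of the subject
    return phi, base


def sampling_shapley(model, X: np.ndarray, background: np.ndarray,
                     n_permutations: int = 200,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley estimate (for > max_exact features).

    Averages marginal contributions over random feature orderings; unbiased,
    with Monte-Carlo error shrinking as 1/sqrt(n_permutations).
    """
    predict = _predict_fn(model)
    X = np.asarray(X, dtype=float)
    B = np.asarray(background, dtype=float)
    n, k = X.shape
    m = len(B)
    rng = rng or np.random.default_rng(0)
    base = float(predict(B).mean())
    phi = np.zeros((n, k))
    for _ in range(n_permutations):
        order = rng.permutation(k)
        # prefix masks: after inserting order[:j] features
        mask = np.zeros(k, dtype=bool)
        prefix_masks = [mask.copy()]
        for i in order:
            mask[i] = True
            prefix_masks.append(mask.copy())
        pm = np.array(prefix_masks)  # (k+1, k)
        z = np.where(pm[None, :, None, :], X[:, None, None, :], B[None, None, :, :])
        preds = predict(z.reshape(-1, k)).reshape(n, k + 1, m).mean(axis=2)
        contrib = np.diff(preds, axis=1)  # (n, k)
        phi[:, order] += contrib
    return phi / n_permutations, base


def shapley_values(model, X: pd.DataFrame, background: pd.DataFrame | None = None,
                   max_exact: int = 12, n_permutations: int = 200,
                   rng: np.random.Generator | None = None) -> AttributionMatrix:
    """Attribution matrix for one fitted model on its feature frame."""
    if background is None:
        background = X
    if list(X.columns) != list(background.columns):
        raise ValueError("X and background must share feature columns")
    k = X.shape[1]
    if k <= max_exact:
        phi, base = exact_shapley(model, X.to_numpy(), background.to_numpy())
    else:
        phi, base = sampling_shapley(model, X.to_numpy(), background.to_numpy(),
                                     n_permutations, rng)
    return AttributionMatrix(
        frame=pd.DataFrame(phi, index=X.index, columns=X.columns),
        base_value=base)


def aggregate_attributions(matrices: list[AttributionMatrix],
                           universe: list[str] | None = None) -> pd.DataFrame:
    """Row-wise (same subject, same feature) sum across models.

    Features absent from a model contribute 0. All matrices must share the
    subject order.
    """
    if not matrices:
        raise ValueError("no attribution matrices to aggregate")
    index = matrices[0].frame.index
    for m in matrices[1:]:
        if not m.frame.index.equals(index):
            raise ValueError("subject order mismatch between attribution matrices")
    if universe is None:
        universe = sorted({c for m in matrices for c in m.frame.columns})
    total = pd.DataFrame(0.0, index=index, columns=universe)
    for m in matrices:
        total[m.frame.columns] = total[m.frame.columns] + m.frame
    return total


def rank_features(aggregated: pd.DataFrame, X: pd.DataFrame,
                  corr_cut: float = 0.3) -> pd.DataFrame:
    """Direction-annotated importance ranking of an aggregated matrix.

    Rank by mean absolute aggregated attribution (descending, name-stable
    tie-break); direction is the sign of the Pearson correlation between a
    feature's values and its attributions ('+' = high values push toward the
    propensity class), '?' when |r| < corr_cut or undefined.
    """
    rows = []
    for name in aggregated.columns:
        attr = aggregated[name].to_numpy()
        mean_abs = float(np.mean(np.abs(attr)))
        direction = "?"
        if name in X.columns:
            vals = X[name].to_numpy(dtype=float)
            if np.std(attr) > 0 and np.std(vals) > 0:
                r = float(np.corrcoef(vals, attr)[0, 1])
                if abs(r) >= corr_cut:
                    direction = "+" if r > 0 else "-"
        rows.append((name, mean_abs, direction))
    df = pd.DataFrame(rows, columns=["feature", "mean_abs_shap", "direction"])
    df = df.sort_values(["mean_abs_shap", "feature"],
                        ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)[["feature", "rank", "mean_abs_shap", "direction"]]


def explain_models(results, task_frames: dict[str, pd.DataFrame],
                   max_exact: int = 12, n_permutations: int = 200,
                   seed: int = 0, background_size: int | None = None
                   ) -> list[AttributionMatrix]:
    """Attribution matrices for a list of ModelResult.

    ``task_frames`` maps a task name to the normalized feature frame of that
    task's subjects; each model is explained on its own feature subset with
    the training rows as background. ``background_size`` caps the background
    at that many evenly spaced rows (a deterministic thinning that trades
    attribution resolution for speed; local accuracy then holds with respect
    to the thinned background mean).
    """
    rng = np.random.default_rng(seed)
    out = []
    for r in results:
        X = task_frames[r.task][list(r.features)]
        background = X
        if background_size is not None and background_size < len(X):
            pick = np.linspace(0, len(X) - 1, background_size).round().astype(int)
            background = X.iloc[pick]
        out.append(shapley_values(r.model, X, background=background,
                                  max_exact=max_exact,
                                  n_permutations=n_permutations, rng=rng))
    return out
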