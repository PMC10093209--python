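"""Correlation-weighted linear cancer scores.

Two selection strategies produce the same kind of model:

* **ICF** — rank all features by the absolute Pearson correlation of the
  feature with the binary region label over the pooled training cells and
  keep the top five.
* **MANOVA** — greedy forward selection: at each step add the candidate
  feature that minimises the one-way MANOVA Wilks' lambda of the
  already-selected set plus the candidate, so each new feature must add
  discriminative value beyond the current combination.

Either way the score of a cell is ``sum_i w_i * v_i`` where
``w_i = |r_i| / sum_j |r_j|`` (weights sum to one), ``v_i`` is the selected
feature after percentile normalisation to [0, 1] (bounded features pass
through), and negatively correlated features are inverted
(``v_i -> 1 - v_i``), so the score itself lies in [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..registry import BOUNDED_FEATURES
from .normalize import percentile_bounds, percentile_normalize

logger = logging.getLogger(__name__)


@dataclass
class LinearScoreModel:
    """Selected features with correlation weights and percentile normalisers."""

    feature_names: list[str]
    correlations: np.ndarray  # signed r_i
    weights: np.ndarray  # |r_i| / sum |r_j|
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    passthrough: frozenset[str] = BOUNDED_FEATURES

    @property
    def invert(self) -> np.ndarray:
        return self.correlations < 0

    def manifest(self) -> dict:
        return {
            "kind": "linear",
            "features": list(self.feature_names),
            "correlations": [float(r) for r in self.correlations],
            "weights": [float(w) for w in self.weights],
            "bounds": {k: [float(a), float(b)] for k, (a, b) in self.bounds.items()},
        }


def _pearson_with_labels(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r against a binary label; constant columns get 0."""
    y = labels.astype(float)
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return r


def _fit_linear(df: pd.DataFrame, labels: np.ndarray, order: np.ndarray) -> LinearScoreModel:
    names = [df.columns[i] for i in order]
    r = _pearson_with_labels(df.to_numpy(dtype=float), labels)[order]
    total = np.abs(r).sum()
    if total == 0:
        weights = np.full(len(r), 1.0 / len(r))
    else:
        weights = np.abs(r) / total
    bounds = {
        name: percentile_bounds(df[name].to_numpy(dtype=float))
        for name in names
        if name not in BOUNDED_FEATURES
    }
    return LinearScoreModel(names, r, weights, bounds)


def fit_linear_model(
    df: pd.DataFrame, labels: np.ndarray, feature_names: list[str]
) -> LinearScoreModel:
    """Fit weights, inversion flags and percentile bounds for a given feature set
    (e.g. to re-anchor a model selected on normalised features back onto the
    raw feature scale)."""
    order = np.array([df.columns.get_loc(n) for n in feature_names])
    return _fit_linear(df, np.asarray(labels), order)


def icf_select(df: pd.DataFrame, labels: np.ndarray, n_select: int = 5) -> LinearScoreModel:
    """Select the features with the highest |Pearson r| against the labels.

    Correlations are computed over all training cells pooled across slides;
    ties keep column (registry) order; if fewer than ``n_select`` features
    exist, all are selected and the weights renormalised.
    """
    labels = np.asarray(labels)
    if len(df) < 2:
        raise ValueError("at least 2 cells are required")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to correlate features with labels")
    r = _pearson_with_labels(df.to_numpy(dtype=float), labels)
    order = np.argsort(-np.abs(r), kind="stable")[: min(n_select, df.shape[1])]
    return _fit_linear(df, labels, order)


def _wilks_lambda(X: np.ndarray, labels: np.ndarray) -> float:
    """One-way MANOVA Wilks' lambda = det(W) / det(T) for the given columns."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in np.unique(labels):
        Xg = X[labels == g]
        Xg = Xg - Xg.mean(axis=0)
        W += Xg.T @ Xg
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_t <= 0 or sign_w <= 0:
        raise np.linalg.LinAlgError("singular scatter matrix")
    return float(np.exp(logdet_w - logdet_t))


def manova_select(df: pd.DataFrame, labels: np.ndarray, n_select: int = 5) -> LinearScoreModel:
    """Greedy forward selection minimising Wilks' lambda at each step.

    Candidates whose within-class scatter is singular together with the
    current set are skipped with a warning.  Weighting, normalisation and
    inversion are then identical to the ICF model.
    """
    labels = np.asarray(labels)
    if len(df) < 2:
        raise ValueError("at least 2 cells are required")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    X = df.to_numpy(dtype=float)
    n_features = X.shape[1]
    if n_features <= n_select:
        return _fit_linear(df, labels, np.arange(n_features))
    selected: list[int] = []
    remaining = list(range(n_features))
    while len(selected) < n_select and remaining:
        best_j, best_lambda = None, np.inf
        for j in remaining:
            cols = selected + [j]
            try:
                lam = _wilks_lambda(X[:, cols], labels)
            except np.linalg.LinAlgError:
                logger.warning("candidate %s skipped: singular scatter", df.columns[j])
                continue
            if lam < best_lambda - 1e-15:
                best_lambda, best_j = lam, j
        if best_j is None:
            warnings.warn("no further non-singular candidate; selection stopped early")
            break
        selected.append(best_j)
        remaining.remove(best_j)
    return _fit_linear(df, labels, np.array(selected))


def combine_score(df: pd.DataFrame, model: LinearScoreModel) -> np.ndarray:
    """Correlation-weighted sum of the selected, normalised features.

    Each selected feature is percentile-normalised to [0, 1] with the bounds
    fitted on training data (bounded features pass through unchanged);
    negatively correlated features contribute ``1 - v`` instead of ``v``.
    """
    missing = [n for n in model.feature_names if n not in df.columns]
    if missing:
        raise KeyError(f"missing selected feature column(s): {missing}")
    score = np.zeros(len(df))
    for name, w, inv in zip(model.feature_names, model.weights, model.invert):
        x = df[name].to_numpy(dtype=float)
        if name in model.passthrough:
            v = np.clip(x, 0.0, 1.0)
        else:
            v = percentile_normalize(x, *model.bounds[name])
        if inv:
            v = 1.0 - v
        score += w * v
    return np.clip(score, 0.0, 1.0)


def classify_scores(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary call per cell: score strictly greater than the threshold.

    The default 0.5 is the midpoint of the {0, 1} label codes."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not 0.0 <= threshold <= 1.0:
        warnings.warn(f"threshold {threshold} outside [0, 1]; applied anyway")
    return scores > threshold
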