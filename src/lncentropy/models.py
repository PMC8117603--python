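"""Classifier training and evaluation.

Three algorithm families — RBF-kernel SVM, random forest, and
gradient-boosted trees (XGBoost) — are tuned by grid search under
stratified 5-fold cross-validation and compared by pooled out-of-fold
ROC/AUC and precision-recall/AUPR. The SVM grid (two parameters, C and
gamma) is searched exhaustively; the tree models use a staged
coordinate-wise search: one parameter is optimized at a time, in a fixed
order, with the others held at their current best, each stage scored by
mean 5-fold CV AUC.

lncRNA is the positive class throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    auc as _trapezoid_auc,
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import split_xy

ALGOS = ("svm_rbf", "random_forest", "gbt")

# Defaults are small, defensible grids; list order is simplest-first so a
# CV-AUC tie resolves to the simpler setting.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm_rbf": {"C": [0.1, 1, 10, 100], "gamma": [1e-3, 1e-2, 1e-1, 1]},
    "random_forest": {
        "n_estimators": [200, 500],
        "max_depth": [None, 10, 20],
        "min_samples_split": [2, 5],
    },
    "gbt": {
        "max_depth": [3, 6],
        "learning_rate": [0.05, 0.1, 0.3],
        "n_estimators": [100, 300],
    },
}

# Coordinate order for the staged search on the tree models.
STAGED_ORDER: dict[str, tuple[str, ...]] = {
    "random_forest": ("n_estimators", "max_depth", "min_samples_split"),
    "gbt": ("max_depth", "learning_rate", "n_estimators"),
}

N_FOLDS = 5


class UnsupportedAlgoError(ValueError):
    pass


def make_estimator(algo: str, params: dict, seed: int):
    """Instantiate a classifier with the given hyperparameters.

    The SVM is wrapped in a z-scoring pipeline (RBF kernels are
    scale-sensitive; the tree models are not and get raw features).
    """
    if algo == "svm_rbf":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="rbf", random_state=seed, **params)),
            ]
        )
    if algo == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algo == "gbt":
        return XGBClassifier(
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            **params,
        )
    raise UnsupportedAlgoError(f"unknown algorithm {algo!r}; expected one of {ALGOS}")


def _fold_scores(model, X: np.ndarray) -> np.ndarray:
    """Monotone positive-class score for AUC scoring."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _cv_mean_auc(algo: str, params: dict, X: np.ndarray, y: np.ndarray, seed: int) -> float:
    """Mean 5-fold CV AUC of one hyperparameter setting (the staged-search
    scorer). SVMs are scored on the decision function: AUC is rank-based,
    so Platt calibration is unnecessary here."""
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        model = make_estimator(algo, params, seed)
        model.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], _fold_scores(model, X[te])))
    return float(np.mean(aucs))


def staged_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    algo: str,
    grid: dict[str, list] | None = None,
    seed: int = 0,
    scorer=None,
) -> dict:
    """Select hyperparameters by CV AUC.

    svm_rbf: exhaustive product over the grid. Tree models: staged
    coordinate-wise search in STAGED_ORDER — at most
    sum(len(values)) evaluations instead of the full product. Ties keep
    the earlier (simpler) grid value.
    """
    grid = grid if grid is not None else DEFAULT_GRIDS[algo]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    if scorer is None:
        scorer = lambda params: _cv_mean_auc(algo, params, X, y, seed)

    if algo == "svm_rbf":
        names = list(grid)
        best_params, best_score = None, -np.inf
        for combo in product(*(grid[n] for n in names)):
            params = dict(zip(names, combo))
            score = scorer(params)
            if score > best_score:
                best_params, best_score = params, score
        return best_params

    order = [p for p in STAGED_ORDER.get(algo, tuple(grid)) if p in grid]
    order += [p for p in grid if p not in order]
    current = {p: grid[p][0] for p in grid}
    cache: dict[tuple, float] = {}

    def score_of(params: dict) -> float:
        key = tuple(params[p] for p in grid)
        if key not in cache:
            cache[key] = scorer(dict(params))
        return cache[key]

    for param in order:
        best_val, best_score = current[param], -np.inf
        for val in grid[param]:
            trial = {**current, param: val}
            score = score_of(trial)
            if score > best_score:
                best_val, best_score = val, score
        current[param] = best_val
    return current


def roc_auc(labels, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from a threshold sweep and the trapezoidal
    AUC, which equals P(score+ > score-) + 0.5 P(score+ = score-)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size != scores.size:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def pr_aupr(labels, scores) -> tuple[list[tuple[float, float]], float]:
    """Precision-recall points (recall ascending) and the step-wise
    area sum(dR_i * P_i) (average precision)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size != scores.size:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    precision, recall, _ = precision_recall_curve(labels, scores)
    points = list(zip(recall[::-1].tolist(), precision[::-1].tolist()))
    return points, float(average_precision_score(labels, scores))


@dataclass
class EvalResult:
    """Pooled out-of-fold evaluation of one algorithm on one table."""

    scores: np.ndarray
    roc: list[tuple[float, float]]
    auc: float
    pr: list[tuple[float, float]]
    aupr: float


@dataclass
class TrainedClassifier:
    algo: str
    hyperparams: dict
    model: object
    importance: dict[str, float] | None
    metadata: dict = field(default_factory=dict)


def _extract_importance(algo: str, model, names: list[str]) -> dict[str, float] | None:
    if algo == "random_forest":
        return dict(zip(names, model.feature_importances_.tolist()))
    if algo == "gbt":
        gain = model.get_booster().get_score(importance_type="gain")
        return {name: float(gain.get(f"f{i}", 0.0)) for i, name in enumerate(names)}
    return None


def cross_validated_scores(
    table: pd.DataFrame, algo: str, seed: int
) -> tuple[EvalResult, TrainedClassifier]:
    """Nested-CV evaluation: stratified 5-fold outer split; per outer
    fold, grid search (inner 5-fold CV on the training portion) picks
    hyperparameters and the held-out scores are recorded. The pooled
    out-of-fold scores define one ROC/PR curve per algorithm. The
    returned model is refit on all rows with the modal per-fold
    hyperparameters (first-seen on a tie)."""
    if algo not in ALGOS:
        raise UnsupportedAlgoError(f"unknown algorithm {algo!r}; expected one of {ALGOS}")
    X, y, names = split_xy(table)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("table must contain both classes")
    if counts.min() < 10:
        raise ValueError("need at least 10 rows per class")
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    pooled = np.empty(len(y), dtype=float)
    fold_assignment = np.empty(len(y), dtype=int)
    fold_params: list[dict] = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        params = staged_grid_search(X[tr], y[tr], algo, seed=seed)
        model = make_estimator(algo, params, seed)
        model.fit(X[tr], y[tr])
        pooled[te] = _scores_01(model, X[te])
        fold_assignment[te] = fold
        fold_params.append(params)
    roc, auc_value = roc_auc(y, pooled)
    pr, aupr_value = pr_aupr(y, pooled)
    result = EvalResult(pooled, roc, auc_value, pr, aupr_value)

    counted = Counter(tuple(sorted(p.items())) for p in fold_params)
    modal = dict(counted.most_common(1)[0][0])
    final = make_estimator(algo, modal, seed)
    final.fit(X, y)
    clf = TrainedClassifier(
        algo=algo,
        hyperparams=modal,
        model=final,
        importance=_extract_importance(algo, final, names),
        metadata={
            "seed": seed,
            "folds": N_FOLDS,
            "fold_hyperparams": fold_params,
            "fold_assignment": fold_assignment.tolist(),
            "feature_names": names,
        },
    )
    return result, clf


def _scores_01(model, X: np.ndarray) -> np.ndarray:
    """Probability-like positive-class score in [0, 1]."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    raw = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-raw))


def feature_importance_report(
    clf: TrainedClassifier, names: list[str] | None = None
) -> list[tuple[str, float]]:
    """Features sorted by gain-based importance, descending; stable
    (feature-order) tie-break, so the ranking is deterministic."""
    if clf.importance is None:
        raise UnsupportedAlgoError(
            f"feature importance is undefined for algorithm {clf.algo!r}"
        )
    names = names or clf.metadata.get("feature_names") or list(clf.importance)
    pairs = [(n, clf.importance.get(n, 0.0)) for n in names]
    return sorted(pairs, key=lambda kv: -kv[1])
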