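"""Single gradient-boosted classifier stage: stratified splits, balanced
class weights, seeded hyperparameter search with k-fold cross-validation,
test-set metrics and gain importances.

Splits allocate per-class test counts by largest-remainder apportionment
so the held-out set preserves class proportions exactly up to integer
rounding; ties in the remainders break by class order.  The multi-class
AUC is one-vs-rest, macro-averaged by default (configurable to
support-weighted averaging).  Missing genotype codes pass to the tree
learner as NaN and are routed by its default-direction mechanism.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .genotype import GenotypeMatrix, PhenotypeTable

__all__ = [
    "SplitSpec",
    "HyperParams",
    "SearchSpace",
    "FitResult",
    "largest_remainder_allocation",
    "stratified_split",
    "class_weights",
    "tune",
    "train_eval",
    "metric_report",
    "multiclass_auc",
]


@dataclass
class SplitSpec:
    train_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


@dataclass
class HyperParams:
    """Boosting hyperparameters; ``n_rounds`` is the resolved round count
    (set by :func:`tune` from the cross-validated early-stopping point)."""

    max_depth: int = 6
    min_child_weight: float = 1.0
    gamma: float = 0.0
    colsample_bytree: float = 1.0
    subsample: float = 1.0
    learning_rate: float = 0.1
    max_rounds: int = 500
    early_stopping_rounds: int = 35
    n_rounds: int | None = None

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0 < self.colsample_bytree <= 1:
            raise ValueError("colsample_bytree must be in (0, 1]")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must be in (0, 1]")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if min(self.min_child_weight, self.gamma) < 0:
            raise ValueError("min_child_weight and gamma must be >= 0")

    def to_xgb(self, n_classes: int, seed: int = 0) -> dict:
        return {
            "objective": "multi:softprob",
            "num_class": n_classes,
            "max_depth": int(self.max_depth),
            "min_child_weight": float(self.min_child_weight),
            "gamma": float(self.gamma),
            "colsample_bytree": float(self.colsample_bytree),
            "subsample": float(self.subsample),
            "eta": float(self.learning_rate),
            "eval_metric": "mlogloss",
            "tree_method": "hist",
            "seed": int(seed) % (2**31),
            "verbosity": 0,
        }


@dataclass
class SearchSpace:
    """Box bounds for the six tuned hyperparameters."""

    max_depth: tuple[int, int] = (2, 10)
    min_child_weight: tuple[float, float] = (0.0, 10.0)
    gamma: tuple[float, float] = (0.0, 5.0)
    colsample_bytree: tuple[float, float] = (0.3, 1.0)
    subsample: tuple[float, float] = (0.5, 1.0)
    learning_rate: tuple[float, float] = (0.01, 0.3)
    max_rounds: int = 500
    early_stopping_rounds: int = 35

    def sample(self, rng: np.random.Generator) -> HyperParams:
        return HyperParams(
            max_depth=int(rng.integers(self.max_depth[0], self.max_depth[1] + 1)),
            min_child_weight=float(rng.uniform(*self.min_child_weight)),
            gamma=float(rng.uniform(*self.gamma)),
            colsample_bytree=float(rng.uniform(*self.colsample_bytree)),
            subsample=float(rng.uniform(*self.subsample)),
            # log-uniform: small learning rates deserve equal coverage
            learning_rate=float(
                np.exp(rng.uniform(np.log(self.learning_rate[0]), np.log(self.learning_rate[1])))
            ),
            max_rounds=self.max_rounds,
            early_stopping_rounds=self.early_stopping_rounds,
        )


@dataclass
class FitResult:
    split: SplitSpec
    params: HyperParams
    cv_auc: float
    test_metrics: dict
    importance: dict[str, float]  # site id -> total gain
    model_path: str | None = None

    def to_json(self) -> str:
        payload = {
            "split": {"train_ids": self.split.train_ids,
                      "test_ids": self.split.test_ids, "seed": self.split.seed},
            "params": asdict(self.params),
            "cv_auc": self.cv_auc,
            "test_metrics": self.test_metrics,
            "importance": self.importance,
            "model_path": self.model_path,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def largest_remainder_allocation(counts: Sequence[int], total: int) -> list[int]:
    """Apportion ``total`` units proportionally to ``counts``.

    Floors of the exact quotas are assigned first; leftover units go to
    the largest fractional remainders, ties broken by position.
    """
    counts = list(counts)
    n = sum(counts)
    if total > n:
        raise ValueError(f"cannot allocate {total} among {n} items")
    if n == 0:
        return [0] * len(counts)
    quotas = [c * total / n for c in counts]
    alloc = [int(np.floor(q)) for q in quotas]
    leftover = total - sum(alloc)
    remainders = sorted(
        range(len(counts)), key=lambda i: (-(quotas[i] - alloc[i]), i)
    )
    for i in remainders[:leftover]:
        alloc[i] += 1
    return alloc


def stratified_split(phenos: PhenotypeTable, n_test: int, seed: int) -> SplitSpec:
    """Stratified train/test split with an exact held-out count.

    Per-class test counts follow largest-remainder proportional
    allocation; membership within a class is drawn uniformly at random.
    """
    counts = phenos.class_counts()
    classes = [c for c in phenos.class_set if counts[c] > 0]
    if any(counts[c] == 0 for c in phenos.class_set):
        raise ValueError("every class in class_set must be nonempty")
    n_samples = sum(counts.values())
    if n_test >= n_samples:
        raise ValueError("n_test must be smaller than the number of samples")
    alloc = largest_remainder_allocation([counts[c] for c in classes], n_test)
    for c, a in zip(classes, alloc):
        if a > counts[c]:
            raise ValueError(f"class {c!r} allocated {a} test samples, has {counts[c]}")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    by_class: dict[str, list[str]] = {c: [] for c in classes}
    for sid, lab in phenos.assignments.items():
        by_class[lab].append(sid)
    for c, a in zip(classes, alloc):
        members = by_class[c]
        picked = rng.choice(len(members), size=a, replace=False)
        picked_set = set(int(i) for i in picked)
        for i, sid in enumerate(members):
            (test_ids if i in picked_set else train_ids).append(sid)
    return SplitSpec(train_ids=train_ids, test_ids=test_ids, seed=seed)


def class_weights(labels: Sequence[str]) -> dict[str, float]:
    """Balanced weights: w_c = n / (k * n_c)."""
    labels = list(labels)
    uniq = sorted(set(labels))
    n, k = len(labels), len(uniq)
    counts = {c: labels.count(c) for c in uniq}
    if any(v == 0 for v in counts.values()):
        raise ValueError("empty class")
    return {c: n / (k * counts[c]) for c in uniq}


def multiclass_auc(
    y_true: np.ndarray, proba: np.ndarray, n_classes: int, average: str = "macro"
) -> float:
    """One-vs-rest multi-class ROC AUC over predicted probabilities.

    Classes absent from ``y_true`` are excluded from the average (their
    one-vs-rest curve is undefined).
    """
    present = np.unique(y_true)
    if len(present) < 2:
        return float("nan")
    if len(present) == n_classes:
        return float(
            roc_auc_score(y_true, proba, multi_class="ovr", average=average,
                          labels=np.arange(n_classes))
        )
    aucs, weights = [], []
    for c in present:
        bin_true = (y_true == c).astype(int)
        aucs.append(roc_auc_score(bin_true, proba[:, c]))
        weights.append(bin_true.sum())
    if average == "weighted":
        return float(np.average(aucs, weights=weights))
    return float(np.mean(aucs))


def _encode_labels(phenos: PhenotypeTable, sample_ids: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(phenos.class_set)}
    return np.array([index[phenos.assignments[s]] for s in sample_ids], dtype=int)


def _sample_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    n = len(y)
    counts = np.bincount(y, minlength=n_classes)
    present = counts > 0
    k = present.sum()
    w = np.zeros(n_classes)
    w[present] = n / (k * counts[present])
    return w[y]


def _cv_score(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    params: HyperParams,
    n_folds: int,
    seed: int,
    auc_average: str = "macro",
) -> tuple[float, int]:
    """Mean k-fold CV one-vs-rest AUC and mean early-stopped round count."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    aucs: list[float] = []
    rounds: list[int] = []
    xp = params.to_xgb(n_classes, seed=seed)
    for tr, va in skf.split(X, y):
        dtrain = xgb.DMatrix(X[tr], label=y[tr],
                             weight=_sample_weights(y[tr], n_classes),
                             missing=np.nan)
        dval = xgb.DMatrix(X[va], label=y[va], missing=np.nan)
        booster = xgb.train(
            xp, dtrain, num_boost_round=params.max_rounds,
            evals=[(dval, "val")],
            early_stopping_rounds=params.early_stopping_rounds,
            verbose_eval=False,
        )
        best_it = getattr(booster, "best_iteration", None)
        n_rounds = (best_it + 1) if best_it is not None else params.max_rounds
        rounds.append(n_rounds)
        proba = booster.predict(dval, iteration_range=(0, n_rounds))
        aucs.append(multiclass_auc(y[va], proba, n_classes, average=auc_average))
    valid = [a for a in aucs if not np.isnan(a)]
    mean_auc = float(np.mean(valid)) if valid else float("nan")
    return mean_auc, int(round(np.mean(rounds)))


def tune(
    matrix: GenotypeMatrix,
    phenos: PhenotypeTable,
    train_ids: Sequence[str],
    n_trials: int = 250,
    n_folds: int = 4,
    seed: int = 0,
    space: SearchSpace | None = None,
    auc_average: str = "macro",
) -> tuple[HyperParams, float]:
    """Seeded random search over the six-parameter space.

    Each trial scores a sampled configuration by mean ``n_folds``-fold
    cross-validated one-vs-rest AUC with balanced class weights and
    early stopping inside each fold.  Returns the best configuration
    (with its early-stopped round count resolved) and its CV AUC.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if space is None:
        space = SearchSpace()
    sample_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    rows = [sample_index[s] for s in train_ids]
    X = matrix.to_features()[rows]
    y = _encode_labels(phenos, train_ids)
    n_classes = len(phenos.class_set)
    rng = np.random.default_rng(seed)
    best: tuple[float, HyperParams] | None = None
    for _ in range(n_trials):
        cand = space.sample(rng)
        trial_seed = int(rng.integers(0, 2**31))
        score, n_rounds = _cv_score(X, y, n_classes, cand, n_folds, trial_seed,
                                    auc_average=auc_average)
        cand.n_rounds = max(1, n_rounds)
        if best is None or score > best[0]:
            best = (score, cand)
    assert best is not None
    return best[1], best[0]


def train_eval(
    matrix: GenotypeMatrix,
    phenos: PhenotypeTable,
    split: SplitSpec,
    params: HyperParams,
    cv_auc: float = float("nan"),
    auc_average: str = "macro",
    model_path: str | None = None,
) -> FitResult:
    """Fit on the training side of ``split`` and evaluate on the test side.

    The model trains with balanced per-sample weights for
    ``params.n_rounds`` boosting rounds (falling back to ``max_rounds``
    when unresolved).  Importance is the total gain per used feature;
    features never used do not appear in the map.  When ``model_path``
    is given the fitted booster is saved there in the library's native
    format and the path is recorded on the result.
    """
    sample_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    X = matrix.to_features()
    tr = [sample_index[s] for s in split.train_ids]
    te = [sample_index[s] for s in split.test_ids]
    y_tr = _encode_labels(phenos, split.train_ids)
    y_te = _encode_labels(phenos, split.test_ids)
    n_classes = len(phenos.class_set)
    if len(np.unique(y_tr)) < n_classes:
        raise ValueError("every class must be present in the training set")

    dtrain = xgb.DMatrix(
        X[tr], label=y_tr, weight=_sample_weights(y_tr, n_classes),
        missing=np.nan, feature_names=matrix.site_ids,
    )
    n_rounds = params.n_rounds or params.max_rounds
    booster = xgb.train(
        params.to_xgb(n_classes, seed=split.seed), dtrain,
        num_boost_round=n_rounds,
    )
    dtest = xgb.DMatrix(X[te], missing=np.nan, feature_names=matrix.site_ids)
    proba = booster.predict(dtest)
    y_pred = np.argmax(proba, axis=1)

    test_metrics = _compute_metrics(y_te, y_pred, proba, phenos.class_set,
                                    auc_average=auc_average)
    gains = booster.get_score(importance_type="total_gain")
    importance = {k: float(v) for k, v in gains.items() if v > 0}
    if model_path is not None:
        booster.save_model(model_path)
    return FitResult(split=split, params=params, cv_auc=float(cv_auc),
                     test_metrics=test_metrics, importance=importance,
                     model_path=model_path)


def _compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    proba: np.ndarray | None,
    class_set: Sequence[str],
    auc_average: str = "macro",
) -> dict:
    n_classes = len(class_set)
    labels = np.arange(n_classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    accuracy = float(np.trace(cm) / cm.sum())
    present = support > 0
    macro = {
        "precision": float(np.mean(prec[present])),
        "recall": float(np.mean(rec[present])),
        "f1": float(np.mean(f1[present])),
    }
    weighted = {
        "precision": float(np.average(prec[present], weights=support[present])),
        "recall": float(np.average(rec[present], weights=support[present])),
        "f1": float(np.average(f1[present], weights=support[present])),
    }
    auc = (
        multiclass_auc(y_true, proba, n_classes, average=auc_average)
        if proba is not None
        else float("nan")
    )
    per_class = {
        str(class_set[c]): {
            "precision": float(prec[c]),
            "recall": float(rec[c]),
            "f1": float(f1[c]),
            "support": int(support[c]),
        }
        for c in labels
    }
    return {
        "accuracy": accuracy,
        "per_class": per_class,
        "macro": macro,
        "weighted": weighted,
        "auc": auc,
        "confusion": cm.tolist(),
    }


def metrics_from_predictions(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_set: Sequence[str],
) -> dict:
    """Metrics from label sequences (no probabilities, hence no AUC)."""
    index = {c: i for i, c in enumerate(class_set)}
    yt = np.array([index[c] for c in y_true])
    yp = np.array([index[c] for c in y_pred])
    return _compute_metrics(yt, yp, None, class_set)


def metric_report(test_metrics: Mapping) -> pd.DataFrame:
    """Classification-report table: per-class rows plus accuracy,
    macro-avg and weighted-avg rows, with a support column."""
    rows = []
    total_support = 0
    for cls, m in test_metrics["per_class"].items():
        rows.append(
            {"": cls, "precision": m["precision"], "recall": m["recall"],
             "f1-score": m["f1"], "support": m["support"]}
        )
        total_support += m["support"]
    rows.append({"": "accuracy", "precision": np.nan, "recall": np.nan,
                 "f1-score": test_metrics["accuracy"], "support": total_support})
    for name, key in (("macro avg", "macro"), ("weighted avg", "weighted")):
        m = test_metrics[key]
        rows.append({"": name, "precision": m["precision"], "recall": m["recall"],
                     "f1-score": m["f1"], "support": total_support})
    return pd.DataFrame(rows).set_index("")
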