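"""Seven-subgroup supervised classification on metagene features.

Samples are rows, metagene coefficients are features.  The workflow is:
stratified 80/20 split with ceiling-rounded per-class training counts,
min-max scaling to [0, 1] fitted on the training set only, randomized grid
search with stratified k-fold cross-validation over four model families
(RBF-kernel SVM, random forest, gradient boosting, k-nearest neighbours),
and an imbalance-aware evaluation suite.

Because the subgroups are strongly imbalanced, balanced accuracy is the
primary metric.  Two conventions exist in the literature and both are
reported: the macro-averaged recall, and the macro average of per-class
(sensitivity + specificity) / 2.  Model selection during cross-validation
uses the sensitivity/specificity convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .matrix_io import SUBGROUP_LABELS

FAMILIES = ("svm_rbf", "random_forest", "gradient_boosting", "knn")

#: Default randomized-search ranges per family.  Continuous parameters are
#: sampled uniformly over the stated interval, integer parameters uniformly
#: over the stated values.
DEFAULT_GRIDS: dict[str, dict] = {
    "svm_rbf": {"C": (0.01, 50.0), "sigma": (0.001, 1.0)},
    "random_forest": {"mtry": (2, 6)},
    "gradient_boosting": {
        "nrounds": (50, 100, 150, 200),
        "eta": (0.01, 0.3),
        "max_depth": (3, 10),
        "gamma": (0.0, 5.0),
        "colsample_bytree": (0.5, 1.0),
        "min_child_weight": (1, 10),
        "subsample": (0.5, 1.0),
    },
    "knn": {"k": tuple(range(3, 16, 2))},
}


@dataclass
class TrainTestSplit:
    """Stratified split indices; per class, ceil(train_fraction * n) samples
    go to training."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    train_counts: dict[str, int]

    @property
    def n_train(self) -> int:
        return len(self.train_indices)

    @property
    def n_test(self) -> int:
        return len(self.test_indices)

    def train_percentages(self) -> dict[str, float]:
        """Per-class share of the training set, in percent (two decimals)."""
        total = self.n_train
        return {c: round(100.0 * n / total, 2) for c, n in self.train_counts.items()}


def stratified_split(labels: Sequence[str], train_fraction: float = 0.8, seed: int = 0) -> TrainTestSplit:
    """Per class, draw ceil(train_fraction * n_c) samples (seeded, uniform)
    for training; the remainder forms the test set."""
    labels = list(labels)
    if not (0.0 < train_fraction <= 1.0):
        raise ValueError("train_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    classes = sorted(set(labels), key=lambda c: (_vocab_rank(c), c))
    train_idx: list[int] = []
    test_idx: list[int] = []
    counts: dict[str, int] = {}
    for c in classes:
        members = np.array([i for i, lab in enumerate(labels) if lab == c])
        if len(members) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members")
        n_train = math.ceil(train_fraction * len(members))
        perm = rng.permutation(len(members))
        train_idx.extend(members[perm[:n_train]])
        test_idx.extend(members[perm[n_train:]])
        counts[c] = n_train
    if not test_idx:
        warnings.warn("empty test set (train_fraction covers every class fully)")
    return TrainTestSplit(
        train_indices=np.array(sorted(train_idx), dtype=int),
        test_indices=np.array(sorted(test_idx), dtype=int),
        seed=seed,
        train_counts=counts,
    )


def _vocab_rank(label: str) -> int:
    try:
        return SUBGROUP_LABELS.index(label)
    except ValueError:
        return len(SUBGROUP_LABELS)


@dataclass
class MinMaxScaler01:
    """Per-feature affine map fitted on training data: subtract the training
    minimum, divide by the training range, clip to [0, 1].  A constant
    training feature maps to 0 everywhere."""

    mins: np.ndarray
    ranges: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        safe = np.where(self.ranges > 0, self.ranges, 1.0)
        out = (X - self.mins) / safe
        out[:, self.ranges == 0] = 0.0
        return np.clip(out, 0.0, 1.0)


def minmax_scale(train_features: np.ndarray, *other_feature_sets: np.ndarray):
    """Fit a 0-1 scaler on the training features and apply it everywhere.

    Returns ``(scaled_train, *scaled_others, scaler)``.
    """
    train = np.asarray(train_features, dtype=float)
    if np.isnan(train).any():
        raise ValueError("training features contain missing values")
    scaler = MinMaxScaler01(
        mins=train.min(axis=0), ranges=train.max(axis=0) - train.min(axis=0)
    )
    out = [scaler.transform(train)]
    out.extend(scaler.transform(np.asarray(x, dtype=float)) for x in other_feature_sets)
    return (*out, scaler)


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class FittedModel:
    """A tuned classifier with its class vocabulary and selected config."""

    family: str
    estimator: object
    classes: list[str]
    config: dict
    seed: int
    cv_score: float
    cv_table: pd.DataFrame = field(repr=False, default=None)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities in ``self.classes`` order, rows normalized to 1."""
        P = self.estimator.predict_proba(np.asarray(X, dtype=float))
        P = np.clip(P, 0.0, None)
        rows = P.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        return P / rows

    def predict(self, X: np.ndarray) -> list[str]:
        """Argmax of the normalized probabilities (ties -> lowest class index)."""
        P = self.predict_proba(X)
        return [self.classes[i] for i in np.argmax(P, axis=1)]


def _sample_config(family: str, grid: dict, rng: np.random.Generator) -> dict:
    cfg = {}
    for name, rng_spec in grid.items():
        if isinstance(rng_spec, tuple) and len(rng_spec) == 2 and all(
            isinstance(v, float) for v in rng_spec
        ):
            cfg[name] = float(rng.uniform(*rng_spec))
        elif isinstance(rng_spec, tuple) and len(rng_spec) == 2 and all(
            isinstance(v, int) for v in rng_spec
        ):
            cfg[name] = int(rng.integers(rng_spec[0], rng_spec[1] + 1))
        else:  # explicit value list
            cfg[name] = rng_spec[int(rng.integers(len(rng_spec)))]
    return cfg


def _build_estimator(family: str, cfg: dict, seed: int, n_features: int, n_classes: int):
    if family == "svm_rbf":
        # kernlab-style sigma: k(x,y) = exp(-sigma * ||x-y||^2), i.e. gamma
        return SVC(
            C=cfg["C"], gamma=cfg["sigma"], kernel="rbf",
            probability=True, random_state=seed,
        )
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=500,
            max_features=min(int(cfg["mtry"]), n_features),
            random_state=seed,
            n_jobs=1,
        )
    if family == "gradient_boosting":
        return XGBClassifier(
            n_estimators=int(cfg["nrounds"]),
            learning_rate=cfg["eta"],
            max_depth=int(cfg["max_depth"]),
            gamma=cfg["gamma"],
            colsample_bytree=cfg["colsample_bytree"],
            min_child_weight=cfg["min_child_weight"],
            subsample=cfg["subsample"],
            objective="multi:softprob" if n_classes > 2 else "binary:logistic",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=int(cfg["k"]))
    raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")


def _needs_int_labels(family: str) -> bool:
    return family == "gradient_boosting"


def balanced_accuracy_sens_spec(confusion: np.ndarray) -> float:
    """Mean over classes of (recall + specificity) / 2, skipping classes with
    no true members."""
    C = np.asarray(confusion, dtype=float)
    total = C.sum()
    vals = []
    for i in range(C.shape[0]):
        tp = C[i, i]
        fn = C[i].sum() - tp
        fp = C[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            continue
        recall = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp > 0 else np.nan
        vals.append((recall + spec) / 2.0)
    return float(np.mean(vals))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    C = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        C[t, p] += 1
    return C


def tune_and_train(
    features: np.ndarray,
    labels: Sequence[str],
    family: str = "svm_rbf",
    grid: Optional[dict] = None,
    n_candidates: int = 20,
    cv_folds: int = 10,
    seed: int = 0,
) -> FittedModel:
    """Randomized grid search with stratified k-fold CV, then a full refit.

    ``n_candidates`` configurations are sampled (seeded) from the grid; the
    one maximizing mean CV balanced accuracy (sensitivity/specificity
    convention) wins, ties resolved toward the earlier-sampled
    configuration.  The fitted model predicts probabilities normalized over
    the classes present in ``labels``.
    """
    X = np.asarray(features, dtype=float)
    labels = list(labels)
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")
    if X.shape[0] != len(labels):
        raise ValueError("features and labels disagree in length")
    if X.shape[0] < cv_folds:
        raise ValueError(f"{X.shape[0]} training samples < {cv_folds} CV folds")
    classes = sorted(set(labels), key=lambda c: (_vocab_rank(c), c))
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[l] for l in labels])

    grid = dict(DEFAULT_GRIDS[family]) if grid is None else grid
    rng = np.random.default_rng(seed)
    candidates = []
    for _ in range(n_candidates):
        cfg = _sample_config(family, grid, rng)
        if cfg not in candidates:
            candidates.append(cfg)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31))
    folds = list(skf.split(X, y))
    rows = []
    best_cfg, best_score = None, -np.inf
    for cfg in candidates:
        fold_scores = []
        for tr, va in folds:
            est = _build_estimator(family, cfg, seed, X.shape[1], len(classes))
            est.fit(X[tr], y[tr])
            pred = np.asarray(est.predict(X[va]))
            fold_scores.append(
                balanced_accuracy_sens_spec(_confusion(y[va], pred, len(classes)))
            )
        score = float(np.mean(fold_scores))
        rows.append({**cfg, "cv_balanced_accuracy": score})
        if score > best_score:
            best_cfg, best_score = cfg, score

    final = _build_estimator(family, best_cfg, seed, X.shape[1], len(classes))
    final.fit(X, y)
    est = _LabelDecodingEstimator(final, classes)
    return FittedModel(
        family=family,
        estimator=est,
        classes=classes,
        config=best_cfg,
        seed=seed,
        cv_score=best_score,
        cv_table=pd.DataFrame(rows),
    )


class _LabelDecodingEstimator:
    """Keeps the underlying estimator working on integer codes while the
    public surface speaks subgroup labels."""

    def __init__(self, estimator, classes: list[str]):
        self._est = estimator
        self.classes = classes

    def predict_proba(self, X):
        P = self._est.predict_proba(X)
        # map estimator class order (integer codes) onto vocabulary order
        order = np.asarray(self._est.classes_, dtype=int)
        out = np.zeros((P.shape[0], len(self.classes)))
        out[:, order] = P
        return out


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationReport:
    """Confusion matrix, per-class and macro metrics, and per-sample
    probabilities for one labelled feature set."""

    class_names: list[str]
    confusion: np.ndarray
    per_class: pd.DataFrame = field(repr=False)
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    balanced_accuracy_macro_recall: float
    balanced_accuracy_sens_spec: float
    macro_auc: Optional[float]
    probabilities: pd.DataFrame = field(repr=False, default=None)
    predictions: list[str] = field(default=None)

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "balanced_accuracy_macro_recall": self.balanced_accuracy_macro_recall,
            "balanced_accuracy_sens_spec": self.balanced_accuracy_sens_spec,
            "macro_auc": self.macro_auc,
        }


def metrics_from_confusion(confusion: np.ndarray, class_names: Sequence[str]) -> dict:
    """All confusion-derived metrics.

    Per class: precision TP/(TP+FP), recall TP/(TP+FN), specificity
    TN/(TN+FP), F1.  Macro values are unweighted means over classes that
    have true members; classes without true members are reported as NaN and
    excluded from macros with a warning.
    """
    C = np.asarray(confusion, dtype=float)
    class_names = list(class_names)
    n = C.shape[0]
    if C.shape != (n, n) or n != len(class_names):
        raise ValueError("confusion must be square and match class_names")
    total = C.sum()
    precision = np.full(n, np.nan)
    recall = np.full(n, np.nan)
    specificity = np.full(n, np.nan)
    f1 = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    for i in range(n):
        tp = C[i, i]
        fn = C[i].sum() - tp
        fp = C[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            continue
        defined[i] = True
        recall[i] = tp / (tp + fn)
        precision[i] = tp / (tp + fp) if tp + fp > 0 else 0.0
        specificity[i] = tn / (tn + fp) if tn + fp > 0 else np.nan
        f1[i] = (
            2 * precision[i] * recall[i] / (precision[i] + recall[i])
            if precision[i] + recall[i] > 0
            else 0.0
        )
    if not defined.all():
        absent = [class_names[i] for i in range(n) if not defined[i]]
        warnings.warn(f"classes with no true members excluded from macro means: {absent}")
    per_class = pd.DataFrame(
        {
            "class": class_names,
            "precision": precision,
            "recall": recall,
            "specificity": specificity,
            "f1": f1,
        }
    )
    macro_recall = float(np.nanmean(recall[defined]))
    return {
        "per_class": per_class,
        "macro_precision": float(np.nanmean(precision[defined])),
        "macro_recall": macro_recall,
        "macro_f1": float(np.nanmean(f1[defined])),
        "accuracy": float(np.trace(C) / total) if total else float("nan"),
        "balanced_accuracy_macro_recall": macro_recall,
        "balanced_accuracy_sens_spec": float(
            np.nanmean(((recall + specificity) / 2.0)[defined])
        ),
    }


def evaluate(model: FittedModel, features: np.ndarray, labels: Sequence[str]) -> EvaluationReport:
    """Full metric suite for ``model`` on a labelled feature set."""
    X = np.asarray(features, dtype=float)
    labels = list(labels)
    classes = model.classes
    unknown = sorted(set(labels) - set(classes))
    if unknown:
        raise ValueError(f"labels outside model vocabulary: {unknown}")
    P = model.predict_proba(X)
    preds = model.predict(X)
    idx = {c: i for i, c in enumerate(classes)}
    y_true = np.array([idx[l] for l in labels])
    y_pred = np.array([idx[l] for l in preds])
    C = _confusion(y_true, y_pred, len(classes))
    m = metrics_from_confusion(C, classes)

    aucs = np.full(len(classes), np.nan)
    for i, c in enumerate(classes):
        pos = y_true == i
        if pos.any() and (~pos).any():
            _, aucs[i] = roc_curve_ovr(labels, P[:, i], c)
    defined = ~np.isnan(aucs)
    per_class = m["per_class"].copy()
    per_class["auc"] = aucs
    return EvaluationReport(
        class_names=list(classes),
        confusion=C,
        per_class=per_class,
        macro_precision=m["macro_precision"],
        macro_recall=m["macro_recall"],
        macro_f1=m["macro_f1"],
        accuracy=m["accuracy"],
        balanced_accuracy_macro_recall=m["balanced_accuracy_macro_recall"],
        balanced_accuracy_sens_spec=m["balanced_accuracy_sens_spec"],
        macro_auc=float(np.mean(aucs[defined])) if defined.any() else None,
        probabilities=pd.DataFrame(P, columns=classes),
        predictions=preds,
    )


def misclassification_report(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    probabilities: np.ndarray,
    class_names: Sequence[str],
) -> pd.DataFrame:
    """One row per misclassified sample: true label, predicted label, the
    probability assigned to the true class and to the predicted class.

    The predicted label must be the argmax of its probability row and each
    row must sum to 1; by construction the predicted-label probability is
    always >= the true-label probability.
    """
    P = np.asarray(probabilities, dtype=float)
    class_names = list(class_names)
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if P.shape != (len(true_labels), len(class_names)):
        raise ValueError("probability matrix shape mismatch")
    sums = P.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"probability row {bad} sums to {sums[bad]:.6f}, not 1")
    idx = {c: i for i, c in enumerate(class_names)}
    rows = []
    for s, (t, p) in enumerate(zip(true_labels, predicted_labels)):
        argmax = class_names[int(np.argmax(P[s]))]
        if argmax != p:
            raise ValueError(
                f"sample {s}: predicted label {p!r} is not the argmax class {argmax!r}"
            )
        if t != p:
            rows.append(
                {
                    "sample_index": s,
                    "true_label": t,
                    "predicted_label": p,
                    "true_label_probability": P[s, idx[t]],
                    "predicted_label_probability": P[s, idx[p]],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_index",
            "true_label",
            "predicted_label",
            "true_label_probability",
            "predicted_label_probability",
        ],
    )


def roc_curve_ovr(
    true_labels: Sequence[str], scores: np.ndarray, positive_class: str
) -> tuple[list[tuple[float, float]], float]:
    """One-vs-rest ROC curve and AUC for one class.

    Thresholds sweep the unique scores; the AUC is the Mann-Whitney
    statistic (fraction of positive/negative pairs correctly ordered, ties
    counted 1/2), which equals the trapezoidal area under the returned
    curve.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.array([l == positive_class for l in true_labels])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative examples")
    # curve: descending threshold sweep over unique scores
    points = [(0.0, 0.0)]
    for thr in np.unique(scores)[::-1]:
        sel = scores >= thr
        points.append((float((sel & ~y).sum() / n_neg), float((sel & y).sum() / n_pos)))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return points, float(auc)
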