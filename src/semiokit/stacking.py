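"""Feature selection, stacked generalization, and macro-averaged metrics.

The stack is the two-stage scheme standard in clinical tabular work:
stage 1 runs k-fold cross-validation over the training set, each base
classifier contributing its out-of-fold probability as a meta-feature
(test-set meta-features average the k fold models); stage 2 fits a
logistic-regression meta-learner on the out-of-fold matrix.  Class A
(generalized epilepsy) is the positive axis throughout; class B is
focal.  Macro precision/recall average the two per-class values and F1
is their harmonic mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .cohort import FOCAL, GENERALIZED, FeatureMatrix

POSITIVE_LABEL = GENERALIZED  # class A

SELECTION_METHODS = ("rfe", "rf_importance", "mutual_info", "kbest_anova")


@dataclass(frozen=True)
class SelectionConfig:
    method: str
    k: int

    def __post_init__(self) -> None:
        if self.method not in SELECTION_METHODS:
            raise ValueError(f"unknown selection method {self.method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _encode(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    bad = set(np.unique(y)) - {GENERALIZED, FOCAL}
    if bad:
        raise ValueError(f"labels outside {{A,B}}: {sorted(bad)}")
    return (y == POSITIVE_LABEL).astype(int)


def binary_mutual_information(X: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Plug-in mutual information (nats) of each binary feature with the label.

    Computed from each feature's empirical 2x2 joint table with the
    convention 0·log0 = 0; a constant feature scores 0.
    """
    X = np.asarray(X, dtype=float)
    n = len(y01)
    mi = np.zeros(X.shape[1])
    for fv in (0, 1):
        for yv in (0, 1):
            p_joint = ((X == fv) & (y01[:, None] == yv)).mean(axis=0)
            p_f = (X == fv).mean(axis=0)
            p_y = (y01 == yv).mean()
            with np.errstate(divide="ignore", invalid="ignore"):
                term = p_joint * np.log(p_joint / (p_f * p_y))
            mi += np.where(p_joint > 0, term, 0.0)
    return mi


def select_features(
    X: np.ndarray, y: np.ndarray, cfg: SelectionConfig, seed: int = 0
) -> list[int]:
    """Indices of the k retained features, best first."""
    X = np.asarray(X)
    y01 = _encode(np.asarray(y))
    if cfg.k > X.shape[1]:
        raise ValueError(f"k={cfg.k} exceeds {X.shape[1]} features")
    if cfg.method == "kbest_anova":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant features warn; score 0
            scores, _ = f_classif(X, y01)
        scores = np.nan_to_num(scores, nan=0.0)
    elif cfg.method == "mutual_info":
        scores = binary_mutual_information(X, y01)
    elif cfg.method == "rf_importance":
        rf = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
        scores = rf.fit(X, y01).feature_importances_
    else:  # rfe
        est = LogisticRegression(max_iter=1000)
        rfe = RFE(est, n_features_to_select=cfg.k, step=1)
        rfe.fit(X, y01)
        kept = np.flatnonzero(rfe.support_)
        order = np.argsort(-np.abs(rfe.estimator_.coef_[0]), kind="stable")
        return [int(kept[i]) for i in order]
    order = np.argsort(-scores, kind="stable")[: cfg.k]
    return [int(i) for i in order]


# ---------------------------------------------------------------------------
# stacked generalization


@dataclass
class StackedModel:
    """Configuration + fitted state of the two-stage stack."""

    base_models: list[tuple[str, object]]
    n_folds: int = 5
    meta_learner: object = field(
        default_factory=lambda: LogisticRegression(C=1.0, max_iter=1000)
    )
    fold_assignment: np.ndarray | None = None
    fitted_base_: list[list[object]] | None = None
    fitted_meta_: object | None = None
    meta_train_: np.ndarray | None = None


@dataclass
class StackPredictions:
    proba: np.ndarray  # P(class A) per test row
    labels: np.ndarray  # hard labels, generalized/focal
    meta_features: np.ndarray  # n_test x n_base


def default_base_models(seed: int = 0) -> list[tuple[str, object]]:
    """The four base classifiers of the reference roster."""
    from lightgbm import LGBMClassifier
    from xgboost import XGBClassifier

    return [
        ("decision_tree", DecisionTreeClassifier(max_depth=8, random_state=seed)),
        (
            "random_forest",
            RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1),
        ),
        (
            "xgboost",
            XGBClassifier(
                n_estimators=200,
                max_depth=4,
                learning_rate=0.1,
                eval_metric="logloss",
                random_state=seed,
                n_jobs=1,
                verbosity=0,
            ),
        ),
        (
            "lightgbm",
            LGBMClassifier(
                n_estimators=200, max_depth=4, random_state=seed, n_jobs=1, verbose=-1
            ),
        ),
    ]


def xgb_rf_stack(seed: int = 0, n_folds: int = 5) -> StackedModel:
    """The XGBoost + random-forest stack (the best-performing pairing)."""
    roster = dict(default_base_models(seed))
    return StackedModel(
        base_models=[("xgboost", roster["xgboost"]), ("random_forest", roster["random_forest"])],
        n_folds=n_folds,
    )


def _make_folds(
    y01: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    for attempt in range(5):
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        folds = list(kf.split(np.zeros_like(y01), y01))
        if all(len(np.unique(y01[tr])) == 2 for tr, _ in folds):
            return folds
    raise ValueError("could not build folds with both classes in every training part")


def fit_stack(
    train: FeatureMatrix,
    test: FeatureMatrix,
    model: StackedModel,
    seed: int = 0,
) -> tuple[StackedModel, StackPredictions]:
    """Fit the two-stage stack and predict the test set.

    Stage 1: per base model and per fold, fit on the other folds, write
    the held-out fold's probability into the meta-training matrix, and
    predict the whole test set; the test meta-feature is the mean over
    the fold models.  Stage 2: the logistic meta-learner is fit on the
    out-of-fold matrix and applied to the test meta-features.
    """
    y_train = _encode(train.y)
    counts = np.bincount(y_train, minlength=2)
    if counts.min() < model.n_folds:
        raise ValueError("need at least n_folds rows per class in train")
    folds = _make_folds(y_train, model.n_folds, seed)
    n_train, n_test = len(y_train), len(test.doc_ids)
    k = len(model.base_models)
    meta_train = np.zeros((n_train, k))
    meta_test = np.zeros((n_test, k))
    fold_assignment = np.empty(n_train, dtype=int)
    fitted_base: list[list[object]] = []
    for j, (_name, base) in enumerate(model.base_models):
        fold_models = []
        test_cols = np.zeros((model.n_folds, n_test))
        for f, (tr_idx, val_idx) in enumerate(folds):
            est = clone(base)
            if "random_state" in est.get_params():
                est.set_params(random_state=seed + f)
            est.fit(train.X[tr_idx], y_train[tr_idx])
            pos = list(est.classes_).index(1)
            meta_train[val_idx, j] = est.predict_proba(train.X[val_idx])[:, pos]
            test_cols[f] = est.predict_proba(test.X)[:, pos]
            fold_models.append(est)
            fold_assignment[val_idx] = f
        meta_test[:, j] = test_cols.mean(axis=0)
        fitted_base.append(fold_models)
    meta = clone(model.meta_learner)
    if "random_state" in meta.get_params():
        meta.set_params(random_state=seed)
    meta.fit(meta_train, y_train)
    pos = list(meta.classes_).index(1)
    proba = meta.predict_proba(meta_test)[:, pos]
    labels = np.where(proba >= 0.5, GENERALIZED, FOCAL).astype(object)
    model.fold_assignment = fold_assignment
    model.fitted_base_ = fitted_base
    model.fitted_meta_ = meta
    model.meta_train_ = meta_train
    return model, StackPredictions(proba=proba, labels=labels, meta_features=meta_test)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class BinaryConfusion:
    tp_a: int
    fp_a: int
    fn_a: int
    tp_b: int
    fp_b: int
    fn_b: int

    def __post_init__(self) -> None:
        if min(self.tp_a, self.fp_a, self.fn_a, self.tp_b, self.fp_b, self.fn_b) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.fp_a != self.fn_b or self.fn_a != self.fp_b:
            raise ValueError("two-class consistency violated (fp_a=fn_b, fn_a=fp_b)")


def confusion(pred: np.ndarray, y: np.ndarray) -> BinaryConfusion:
    pred = np.asarray(pred)
    y = np.asarray(y)
    if len(pred) != len(y):
        raise ValueError("pred and y must have equal length")
    for arr in (pred, y):
        bad = set(np.unique(arr)) - {GENERALIZED, FOCAL}
        if bad:
            raise ValueError(f"labels outside {{A,B}}: {sorted(bad)}")
    a, b = GENERALIZED, FOCAL
    return BinaryConfusion(
        tp_a=int(np.sum((pred == a) & (y == a))),
        fp_a=int(np.sum((pred == a) & (y == b))),
        fn_a=int(np.sum((pred == b) & (y == a))),
        tp_b=int(np.sum((pred == b) & (y == b))),
        fp_b=int(np.sum((pred == b) & (y == a))),
        fn_b=int(np.sum((pred == a) & (y == b))),
    )


def per_class_precision(conf: BinaryConfusion) -> tuple[float, float]:
    pa = conf.tp_a / (conf.tp_a + conf.fp_a) if conf.tp_a + conf.fp_a else 0.0
    pb = conf.tp_b / (conf.tp_b + conf.fp_b) if conf.tp_b + conf.fp_b else 0.0
    return pa, pb


def macro_metrics(conf: BinaryConfusion) -> tuple[float, float, float]:
    """Macro precision, recall and F1.

    Precision = (TP_A/(TP_A+FP_A) + TP_B/(TP_B+FP_B)) / 2, recall the
    analogue with FN, F1 = 2PR/(P+R).  A zero denominator contributes 0
    to its average with a warning.
    """
    if conf.tp_a + conf.fp_a + conf.fn_a + conf.tp_b == 0:
        raise ValueError("all-zero confusion")

    def ratio(num: int, den: int, what: str) -> float:
        if den == 0:
            warnings.warn(f"zero denominator for {what}; term contributes 0",
                          stacklevel=3)
            return 0.0
        return num / den

    precision = 0.5 * (
        ratio(conf.tp_a, conf.tp_a + conf.fp_a, "precision(A)")
        + ratio(conf.tp_b, conf.tp_b + conf.fp_b, "precision(B)")
    )
    recall = 0.5 * (
        ratio(conf.tp_a, conf.tp_a + conf.fn_a, "recall(A)")
        + ratio(conf.tp_b, conf.tp_b + conf.fn_b, "recall(B)")
    )
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation; ties get midranks.

    ``scores`` are per-row probabilities of class A (generalized).
    """
    scores = np.asarray(scores, dtype=float)
    y01 = _encode(np.asarray(y))
    n_pos = int(y01.sum())
    n_neg = len(y01) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    rank_sum_pos = float(ranks[y01 == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_points(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(fpr, tpr, threshold) rows for export, sweeping unique scores."""
    scores = np.asarray(scores, dtype=float)
    y01 = _encode(np.asarray(y))
    order = np.argsort(-scores, kind="stable")
    s, ys = scores[order], y01[order]
    n_pos, n_neg = ys.sum(), len(ys) - ys.sum()
    pts = [(0.0, 0.0, np.inf)]
    tp = fp = 0
    for i in range(len(ys)):
        tp += ys[i]
        fp += 1 - ys[i]
        if i + 1 == len(ys) or s[i + 1] != s[i]:
            pts.append((fp / n_neg, tp / n_pos, s[i]))
    return np.array(pts)


def grid_search_cv(
    estimator: object,
    param_grid: dict[str, Sequence],
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    scoring: str = "f1_macro",
) -> tuple[dict, float]:
    """Generic grid search with stratified k-fold CV; returns (params, score)."""
    y01 = _encode(np.asarray(y))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(estimator, param_grid, cv=cv, scoring=scoring, n_jobs=1)
    gs.fit(np.asarray(X), y01)
    return gs.best_params_, float(gs.best_score_)
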