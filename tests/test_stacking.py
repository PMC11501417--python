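import numpy as np
import pytest

from semiokit.cohort import FOCAL, GENERALIZED, FeatureMatrix, SymptomVocabulary
from semiokit.stacking import (
    BinaryConfusion,
    SelectionConfig,
    StackedModel,
    binary_mutual_information,
    confusion,
    fit_stack,
    grid_search_cv,
    macro_metrics,
    per_class_precision,
    roc_auc,
    roc_points,
    select_features,
    xgb_rf_stack,
)


def _labels(y01):
    return np.where(np.asarray(y01) == 1, GENERALIZED, FOCAL).astype(object)


def _planted_design(n=2000, p=8, seed=0):
    """Feature 0 is strongly class-dependent; the rest are independent noise."""
    rng = np.random.default_rng(seed)
    y01 = rng.integers(0, 2, size=n)
    X = (rng.random((n, p)) < 0.5).astype(np.int8)
    X[:, 0] = (rng.random(n) < np.where(y01 == 1, 0.9, 0.1)).astype(np.int8)
    return X, _labels(y01)


# ---------------------------------------------------------------------------
# feature selection


def test_k_equal_to_n_features_is_identity():
    X, y = _planted_design(n=300)
    for method in ("kbest_anova", "mutual_info", "rf_importance", "rfe"):
        kept = select_features(X, y, SelectionConfig(method, X.shape[1]), seed=0)
        assert sorted(kept) == list(range(X.shape[1]))


@pytest.mark.parametrize("method", ["kbest_anova", "mutual_info", "rf_importance", "rfe"])
def test_planted_feature_ranked_first(method):
    X, y = _planted_design(n=2000, seed=1)
    kept = select_features(X, y, SelectionConfig(method, 3), seed=1)
    assert kept[0] == 0


def test_planted_top1_consistent_across_seeds():
    for seed in range(5):
        X, y = _planted_design(n=2000, seed=seed)
        tops = {
            select_features(X, y, SelectionConfig(m, 1), seed=seed)[0]
            for m in ("kbest_anova", "mutual_info", "rf_importance", "rfe")
        }
        assert tops == {0}


def test_mutual_information_identities():
    rng = np.random.default_rng(2)
    y01 = rng.integers(0, 2, size=5000)
    X = np.column_stack([rng.integers(0, 2, size=5000), y01])
    mi = binary_mutual_information(X, y01)
    assert abs(mi[0]) < 0.002  # independent feature
    p = y01.mean()
    entropy = -(p * np.log(p) + (1 - p) * np.log(1 - p))
    assert mi[1] == pytest.approx(entropy)  # the label itself carries H(y)


def test_constant_feature_scores_zero():
    X, y = _planted_design(n=200)
    X[:, 3] = 1
    kept = select_features(X, y, SelectionConfig("kbest_anova", X.shape[1]), seed=0)
    assert kept[-1] == 3 or kept.index(3) > kept.index(0)


def test_selection_config_validation():
    with pytest.raises(ValueError):
        SelectionConfig("pca", 3)
    with pytest.raises(ValueError):
        SelectionConfig("rfe", 0)


# ---------------------------------------------------------------------------
# stacking


def _fm(X, y):
    vocab = SymptomVocabulary(
        term_ids=tuple(f"S{j}" for j in range(X.shape[1])),
        labels=tuple(f"s{j}" for j in range(X.shape[1])),
    )
    return FeatureMatrix(
        doc_ids=[f"d{i}" for i in range(len(y))], X=X, y=y, vocab=vocab
    )


def test_meta_training_matrix_structure():
    X, y = _planted_design(n=200, seed=3)
    train, test = _fm(X[:150], y[:150]), _fm(X[150:], y[150:])
    model, preds = fit_stack(train, test, xgb_rf_stack(0), seed=0)
    assert model.meta_train_.shape == (150, 2)
    # every training row predicted exactly once out-of-fold
    assert sorted(np.unique(model.fold_assignment)) == list(range(5))
    assert np.bincount(model.fold_assignment).sum() == 150
    assert preds.meta_features.shape == (50, 2)
    assert preds.proba.shape == (50,)


class _Constant:
    """Uninformative base model emitting probability 0.5 everywhere."""

    def __init__(self):
        self.classes_ = np.array([0, 1])

    def get_params(self, deep=True):
        return {}

    def set_params(self, **kw):
        return self

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        return np.full((len(X), 2), 0.5)


def test_constant_base_model_degenerates_to_majority_class():
    rng = np.random.default_rng(4)
    y01 = (rng.random(400) < 0.6).astype(int)
    X = rng.integers(0, 2, size=(400, 5)).astype(np.int8)
    y = _labels(y01)
    train, test = _fm(X[:300], y[:300]), _fm(X[300:], y[300:])
    model = StackedModel(base_models=[("const", _Constant())])
    _, preds = fit_stack(train, test, model, seed=0)
    majority = max(np.mean(test.y == GENERALIZED), np.mean(test.y == FOCAL))
    accuracy = np.mean(preds.labels == test.y)
    assert accuracy == pytest.approx(majority, abs=0.02)


def test_stack_reproducible_for_fixed_seed():
    X, y = _planted_design(n=300, seed=5)
    train, test = _fm(X[:200], y[:200]), _fm(X[200:], y[200:])
    _, p1 = fit_stack(train, test, xgb_rf_stack(0), seed=7)
    _, p2 = fit_stack(train, test, xgb_rf_stack(0), seed=7)
    assert np.array_equal(p1.proba, p2.proba)
    assert np.array_equal(p1.meta_features, p2.meta_features)


def test_stack_needs_enough_rows_per_class():
    X, y = _planted_design(n=40, seed=6)
    y[:] = FOCAL
    y[:3] = GENERALIZED
    with pytest.raises(ValueError):
        fit_stack(_fm(X, y), _fm(X, y), xgb_rf_stack(0), seed=0)


# ---------------------------------------------------------------------------
# metrics


def test_macro_metrics_hand_example():
    # precision = (50/60 + 80/100)/2 = 0.81667
    conf = BinaryConfusion(tp_a=50, fp_a=10, fn_a=20, tp_b=80, fp_b=20, fn_b=10)
    precision, recall, f1 = macro_metrics(conf)
    assert precision == pytest.approx(0.81667, abs=1e-4)
    assert recall == pytest.approx(0.5 * (50 / 70 + 80 / 90), abs=1e-9)


def test_macro_metrics_perfect_and_symmetric():
    perfect = BinaryConfusion(10, 0, 0, 20, 0, 0)
    assert macro_metrics(perfect) == (1.0, 1.0, 1.0)
    sym = BinaryConfusion(8, 2, 2, 8, 2, 2)
    p, r, f1 = macro_metrics(sym)
    assert p == r == pytest.approx(f1)


def test_macro_metrics_matches_independent_per_class_computation():
    from sklearn.metrics import precision_recall_fscore_support

    rng = np.random.default_rng(8)
    for _ in range(20):
        y = _labels(rng.integers(0, 2, size=100))
        pred = _labels(rng.integers(0, 2, size=100))
        conf = confusion(pred, y)
        p, r, _ = macro_metrics(conf)
        sp, sr, _, _ = precision_recall_fscore_support(
            y.astype(str), pred.astype(str), average="macro", zero_division=0
        )
        assert p == pytest.approx(sp)
        assert r == pytest.approx(sr)


def test_confusion_counts_and_validation():
    y = _labels([1, 1, 0, 0, 0])
    assert confusion(y, y).fp_a == 0 and confusion(y, y).fn_a == 0
    const_a = _labels([1, 1, 1, 1, 1])
    conf = confusion(const_a, y)
    assert conf.fp_a == 3 and conf.fn_b == 3
    with pytest.raises(ValueError):
        confusion(np.array(["x"] * 5, dtype=object), y)


def test_confusion_brute_force_recount():
    rng = np.random.default_rng(9)
    for _ in range(30):
        n = int(rng.integers(2, 100))
        y, pred = _labels(rng.integers(0, 2, n)), _labels(rng.integers(0, 2, n))
        conf = confusion(pred, y)
        tp_a = sum(1 for p, t in zip(pred, y) if p == t == GENERALIZED)
        fp_a = sum(1 for p, t in zip(pred, y) if p == GENERALIZED and t == FOCAL)
        fn_a = sum(1 for p, t in zip(pred, y) if p == FOCAL and t == GENERALIZED)
        assert (conf.tp_a, conf.fp_a, conf.fn_a) == (tp_a, fp_a, fn_a)
        assert conf.fp_a == conf.fn_b and conf.fn_a == conf.fp_b


def test_binary_confusion_consistency_enforced():
    with pytest.raises(ValueError):
        BinaryConfusion(1, 2, 3, 4, 5, 6)


def test_roc_auc_extremes_and_null():
    y = _labels([1, 1, 0, 0])
    assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), y) == 1.0
    assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 0.0
    rng = np.random.default_rng(10)
    y_big = _labels(rng.integers(0, 2, size=10000))
    assert roc_auc(rng.random(10000), y_big) == pytest.approx(0.5, abs=0.02)


def test_roc_auc_monotone_invariance_and_sklearn_agreement():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(11)
    y = _labels(rng.integers(0, 2, size=500))
    s = rng.random(500)
    a = roc_auc(s, y)
    assert roc_auc(np.exp(3 * s), y) == pytest.approx(a)
    assert a == pytest.approx(roc_auc_score((y == GENERALIZED).astype(int), s))
    with pytest.raises(ValueError):
        roc_auc(s, _labels(np.ones(500)))


def test_roc_points_start_and_end():
    y = _labels([1, 0, 1, 0])
    pts = roc_points(np.array([0.9, 0.8, 0.4, 0.1]), y)
    assert tuple(pts[0][:2]) == (0.0, 0.0)
    assert tuple(pts[-1][:2]) == (1.0, 1.0)


def test_grid_search_utility_returns_best_params():
    from sklearn.tree import DecisionTreeClassifier

    X, y = _planted_design(n=300, seed=12)
    params, score = grid_search_cv(
        DecisionTreeClassifier(random_state=0), {"max_depth": [1, 3]}, X, y,
        n_folds=3, seed=0
    )
    assert params["max_depth"] in (1, 3)
    assert 0.5 <= score <= 1.0
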