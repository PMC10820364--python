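import numpy as np
import pytest

from aopqsar.assay_labeling import EndpointDataset
from aopqsar.chem_curation import CuratedCompound
from aopqsar.evaluation import (
    SplitPlan,
    compute_metrics,
    grid_search,
    permutation_importance,
    repeated_kfold_cv,
    shap_summary,
    stratified_split,
)


def _dataset(n, n_active, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_active]] = 1
    compounds = [CuratedCompound("C" * (i + 1), [str(i)]) for i in range(n)]
    return EndpointDataset("x", compounds, labels, n_assays_used=1)


# -- splitting --------------------------------------------------------------


@pytest.mark.parametrize(
    "n,n_active,fraction,n_train,n_test",
    [
        (232, 184, 0.10, 209, 23),
        (636, 191, 0.10, 572, 64),
        (5004, 1147, 0.10, 4504, 500),
        (5004, 1147, 0.20, 4003, 1001),
        (5004, 1147, 0.30, 3503, 1501),
    ],
)
def test_split_sizes_round_half_away(n, n_active, fraction, n_train, n_test):
    train, test = stratified_split(_dataset(n, n_active), SplitPlan(fraction, seed=0))
    assert (len(train), len(test)) == (n_train, n_test)


def test_split_preserves_class_ratio_exactly_when_proportional():
    train, test = stratified_split(_dataset(10, 5), SplitPlan(0.2, seed=1))
    assert len(test) == 2 and test.labels.sum() == 1


def test_split_partitions_and_determinism():
    ds = _dataset(100, 30)
    a_train, a_test = stratified_split(ds, SplitPlan(0.2, seed=7))
    b_train, b_test = stratified_split(ds, SplitPlan(0.2, seed=7))
    assert a_test.smiles == b_test.smiles  # same seed -> identical partition
    assert set(a_train.smiles) | set(a_test.smiles) == set(ds.smiles)
    assert not set(a_train.smiles) & set(a_test.smiles)
    assert (a_train.partition, a_test.partition) == ("train", "test")
    c_train, c_test = stratified_split(ds, SplitPlan(0.2, seed=8))
    assert c_test.smiles != a_test.smiles


def test_split_forces_minority_test_compound():
    ds = _dataset(40, 2)
    with pytest.warns(UserWarning):
        _, test = stratified_split(ds, SplitPlan(0.1, seed=0))
    assert test.labels.sum() >= 1


def test_split_requires_both_classes():
    with pytest.raises(ValueError):
        stratified_split(_dataset(10, 0), SplitPlan(0.2))


# -- metrics ----------------------------------------------------------------


def test_metrics_hand_worked_confusion():
    # TP=3, FP=1, TN=5, FN=1
    y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    y_pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
    r = compute_metrics(y_true, y_pred)
    assert (r.tp, r.fp, r.tn, r.fn) == (3, 1, 5, 1)
    assert r.precision == pytest.approx(0.750)
    assert r.sensitivity == pytest.approx(0.750)
    assert r.specificity == pytest.approx(5 / 6)
    assert r.balanced_accuracy == pytest.approx((0.75 + 5 / 6) / 2)
    assert r.f1 == pytest.approx(0.750)
    assert r.mcc == pytest.approx(14 / 24)


def test_metrics_perfect_and_conventions():
    perfect = compute_metrics([1, 0, 1], [1, 0, 1])
    assert all(v == 1.0 for v in perfect.as_dict().values())
    all_neg = compute_metrics([1, 0], [0, 0])
    assert all_neg.precision == 0.0 and all_neg.sensitivity == 0.0
    assert all_neg.mcc == 0.0  # zero denominator -> 0 by convention
    with pytest.raises(ValueError):
        compute_metrics([], [])


def test_metrics_match_sklearn_oracle_on_random_vectors(rng):
    from sklearn.metrics import (
        balanced_accuracy_score,
        f1_score,
        matthews_corrcoef,
        precision_score,
        recall_score,
    )

    for _ in range(1000):
        n = int(rng.integers(2, 30))
        y_true = rng.integers(0, 2, n)
        y_pred = rng.integers(0, 2, n)
        if len(np.unique(y_true)) < 2:
            continue
        r = compute_metrics(y_true, y_pred)
        assert r.balanced_accuracy == pytest.approx(
            balanced_accuracy_score(y_true, y_pred)
        )
        assert r.precision == pytest.approx(
            precision_score(y_true, y_pred, zero_division=0)
        )
        assert r.sensitivity == pytest.approx(recall_score(y_true, y_pred))
        assert r.f1 == pytest.approx(f1_score(y_true, y_pred, zero_division=0))
        assert r.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)


# -- cross-validation -------------------------------------------------------


class _Oracle:
    """Memorizes the labels of rows by value (rows are unique)."""

    def fit(self, X, y):
        self.table = {tuple(row): lab for row, lab in zip(X, y)}
        return self

    def predict_proba(self, X):
        return np.array([self.table.get(tuple(row), 0) for row in X], dtype=float)


class _Constant:
    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return np.zeros(len(X))


def test_cv_perfect_oracle_scores_one(rng):
    X = np.arange(60, dtype=float).reshape(60, 1)
    y = np.array([0, 1] * 30)

    class Prefit(_Oracle):  # knows every label up front: CV cannot punish it
        def fit(self, X_, y_):
            return self

    oracle = Prefit()
    _Oracle.fit(oracle, X, y)
    result = repeated_kfold_cv(lambda s: oracle, X, y, k=5, iterations=2, seed=0)
    assert all(r.balanced_accuracy == 1.0 for r in result.fold_reports)


def test_cv_constant_model_balanced_accuracy_half(rng):
    X = rng.normal(size=(80, 3))
    y = np.array([1] * 20 + [0] * 60)
    result = repeated_kfold_cv(lambda s: _Constant(), X, y, k=4, iterations=1, seed=0)
    assert result.mean["balanced_accuracy"] == pytest.approx(0.5)


def test_cv_fold_assignment_depends_only_on_seed(rng):
    X = rng.normal(size=(50, 2))
    y = np.array([0, 1] * 25)
    a = repeated_kfold_cv(lambda s: _Constant(), X, y, k=5, iterations=1, seed=3)
    b = repeated_kfold_cv(lambda s: _Constant(), X, y, k=5, iterations=1, seed=3)
    assert [r.as_row() for r in a.fold_reports] == [r.as_row() for r in b.fold_reports]


def test_cv_validates_inputs(rng):
    X = rng.normal(size=(10, 2))
    with pytest.raises(ValueError):
        repeated_kfold_cv(lambda s: _Constant(), X, np.zeros(10, dtype=int), k=1)
    with pytest.raises(ValueError):
        repeated_kfold_cv(
            lambda s: _Constant(), X, np.array([1] + [0] * 9), k=5
        )


# -- grid search ------------------------------------------------------------


def test_grid_single_point_returned(rng):
    X = rng.normal(size=(40, 2))
    y = np.array([0, 1] * 20)
    from aopqsar.models.baselines import BaselineModel

    res = grid_search(
        lambda p, s: BaselineModel("knn", p, seed=s),
        {"n_neighbors": [3]},
        X, y, k=3, seed=0,
    )
    assert res.best_params == {"n_neighbors": 3}
    assert len(res.table) == 1


def test_grid_prefers_memorizing_knn_on_twin_points():
    # twin points share a label; the nearest non-twin pair is opposite:
    # k=1 is CV-perfect, k=3 votes with the wrong neighbors
    base = np.arange(20, dtype=float)
    X = np.concatenate([base, base + 0.01]).reshape(-1, 1)
    y = np.concatenate([base.astype(int) % 2, base.astype(int) % 2])
    from aopqsar.models.baselines import BaselineModel

    res = grid_search(
        lambda p, s: BaselineModel("knn", p, seed=s),
        {"n_neighbors": [1, 3]},
        X, y, k=4, seed=1,
    )
    assert res.best_params == {"n_neighbors": 1}
    table = res.table.set_index("n_neighbors")
    assert table.loc[1, "mean_f1"] > table.loc[3, "mean_f1"]


# -- explainability ---------------------------------------------------------


def test_permutation_importance_constant_feature_zero(rng):
    X = np.hstack([rng.normal(size=(60, 1)), np.full((60, 1), 3.0)])
    y = (X[:, 0] > 0).astype(int)
    from aopqsar.models.baselines import BaselineModel

    model = BaselineModel("knn", {"n_neighbors": 1}).fit(X, y)
    imp = permutation_importance(model, X, y, repeats=3, seed=0)
    by_feature = imp.set_index("feature")
    assert by_feature.loc[1, "importance_mean"] == 0.0
    assert by_feature.loc[0, "importance_mean"] > 0.0


def test_shap_linear_additivity_and_symmetry(rng):
    from sklearn.linear_model import LinearRegression

    X = rng.normal(size=(50, 3))
    dup = np.hstack([X, X[:, [0]]])  # feature 3 duplicates feature 0
    y = X @ np.array([1.0, -2.0, 0.5])
    model = LinearRegression().fit(dup, y)
    phi, base = shap_summary(model, dup, dup[:5])
    preds = model.predict(dup[:5])
    assert np.allclose(base + phi.sum(axis=1), preds, atol=1e-3)
    # duplicated features get equal attributions (symmetry)
    assert np.allclose(phi[:, 0], phi[:, 3], atol=1e-8)


def test_shap_constant_model_all_zero(rng):
    class Const:
        def predict_proba(self, X):
            return np.full(len(X), 0.7)

    X = rng.normal(size=(20, 3))
    phi, base = shap_summary(Const(), X, X[:3], n_samples=10, seed=0)
    assert base == pytest.approx(0.7)
    assert np.allclose(phi, 0.0)


def test_shap_rejects_model_without_probabilities():
    class Bare:
        pass

    with pytest.raises(TypeError, match="permutation_importance"):
        shap_summary(Bare(), np.zeros((4, 2)), np.zeros((2, 2)))
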