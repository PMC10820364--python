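import numpy as np
import pytest

from aopqsar.models import (
    EncodedDataset,
    ModelSpec,
    TrainConfig,
    build_model,
    predict,
    train,
)
from aopqsar.models.baselines import BASELINE_FAMILIES, BaselineModel
from aopqsar.models.networks import MultimodalClassifier


def test_spec_validates_encoder_compatibility():
    with pytest.raises(ValueError):
        ModelSpec("mpnn", ["circular_fp"])  # graphs only
    with pytest.raises(ValueError):
        ModelSpec("nlp_seq", ["descriptors"])  # token sequences only
    with pytest.raises(ValueError):
        ModelSpec("logreg", ["graph"])
    with pytest.raises(ValueError):
        ModelSpec("logreg", ["circular_fp", "maccs_fp"])  # singleton encoder
    with pytest.raises(ValueError):
        ModelSpec("multimodal", ["circular_fp"])  # needs all five branches
    with pytest.raises(ValueError):
        ModelSpec("quantum", ["latent"])


def test_multimodal_has_five_branches():
    model = MultimodalClassifier(
        {"maccs_fp": 167, "circular_fp": 64, "descriptors": 10, "latent": 8},
        vocab_size=12,
        branch_hidden={"circular_fp": [16], "maccs_fp": [16],
                       "descriptors": [8], "latent": [8]},
        embed_dim=4, lstm_hidden=8, gru_hidden=4, head_hidden=[16],
    )
    assert model.n_branches == 5


def test_dnn_width_constraint_enforced():
    spec = ModelSpec("dnn", ["latent"], {"n_in": 8, "hidden": [48]})
    with pytest.raises(ValueError, match="powers of 2"):
        build_model(spec)
    ok = build_model(ModelSpec("dnn", ["latent"], {"n_in": 8, "hidden": [256, 128, 64]}))
    assert ok.body.hidden == [256, 128, 64]


def test_mpnn_zero_rounds_is_legal(rng):
    from aopqsar.encoders.graphs import featurize_graph

    ds = EncodedDataset(
        labels=np.array([1, 0, 1, 0] * 3),
        graphs=[featurize_graph(s) for s in ["CCO", "CCC", "CCN", "CCCl"] * 3],
    )
    spec = ModelSpec("mpnn", ["graph"], {"hidden": 8, "n_rounds": 0})
    tm = train(spec, ds, TrainConfig(max_epochs=2, seed=0))
    proba, labels = predict(tm, ds)
    assert proba.shape == (12,)


def _toy_tabular(rng, n=80):
    X = rng.normal(size=(n * 2, 6))
    margin = np.abs(X[:, 0] + X[:, 1]) > 0.5  # separable with a clear margin
    X = X[margin][:n]
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    return EncodedDataset(y, tabular={"latent": X})


def test_logreg_fits_separable_data(rng):
    from aopqsar.evaluation import compute_metrics

    ds = _toy_tabular(rng)
    tm = train(ModelSpec("logreg", ["latent"]), ds)
    _, labels = predict(tm, ds)
    assert compute_metrics(ds.labels, labels).balanced_accuracy == 1.0


@pytest.mark.parametrize("family", BASELINE_FAMILIES)
def test_baseline_battery_uniform_interface(family, rng):
    ds = _toy_tabular(rng, n=60)
    tm = train(ModelSpec(family, ["latent"], seed=1), ds)
    proba, labels = predict(tm, ds)
    assert proba.shape == (60,) and np.all((proba >= 0) & (proba <= 1))
    assert set(np.unique(labels)) <= {0, 1}


def test_prediction_threshold_rule():
    class Half:
        classes_ = [0, 1]

        def predict_proba(self, X):
            return np.tile([0.5, 0.5], (len(X), 1))

    bm = BaselineModel.__new__(BaselineModel)
    bm.family = "stub"
    bm.estimator = Half()
    from aopqsar.models.api import TrainedModel

    tm = TrainedModel(ModelSpec("logreg", ["latent"]), bm)
    ds = EncodedDataset(np.zeros(4, dtype=int), tabular={"latent": np.zeros((4, 2))})
    proba, labels = predict(tm, ds)
    assert np.all(proba == 0.5) and np.all(labels == 1)  # >= rule: tie -> active


def test_row_permutation_permutes_predictions(rng):
    ds = _toy_tabular(rng)
    tm = train(ModelSpec("rforest", ["latent"], seed=2), ds)
    proba, _ = predict(tm, ds)
    perm = rng.permutation(len(ds))
    ds_perm = EncodedDataset(ds.labels[perm], tabular={"latent": ds.tabular["latent"][perm]})
    proba_perm, _ = predict(tm, ds_perm)
    assert np.allclose(proba_perm, proba[perm])


def test_network_training_with_oversampling_hook(rng):
    # the oversample hook applies to baselines only; networks use bias init
    from aopqsar.imbalance import OversampleConfig

    X = rng.normal(size=(100, 4))
    y = np.array([1] * 20 + [0] * 80)
    X[y == 1] += 2.0
    ds = EncodedDataset(y, tabular={"latent": X})
    cfg = TrainConfig(oversample=OversampleConfig("smote", seed=0), seed=0)
    tm = train(ModelSpec("logreg", ["latent"]), ds, cfg)
    proba, _ = predict(tm, ds)
    assert proba.shape == (100,)


def test_missing_encoding_raises(rng):
    ds = _toy_tabular(rng)
    with pytest.raises(ValueError, match="descriptors"):
        train(ModelSpec("logreg", ["descriptors"]), ds)
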