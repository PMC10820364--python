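"""Gradient and training-loop checks for the numpy network toolkit."""

import numpy as np
import pytest

from aopqsar.nn import autodiff as ad
from aopqsar.nn.autodiff import Tensor
from aopqsar.nn.layers import GRU, LSTM, MLP, Dense, Module, is_power_of_two
from aopqsar.nn.training import NetworkTrainConfig, fit_network, predict_proba
from aopqsar.models.networks import ArrayData, DNNClassifier


def _numeric_grad(fn, params, eps=1e-6):
    grads = []
    base = fn()
    for P in params:
        g = np.zeros_like(P.data)
        for idx in np.ndindex(P.data.shape):
            old = P.data[idx]
            P.data[idx] = old + eps
            g[idx] = (fn() - base) / eps
            P.data[idx] = old
        grads.append(g)
    return grads


@pytest.mark.parametrize("cell", ["lstm", "gru"])
def test_recurrent_cell_gradients_match_numeric(cell, rng):
    layer = (LSTM if cell == "lstm" else GRU)(3, 4, rng)
    head = Dense(4, 1, rng)
    xs_data = [rng.normal(size=(5, 3)) for _ in range(4)]
    y = rng.integers(0, 2, size=5).astype(float)

    def loss_value():
        hs = layer([Tensor(x) for x in xs_data])
        return float(ad.bce_with_logits(head(hs[-1]), y).data)

    params = layer.parameters() + head.parameters()
    hs = layer([Tensor(x) for x in xs_data])
    loss = ad.bce_with_logits(head(hs[-1]), y)
    for p in params:
        p.grad = None
    loss.backward()
    numeric = _numeric_grad(loss_value, params)
    for p, num in zip(params, numeric):
        assert np.abs(p.grad - num).max() < 1e-4


def test_mpnn_gradients_match_numeric(rng):
    from aopqsar.models.networks import GraphData, MPNNClassifier
    from aopqsar.encoders.graphs import featurize_graph

    model = MPNNClassifier(hidden=4, n_rounds=2, seed=0)
    data = GraphData([featurize_graph(s) for s in ["CCO", "c1ccccc1", "CC(N)=O"]])
    y = np.array([1.0, 0.0, 1.0])
    batch = data.take(np.arange(3))
    model.train(False)  # deterministic forward for the numeric check

    def loss_value():
        return float(ad.bce_with_logits(model.forward(batch), y).data)

    loss = ad.bce_with_logits(model.forward(batch), y)
    model.zero_grad()
    loss.backward()
    params = model.parameters()
    numeric = _numeric_grad(loss_value, params)
    for p, num in zip(params, numeric):
        assert np.abs(p.grad - num).max() < 1e-4


def test_module_collects_nested_parameters(rng):
    class Net(Module):
        def __init__(self):
            self.a = Dense(2, 3, rng)
            self.items = [Dense(3, 1, rng)]
            self.table = {"x": Dense(1, 1, rng)}

    assert len(Net().parameters()) == 6  # three W/b pairs


def test_mlp_rejects_non_power_of_two_widths(rng):
    assert is_power_of_two(64) and not is_power_of_two(48)
    with pytest.raises(ValueError):
        MLP(8, [48], rng)


def test_output_bias_initialization_matches_class_ratio(rng):
    X = rng.normal(size=(200, 10))
    y = (rng.random(200) < 0.23).astype(float)
    model = DNNClassifier(10, hidden=[16], seed=0)
    cfg = NetworkTrainConfig(max_epochs=0, seed=0)
    fit_network(model, ArrayData(X), y, cfg)
    proba = predict_proba(model, ArrayData(X))
    # sigmoid(log(p/(1-p))) = p: untrained mean prediction near base rate
    assert proba.mean() == pytest.approx(y.mean(), abs=0.05)


def test_training_reduces_loss_and_is_deterministic(rng):
    X = rng.normal(size=(120, 6))
    w = rng.normal(size=6)
    y = (X @ w > 0).astype(float)

    def run():
        model = DNNClassifier(6, hidden=[16, 8], seed=3)
        history = fit_network(
            model, ArrayData(X), y, NetworkTrainConfig(max_epochs=15, seed=3)
        )
        return history, predict_proba(model, ArrayData(X))

    h1, p1 = run()
    h2, p2 = run()
    assert h1.train_loss[-1] < h1.train_loss[0]
    assert np.array_equal(p1, p2)
    assert h1.val_loss == h2.val_loss


def test_plateau_decays_learning_rate():
    local = np.random.default_rng(1234)
    X = local.normal(size=(60, 4))
    y = local.integers(0, 2, 60).astype(float)  # pure noise: loss plateaus
    model = DNNClassifier(4, hidden=[8], seed=1)
    cfg = NetworkTrainConfig(
        max_epochs=40, plateau_patience=2, early_stop_patience=30, seed=1
    )
    history = fit_network(model, ArrayData(X), y, cfg)
    rates = set(history.learning_rate)
    assert len(rates) >= 2  # at least one factor-10 decay happened
    assert min(rates) == pytest.approx(max(rates) / 10)


def test_non_finite_loss_aborts():
    X = np.full((40, 3), 1.0)
    X[::2, 0] = np.inf  # poisoned feature propagates to a non-finite loss
    y = np.zeros(40)
    model = DNNClassifier(3, hidden=[8], seed=0)
    with pytest.raises(FloatingPointError):
        fit_network(model, ArrayData(X), y, NetworkTrainConfig(max_epochs=2, seed=0))
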