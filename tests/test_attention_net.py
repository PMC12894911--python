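"""Tests of the attention gate, training loop and hyperparameter search."""

import numpy as np
import pytest

from pmikit import HyperParams, attention_forward, build_model, predict, train
from pmikit.attention_net import (
    EarlyStopper,
    ModelConfigError,
    PMIRegressor,
    hyperparameter_search,
)


def small_hp(**kw):
    defaults = dict(
        use_attention=True,
        n_hidden_layers=1,
        nodes_per_layer=(32,),
        dropout_per_layer=(0.05,),
        learning_rate=5e-3,
        seed=0,
    )
    defaults.update(kw)
    return HyperParams(**defaults)


# ---------------------------------------------------------------------------
# attention gate
# ---------------------------------------------------------------------------

def test_unit_gate_is_identity_on_non_negative_inputs(rng):
    x = np.abs(rng.normal(size=(6, 4)))
    np.testing.assert_array_equal(attention_forward(x, np.ones(4), np.zeros(4)), x)


def test_zero_weight_annihilates():
    x = np.array([[1.0, -3.0, 9.9]])
    assert (attention_forward(x, np.zeros(3), np.zeros(3)) == 0).all()


def test_gate_scalar_evaluation():
    out = attention_forward(np.array([3.0, 5.0]), np.array([2.0, -1.0]), np.array([0.0, 1.0]))
    np.testing.assert_array_equal(out, [6.0, 0.0])


def test_gate_length_mismatch_raises():
    with pytest.raises(ModelConfigError):
        attention_forward(np.zeros(3), np.zeros(2), np.zeros(2))


def test_no_cross_feature_mixing(rng):
    model = build_model(small_hp(seed=2), 8)
    model.params["att_w"] = rng.normal(size=8)
    model.params["att_b"] = rng.normal(size=8)
    X = rng.normal(size=(10, 8))
    base = model.attention_activations(X)
    X2 = X.copy()
    X2[:, 3] += 1.7
    perturbed = model.attention_activations(X2)
    changed = (base != perturbed).any(axis=0)
    assert not changed[np.arange(8) != 3].any()


def test_activations_equal_gate_applied_rowwise(rng):
    model = build_model(small_hp(seed=5), 6)
    model.params["att_w"] = rng.normal(size=6)
    model.params["att_b"] = rng.normal(size=6)
    X = rng.normal(size=(7, 6))
    expected = np.stack([attention_forward(row, model.params["att_w"], model.params["att_b"]) for row in X])
    np.testing.assert_allclose(model.attention_activations(X), expected)


def test_model_without_attention_refuses_activations():
    model = build_model(small_hp(use_attention=False), 4)
    with pytest.raises(ModelConfigError):
        model.attention_activations(np.zeros((2, 4)))


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def test_selected_architecture_is_valid():
    hp = HyperParams(
        use_attention=True,
        n_hidden_layers=1,
        nodes_per_layer=(288,),
        dropout_per_layer=(0.15,),
        learning_rate=0.005,
    )
    assert build_model(hp, 300).n_parameters > 0


@pytest.mark.parametrize(
    "kw",
    [
        {"n_hidden_layers": 5, "nodes_per_layer": (32,) * 5, "dropout_per_layer": (0.1,) * 5},
        {"nodes_per_layer": (600,)},
        {"dropout_per_layer": (0.6,)},
        {"learning_rate": 0.5},
        {"nodes_per_layer": (32, 32)},  # length != n_hidden_layers
    ],
)
def test_out_of_range_hyperparams_rejected(kw):
    with pytest.raises(ModelConfigError):
        small_hp(**kw)


def test_parameter_counts():
    no_att = build_model(small_hp(use_attention=False), 10)
    assert no_att.n_parameters == 10 * 32 + 32 + 32 + 1
    with_att = build_model(small_hp(use_attention=True), 10)
    assert with_att.n_parameters == no_att.n_parameters + 2 * 10


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def test_analytic_gradient_matches_central_differences(rng):
    model = build_model(small_hp(seed=1), 5)
    X = rng.normal(size=(8, 5))
    y = rng.normal(size=8)
    loss, grads = model.loss_and_gradients(X, y)
    analytic = model.flatten_gradients(grads)
    flat = model.get_flat_params()
    eps = 1e-6
    numeric = np.empty_like(flat)
    for i in range(len(flat)):
        for sign, store in ((1, "hi"), (-1, "lo")):
            bumped = flat.copy()
            bumped[i] += sign * eps
            model.set_flat_params(bumped)
            val = model.loss_and_gradients(X, y)[0]
            if sign == 1:
                hi = val
            else:
                lo = val
        numeric[i] = (hi - lo) / (2 * eps)
    model.set_flat_params(flat)
    denom = np.maximum(np.abs(numeric), 1e-8)
    rel = np.abs(analytic - numeric) / denom
    # ignore coordinates whose gradient is essentially zero on both sides
    active = (np.abs(numeric) > 1e-10) | (np.abs(analytic) > 1e-10)
    assert rel[active].max() < 1e-4


# ---------------------------------------------------------------------------
# early stopping
# ---------------------------------------------------------------------------

def test_monotone_improvement_never_stops():
    stopper = EarlyStopper(patience=25)
    for epoch, loss in enumerate(np.linspace(10, 1, 40)):
        assert not stopper.update(epoch, loss)
    assert stopper.best_epoch == 39


def test_patience_semantics_on_constructed_sequence():
    """Minimum at epoch 3, flat afterwards: stop at epoch 3 + 25."""
    stopper = EarlyStopper(patience=25)
    losses = [5.0, 4.0, 3.5, 1.0] + [2.0] * 100
    stopped_at = None
    for epoch, loss in enumerate(losses):
        if stopper.update(epoch, loss):
            stopped_at = epoch
            break
    assert stopper.best_epoch == 3
    assert stopped_at == 3 + 25


def test_restored_weights_attain_minimal_validation_loss(small_standardized):
    tr, va = small_standardized["train"], small_standardized["validation"]
    model = build_model(small_hp(seed=3), tr.n_features)
    train(model, tr, va, patience=10, max_epochs=60)
    assert model.best_val_loss == min(model.history["val_loss"])
    assert model.history["val_loss"][model.best_epoch] == model.best_val_loss
    # forward pass with the restored weights reproduces the recorded best
    val_pred = model.predict(va.values())
    mse = float(np.mean((val_pred - va.pmi) ** 2))
    assert mse == pytest.approx(model.best_val_loss, rel=1e-10)


# ---------------------------------------------------------------------------
# training behaviour
# ---------------------------------------------------------------------------

def test_fits_noise_free_linear_map(rng):
    X = rng.normal(size=(300, 10))
    beta = rng.normal(size=10)
    y = X @ beta
    model = PMIRegressor(small_hp(use_attention=False, dropout_per_layer=(0.05,), seed=4), 10)
    model.fit(X, y, X[:50], y[:50], patience=50, max_epochs=400)
    train_mae = float(np.mean(np.abs(model.predict(X) - y)))
    assert train_mae < 0.05 * y.std()


def test_zero_initialized_net_outputs_bias():
    model = build_model(small_hp(), 4)
    model.set_flat_params(np.zeros(model.n_parameters))
    model.params["b_out"] = np.array([1.5])
    np.testing.assert_allclose(model.predict(np.random.default_rng(0).normal(size=(3, 4))), 1.5)


def test_prediction_is_deterministic(small_standardized):
    tr, va = small_standardized["train"], small_standardized["validation"]
    model = build_model(small_hp(seed=9), tr.n_features)
    train(model, tr, va, patience=5, max_epochs=20)
    a = predict(model, va)
    b = predict(model, va)
    np.testing.assert_array_equal(a, b)


def test_training_is_seed_reproducible(small_standardized):
    tr, va = small_standardized["train"], small_standardized["validation"]
    models = []
    for _ in range(2):
        m = build_model(small_hp(seed=17), tr.n_features)
        train(m, tr, va, patience=5, max_epochs=25)
        models.append(m)
    np.testing.assert_array_equal(models[0].get_flat_params(), models[1].get_flat_params())
    assert models[0].history == models[1].history


def test_feature_order_mismatch_rejected(small_standardized):
    tr, va = small_standardized["train"], small_standardized["validation"]
    model = build_model(small_hp(seed=9), tr.n_features)
    train(model, tr, va, patience=3, max_epochs=5)
    shuffled = va.copy()
    shuffled.intensities = shuffled.intensities[list(shuffled.intensities.columns[::-1])]
    shuffled.feature_meta = shuffled.feature_meta.iloc[::-1]
    with pytest.raises(ModelConfigError):
        predict(model, shuffled)


def test_save_load_round_trip(tmp_path, small_standardized):
    tr, va = small_standardized["train"], small_standardized["validation"]
    model = build_model(small_hp(seed=13), tr.n_features)
    model.normalization = small_standardized["params"]
    train(model, tr, va, patience=5, max_epochs=15)
    model.save(tmp_path / "archive")
    back = PMIRegressor.load(tmp_path / "archive")
    np.testing.assert_array_equal(model.get_flat_params(), back.get_flat_params())
    np.testing.assert_array_equal(model.predict(va.values()), back.predict(va.values()))
    assert back.feature_order == model.feature_order
    assert back.normalization is not None


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def test_search_single_config(small_standardized):
    tr, va = small_standardized["train"], small_standardized["validation"]
    result = hyperparameter_search(tr, va, n_configs=1, repeats=1, seed=0, max_epochs=5, patience=3)
    assert len(result) == 1
    assert len(result.entries[0].val_maes) == 1


def test_search_is_seed_deterministic(small_standardized):
    tr, va = small_standardized["train"], small_standardized["validation"]
    a = hyperparameter_search(tr, va, n_configs=3, repeats=2, seed=4, max_epochs=5, patience=3)
    b = hyperparameter_search(tr, va, n_configs=3, repeats=2, seed=4, max_epochs=5, patience=3)
    assert [(e.hp, e.val_maes) for e in a.entries] == [(e.hp, e.val_maes) for e in b.entries]
    assert [e.score for e in a.entries] == sorted(e.score for e in a.entries)
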