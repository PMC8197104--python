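"""Network training and Garson connection-weight importance: dataset
construction, planted-signal recovery, and the decomposition against an
exhaustive path-enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from comfortrisk.importance import (
    FEATURES,
    TARGETS,
    ImportanceResult,
    NetworkSpec,
    TrainedNetwork,
    ValidationError,
    build_dataset,
    garson_importance,
    train_network,
)


def _model_from_weights(w, v):
    """Wrap raw (4, h) and (h, 2) matrices with zero biases."""
    n_in, n_hid = w.shape
    n_out = v.shape[1]
    w1 = np.vstack([w, np.zeros((1, n_hid))])
    w2 = np.vstack([v, np.zeros((1, n_out))])
    return TrainedNetwork(
        spec=NetworkSpec(n_inputs=n_in, hidden_units=n_hid, n_outputs=n_out),
        w_hidden=w1, w_output=w2, feature_names=FEATURES[:n_in],
        r2=0.0, epochs=0, final_loss=0.0, converged=True,
        x_min=np.zeros(n_in), x_range=np.ones(n_in),
    )


from _oracles import oracle_garson


# ------------------------------------------------------------ decomposition

def test_garson_matches_path_enumeration_oracle(rng):
    for _ in range(10):
        w = rng.normal(size=(4, 9))
        v = rng.normal(size=(9, 2))
        got = garson_importance(_model_from_weights(w, v)).importances
        expected = oracle_garson(w, v)
        assert np.allclose(list(got.values()), expected, atol=1e-12)
        assert sum(got.values()) == pytest.approx(1.0, abs=1e-12)


def test_garson_symmetric_weights_give_quarter_shares(rng):
    w = np.ones((4, 9)) * np.sign(rng.normal(size=(4, 9)))  # equal |w|
    v = rng.normal(size=(9, 2))
    got = garson_importance(_model_from_weights(w, v)).importances
    assert np.allclose(list(got.values()), 0.25, atol=1e-12)


def test_garson_single_active_input(rng):
    w = np.zeros((4, 9))
    w[0, :] = rng.normal(size=9)
    v = rng.normal(size=(9, 2))
    got = garson_importance(_model_from_weights(w, v)).importances
    assert got["ta"] == pytest.approx(1.0)


def test_garson_invariant_to_hidden_permutation(rng):
    w = rng.normal(size=(4, 9))
    v = rng.normal(size=(9, 2))
    perm = rng.permutation(9)
    a = garson_importance(_model_from_weights(w, v)).importances
    b = garson_importance(_model_from_weights(w[:, perm], v[perm])).importances
    assert np.allclose(list(a.values()), list(b.values()), atol=1e-12)


def test_olden_variant_and_zero_weights():
    w = np.zeros((4, 9))
    v = np.zeros((9, 2))
    with pytest.raises(ValidationError):
        garson_importance(_model_from_weights(w, v))
    w[0, 0] = 2.0
    v[0, 0] = -1.5
    res = garson_importance(_model_from_weights(w, v), method="olden")
    assert res.importances["ta"] == pytest.approx(-3.0)


# ------------------------------------------------------------ dataset

def _toy_climate(hours=3):
    ts = pd.date_range("2012-03-05 09:00", periods=hours, freq="h")
    return pd.DataFrame(
        {"city": "Seoul", "district": "A", "timestamp": ts,
         "ta": [10.0, 12.0, 14.0][:hours], "tmrt": 20.0, "v": 1.0, "rh": 50.0}
    )


def test_build_dataset_hand_tally():
    clim = _toy_climate()
    linked = pd.DataFrame(
        {"city": ["Seoul"], "district": ["A"],
         "timestamp": [pd.Timestamp("2012-03-05 10:00")],
         "accident_type": ["fall"], "severity": ["fatal"]}
    )
    table = build_dataset(linked, clim)
    assert len(table) == 3  # all working station-hours kept
    assert table["fatal"].sum() == 1
    assert table.loc[table["fatal"] == 1, "timestamp"].iloc[0] == \
        pd.Timestamp("2012-03-05 10:00")
    assert table["injury"].sum() == 0


def test_build_dataset_zero_accidents_keeps_feature_rows():
    clim = _toy_climate()
    table = build_dataset(clim.iloc[0:0].assign(accident_type=None,
                                                severity=None), clim)
    assert len(table) == 3
    assert (table[["fatal", "injury"]] == 0).all().all()


def test_build_dataset_row_count_conserves_working_hours(small_linked,
                                                         small_climate,
                                                         small_cfg):
    from comfortrisk.simulate import working_hour_mask

    table = build_dataset(small_linked, small_climate,
                          working_hours=small_cfg.working_hours)
    expected = working_hour_mask(
        pd.DatetimeIndex(small_climate["timestamp"]), small_cfg.working_hours
    ).sum()
    assert len(table) == expected
    assert table["fatal"].sum() + table["injury"].sum() == len(small_linked)


def test_build_dataset_binary_encoding(small_linked, small_climate):
    table = build_dataset(small_linked, small_climate, encoding="binary")
    assert set(np.unique(table[["fatal", "injury"]])) <= {0, 1}
    with pytest.raises(ValidationError):
        build_dataset(small_linked, small_climate, encoding="fancy")


# ------------------------------------------------------------ training

def _planted_table(rng, n=600):
    ta = rng.uniform(-5, 30, n)
    table = pd.DataFrame(
        {"ta": ta, "tmrt": rng.uniform(-5, 40, n), "v": rng.uniform(0, 8, n),
         "rh": rng.uniform(10, 90, n)}
    )
    signal = 1.0 / (1.0 + np.exp(-(ta - 12.0) / 4.0))
    table["fatal"] = signal + rng.normal(0, 0.02, n)
    table["injury"] = signal + rng.normal(0, 0.02, n)
    return table


def test_planted_signal_recovery(rng):
    table = _planted_table(rng)
    model = train_network(table, NetworkSpec(seed=0, max_epochs=3000))
    assert model.r2 >= 0.9
    imp = garson_importance(model)
    assert max(imp.importances, key=imp.importances.get) == "ta"


def test_planted_signal_learnable_by_independent_estimator(rng):
    """Sanity check of the planted dataset itself: an off-the-shelf MLP
    (independent of this package's trainer) also reaches high R^2 on it,
    so the recovery test exercises the trainer, not a quirk of the data."""
    from sklearn.neural_network import MLPRegressor

    table = _planted_table(rng)
    x = table[list(FEATURES)].to_numpy()
    y = table[list(TARGETS)].to_numpy()
    x = (x - x.min(0)) / (x.max(0) - x.min(0))
    ref = MLPRegressor(hidden_layer_sizes=(9,), activation="logistic",
                       solver="lbfgs", random_state=0, max_iter=5000)
    split = int(0.7 * len(x))
    ref.fit(x[:split], y[:split])
    assert ref.score(x[split:], y[split:]) >= 0.9


def test_training_is_deterministic(rng):
    table = _planted_table(rng, n=200)
    spec = NetworkSpec(seed=5, max_epochs=300)
    a = train_network(table, spec)
    b = train_network(table, spec)
    assert np.array_equal(a.w_hidden, b.w_hidden)
    assert np.array_equal(a.w_output, b.w_output)
    assert a.r2 == b.r2


def test_constant_targets_r2_convention(rng):
    table = _planted_table(rng, n=150)
    table["fatal"] = 0
    table["injury"] = 0
    model = train_network(table, NetworkSpec(seed=1, max_epochs=200))
    assert model.r2 == 0.0


def test_training_requires_rows(rng):
    with pytest.raises(ValidationError):
        train_network(_planted_table(rng, n=50))


def test_importance_result_normalisation_guard():
    with pytest.raises(AssertionError):
        ImportanceResult(importances={"ta": 0.9, "rh": 0.9}, r2=0.0,
                         epochs=1, final_loss=0.0, method="garson")
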