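"""Classifier suite: balancing, normalization, windowing, feature models
and the recurrent raw-signal model."""

import numpy as np
import pandas as pd
import pytest

import equigait as eg
from equigait.classify import (
    FEATURE_SUBSETS,
    SENSOR_SUBSETS,
    ModelSpec,
    WindowSet,
    balance_by_duplication,
    channel_minmax,
    normalize_signals,
    predict,
    train_feature_model,
    train_sequence_model,
    window_signals,
    windows_dataset,
)
from equigait.rnn import GRUClassifier
from equigait.simulate import generate_signals, generate_timeline
from equigait.types import Gait, HorseProfile, SignalBlock

HORSE = HorseProfile(horse_id="h")


def _block(values, gait=Gait.trot, fs=200.0):
    values = np.asarray(values, dtype=float)
    names = [f"s{i}.acc_x" for i in range(values.shape[1])]
    return SignalBlock(
        horse_id="h", gait=gait, sample_rate=fs, channel_names=names, values=values
    )


def _two_gait_table(n=40, seed=0):
    presets = eg.builtin_presets()
    tls = [
        generate_timeline(presets[Gait.trot], HorseProfile(horse_id="a"), n, rng_seed=seed),
        generate_timeline(presets[Gait.walk], HorseProfile(horse_id="b"), n, rng_seed=seed + 1),
    ]
    return eg.feature_table(tls)


# --- balancing --------------------------------------------------------------


def test_balance_upsamples_to_majority():
    df = pd.DataFrame(
        {"gait_label": ["A"] * 10 + ["B"] * 4, "x": range(14), "horse_id": "h"}
    )
    out = balance_by_duplication(df, rng_seed=0)
    counts = out["gait_label"].value_counts()
    assert counts["A"] == counts["B"] == 10
    assert set(out.loc[out.gait_label == "B", "x"]) <= set(range(10, 14))


def test_balance_identity_when_already_balanced():
    df = pd.DataFrame({"gait_label": ["A", "B"] * 5, "x": range(10), "horse_id": "h"})
    out = balance_by_duplication(df, rng_seed=0)
    assert len(out) == 10
    assert sorted(out["x"]) == sorted(df["x"])


def test_balance_study_proportioned_cohort(cohort_table):
    out = balance_by_duplication(cohort_table, rng_seed=0)
    counts = out["gait_label"].value_counts()
    assert counts.nunique() == 1 and len(counts) == 8


def test_balance_rejects_empty():
    with pytest.raises(ValueError):
        balance_by_duplication(pd.DataFrame({"gait_label": []}), rng_seed=0)


# --- normalization ----------------------------------------------------------


def test_minmax_scaling_basic():
    b = _block(np.array([[-2.0], [0.0], [2.0]]))
    out = normalize_signals(b)
    np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0])


def test_constant_channel_maps_to_half_with_warning():
    b = _block(np.ones((5, 1)))
    with pytest.warns(UserWarning):
        out = normalize_signals(b)
    np.testing.assert_allclose(out.values, 0.5)


def test_training_stats_applied_and_clipped():
    train = _block(np.array([[0.0], [10.0]]))
    stats = channel_minmax(train)
    test = _block(np.array([[-5.0], [5.0], [20.0]]))
    out = normalize_signals(test, stats=stats)
    np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0])
    again = normalize_signals(out, stats={c: (0.0, 1.0) for c in out.channel_names})
    np.testing.assert_allclose(again.values, out.values)


# --- windowing --------------------------------------------------------------


def test_window_count_floor():
    presets = eg.builtin_presets()
    tl = generate_timeline(presets[Gait.walk], HORSE, 10, rng_seed=0)
    block = generate_signals(tl, sample_rate=200.0, rng_seed=0)
    wins = window_signals(block, 3.0, "all")
    assert len(wins) == int(block.duration // 3)
    assert wins[0][0].shape == (600, 42)


def test_upper_body_subset_has_18_channels():
    presets = eg.builtin_presets()
    tl = generate_timeline(presets[Gait.trot], HORSE, 8, rng_seed=0)
    block = generate_signals(tl, rng_seed=0)
    wins = window_signals(block, 1.0, "upper_body")
    assert wins[0][0].shape[1] == 18
    assert all(g == "trot" for _, g, _ in wins)


def test_short_block_yields_empty_with_warning(caplog):
    b = _block(np.zeros((50, 1)), fs=200.0)
    assert window_signals(b, 1.0, ["s0"]) == []


def test_sensor_subset_definitions():
    assert SENSOR_SUBSETS["upper_body"] == ["poll", "withers", "pelvis"]
    assert len(SENSOR_SUBSETS["all"]) == 7
    assert FEATURE_SUBSETS["hildebrand2"] == ["duty_factor", "lateral_advanced_placement"]
    assert set(FEATURE_SUBSETS["stride_only"]) < set(FEATURE_SUBSETS["all"])
    assert len(FEATURE_SUBSETS["all"]) == 21


# --- feature models ---------------------------------------------------------


@pytest.mark.parametrize("kind", ["lda", "qda", "tree", "forest", "svm", "fc"])
def test_two_separated_gaits_fit_perfectly(kind):
    table = _two_gait_table()
    model = train_feature_model(ModelSpec(kind=kind, rng_seed=0), table)
    acc = (predict(model, table) == table["gait_label"]).mean()
    assert acc == 1.0


def test_hildebrand2_model_input_dimension():
    table = _two_gait_table()
    model = train_feature_model(ModelSpec(kind="lda", rng_seed=0), table, subset="hildebrand2")
    assert model.feature_columns == ["duty_factor", "lateral_advanced_placement"]
    assert model.estimator[-1].n_features_in_ == 2


def test_same_seed_same_predictions():
    table = _two_gait_table()
    m1 = train_feature_model(ModelSpec(kind="fc", rng_seed=3), table)
    m2 = train_feature_model(ModelSpec(kind="fc", rng_seed=3), table)
    assert np.array_equal(predict(m1, table), predict(m2, table))


def test_single_class_training_rejected():
    table = _two_gait_table()
    only = table[table.gait_label == "trot"]
    with pytest.raises(ValueError):
        train_feature_model(ModelSpec(kind="lda", rng_seed=0), only)


def test_missing_feature_columns_rejected():
    table = _two_gait_table().drop(columns=["duty_factor"])
    with pytest.raises(ValueError):
        train_feature_model(ModelSpec(kind="lda", rng_seed=0), table)


def test_predict_contracts():
    table = _two_gait_table()
    model = train_feature_model(ModelSpec(kind="tree", rng_seed=0), table)
    assert len(predict(model, table.iloc[:0])) == 0
    labels = predict(model, table)
    assert set(labels) <= set(model.classes)
    with pytest.raises(ValueError):
        predict(model, np.zeros((3, 2)))


def test_model_spec_validates_kind_and_hyperparameters():
    with pytest.raises(ValueError):
        ModelSpec(kind="boost")
    with pytest.raises(ValueError):
        ModelSpec(kind="lda", hyperparameters={"width": 3})


# --- sequence model ---------------------------------------------------------


def test_gru_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(4, 6, 3))
    y = np.array([0, 1, 2, 1])
    clf = GRUClassifier(n_layers=2, width=5, bidirectional=True, pool=1, seed=0)
    clf.classes_ = np.array([0, 1, 2])
    clf._build(3, 3)
    _, layer_grads, gW, gb = clf.loss_and_grads(X, y)
    eps = 1e-6
    for gi, group in enumerate(clf.layers_):
        for di, layer in enumerate(group):
            for name in layer.PARAM_NAMES:
                P = layer.params[name]
                idx = tuple(rng.integers(0, s) for s in P.shape)
                P[idx] += eps
                l1, *_ = clf.loss_and_grads(X, y)
                P[idx] -= 2 * eps
                l2, *_ = clf.loss_and_grads(X, y)
                P[idx] += eps
                num = (l1 - l2) / (2 * eps)
                assert layer_grads[gi][di][name][idx] == pytest.approx(num, abs=1e-4, rel=1e-3)


def test_bidirectional_doubles_recurrent_parameters():
    uni = GRUClassifier(n_layers=2, width=16, bidirectional=False, pool=1, seed=0)
    uni._build(6, 4)
    bi = GRUClassifier(n_layers=1, width=16, bidirectional=True, pool=1, seed=0)
    bi._build(6, 4)
    one = GRUClassifier(n_layers=1, width=16, bidirectional=False, pool=1, seed=0)
    one._build(6, 4)
    assert bi.n_recurrent_params == 2 * one.n_recurrent_params
    assert uni.n_recurrent_params > one.n_recurrent_params


def _two_gait_windows(noise=0.0, n_strides=14):
    presets = eg.builtin_presets()
    blocks = []
    for i, gait in enumerate((Gait.trot, Gait.walk)):
        for h in range(2):
            horse = HorseProfile(horse_id=f"{gait.value}{h}", signal_noise_sd=noise)
            tl = generate_timeline(presets[gait], horse, n_strides, rng_seed=10 * i + h)
            blocks.append(generate_signals(tl, rng_seed=i + h, noise_sd=noise))
    return windows_dataset(blocks, 1.0, "upper_body")


def test_sequence_model_separates_two_gaits_noiseless():
    ws = _two_gait_windows()
    spec = ModelSpec(kind="sequence", hyperparameters={"max_epochs": 30}, rng_seed=0)
    model = train_sequence_model(spec, ws)
    assert (predict(model, ws) == ws.y).mean() == 1.0
    assert set(predict(model, ws)) <= {"trot", "walk"}


def test_sequence_rejects_inconsistent_window_shapes():
    ws = _two_gait_windows()
    bad = WindowSet(
        X=np.array([ws.X[0], ws.X[1][:100]], dtype=object),
        y=ws.y[:2],
        horse_ids=ws.horse_ids[:2],
        channel_names=ws.channel_names,
    )
    with pytest.raises(ValueError):
        train_sequence_model(ModelSpec(kind="sequence", rng_seed=0), bad)


def test_sequence_predict_shape_checked():
    ws = _two_gait_windows()
    spec = ModelSpec(kind="sequence", hyperparameters={"max_epochs": 5}, rng_seed=0)
    model = train_sequence_model(spec, ws)
    with pytest.raises(ValueError):
        predict(model, np.zeros((2, 200, 3)))
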