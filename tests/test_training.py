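"""Splitting, fitting, early stopping, search, and the training paradigms."""

import numpy as np
import pytest
from dataclasses import replace

from erosdecode import (
    SimConfig, ModelConfig, TrainConfig, SearchSpace, Network,
    generate_subject_dataset, make_splits, fit, evaluate_on,
    random_search, select_best_config,
    run_montage_specific, run_cross_montage, run_pretrain_finetune,
)

TINY = ModelConfig(C=42, T=56, F1=2, D=1, F2=4)


def _clean_dataset(seed=0, n_blocks=5, amp=4.0, montages=1):
    """Small, strongly separable synthetic subject for fast fits."""
    cfg = SimConfig(n_blocks=n_blocks, n_montages_per_subject=montages,
                    effect_amplitude=amp, noise_sd=0.5, pulse_amplitude=0.1,
                    voxel_dropout_range=(0.0, 0.1), seed=seed)
    return generate_subject_dataset(cfg, 0)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def test_split_arithmetic_240_trials():
    labels = np.tile([0, 1], 120)
    spec = make_splits(labels, seed=0)
    assert len(spec.test_indices) == 48
    pool = np.concatenate([spec.cv_folds[0][0], spec.cv_folds[0][1]])
    assert len(pool) == 192
    for _, val in spec.cv_folds:
        assert len(val) in (38, 39)
    # test set stratified by label
    assert abs(labels[spec.test_indices].sum() - 24) <= 1


def test_splits_deterministic_and_disjoint():
    labels = np.tile([0, 1], 60)
    s1 = make_splits(labels, seed=7)
    s2 = make_splits(labels, seed=7)
    np.testing.assert_array_equal(s1.test_indices, s2.test_indices)
    for (a, b), (c, d) in zip(s1.cv_folds, s2.cv_folds):
        np.testing.assert_array_equal(a, c)
        np.testing.assert_array_equal(b, d)
    s1.validate_disjoint()
    # validation folds tile the 80% pool exactly once
    vals = np.concatenate([v for _, v in s1.cv_folds])
    pool = np.setdiff1d(np.arange(len(labels)), s1.test_indices)
    np.testing.assert_array_equal(np.sort(vals), pool)


def test_splits_require_both_classes():
    with pytest.raises(ValueError):
        make_splits(np.zeros(40, dtype=int), seed=0)


def test_montage_stratified_splits():
    labels = np.tile([0, 1], 60)
    montages = np.repeat(["A", "B", "C"], 40)
    spec = make_splits(labels, seed=1, montages=montages)
    test_m = montages[spec.test_indices]
    counts = [np.sum(test_m == m) for m in "ABC"]
    assert max(counts) - min(counts) <= 1
    for tr, va in spec.cv_folds:
        c = [np.sum(montages[va] == m) for m in "ABC"]
        assert max(c) - min(c) <= 1


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_zero_learning_rate_freezes_weights():
    data = _clean_dataset()["A"]["phase"]
    splits = make_splits(data.labels, seed=0)
    tr, va = splits.cv_folds[0]
    net = Network(TINY, seed=0)
    from erosdecode.model import constrain_weights
    constrain_weights(net)              # projection applied before the snapshot
    w0 = [p.value.copy() for p in net.params()]
    tcfg = TrainConfig(max_epochs=4, learning_rate=0.0, weight_decay=0.0,
                       optimizer_name="sgd", seed=0)
    run = fit(net, data.data[tr], data.labels[tr], data.data[va], data.labels[va], tcfg)
    for p, w in zip(net.params(), w0):
        np.testing.assert_array_equal(p.value, w)
    # trainable weights frozen; only batch-norm running statistics settle,
    # so validation accuracy is constant once they have (after epoch 1)
    assert max(run.val_accuracy[1:]) - min(run.val_accuracy[1:]) <= 1.0 / len(va) + 1e-12


def test_separable_data_reaches_perfect_training_accuracy():
    """A strongly planted, nearly noise-free effect is learned quickly."""
    cfg = SimConfig(n_blocks=5, n_montages_per_subject=1, effect_amplitude=6.0,
                    noise_sd=0.1, pulse_amplitude=0.0,
                    voxel_dropout_range=(0.0, 0.0), seed=0)
    data = generate_subject_dataset(cfg, 0)["A"]["phase"]
    splits = make_splits(data.labels, seed=0)
    tr, va = splits.cv_folds[0]
    net = Network(TINY, seed=1)
    tcfg = TrainConfig(max_epochs=60, patience=59, seed=1)
    fit(net, data.data[tr], data.labels[tr], data.data[va], data.labels[va], tcfg)
    pred = net.predict_proba(data.data[tr]) > 0.5
    assert np.mean(pred == data.labels[tr]) == 1.0


def test_early_stopping_restores_best_weights():
    data = _clean_dataset()["A"]["phase"]
    splits = make_splits(data.labels, seed=2)
    tr, va = splits.cv_folds[0]
    net = Network(TINY, seed=2)
    tcfg = TrainConfig(max_epochs=15, patience=5, seed=2)
    run = fit(net, data.data[tr], data.labels[tr], data.data[va], data.labels[va], tcfg)
    # restored weights reproduce the best logged validation accuracy
    prob = net.predict_proba(data.data[va])
    acc = np.mean((prob > 0.5) == data.labels[va])
    assert acc == pytest.approx(max(run.val_accuracy))
    assert run.best_epoch <= run.stopped_epoch


def test_fit_deterministic_given_seeds():
    data = _clean_dataset()["A"]["phase"]
    splits = make_splits(data.labels, seed=0)
    tr, va = splits.cv_folds[0]
    tcfg = TrainConfig(max_epochs=4, seed=5)
    outs = []
    for _ in range(2):
        net = Network(TINY, seed=5)
        fit(net, data.data[tr], data.labels[tr], data.data[va], data.labels[va], tcfg)
        outs.append(net.predict_proba(data.data[va]))
    np.testing.assert_array_equal(outs[0], outs[1])


# ---------------------------------------------------------------------------
# random search
# ---------------------------------------------------------------------------

def _tiny_search_inputs():
    data = _clean_dataset()["A"]["phase"]
    splits = make_splits(data.labels, seed=0)
    tcfg = TrainConfig(max_epochs=2, seed=0)
    return data, splits, tcfg


def test_search_single_config_selected():
    data, splits, tcfg = _tiny_search_inputs()
    space = SearchSpace(f1=(2,), d=(1,), f2=(4,), optimizer=("adam",),
                        n_configs=1, n_iterations=1)
    best, runs = random_search(space, data.data, data.labels, splits, TINY, tcfg)
    assert best == 0 and len(runs) == 1


def test_search_selection_equals_brute_force_argmax():
    data, splits, tcfg = _tiny_search_inputs()
    space = SearchSpace(f1=(2, 4), d=(1,), f2=(4,), optimizer=("adam",),
                        n_configs=4, n_iterations=2)
    best, runs = random_search(space, data.data, data.labels, splits, TINY, tcfg,
                               seed=3)
    assert best == select_best_config(runs)


def test_search_dominant_config_wins():
    runs = [{"config_index": 0, "iteration": i, "val_accuracy": 0.55} for i in range(3)]
    runs += [{"config_index": 1, "iteration": i, "val_accuracy": 0.80} for i in range(3)]
    assert select_best_config(runs) == 1


# ---------------------------------------------------------------------------
# paradigms
# ---------------------------------------------------------------------------

def test_montage_specific_picks_planted_better_montage():
    """A montage with a strong effect beats one with no effect, chosen on
    validation accuracy alone."""
    strong = _clean_dataset(seed=1, amp=5.0)["A"]["phase"]
    null_ds = generate_subject_dataset(
        SimConfig(n_blocks=5, n_montages_per_subject=1, effect_amplitude=0.0,
                  noise_sd=0.5, voxel_dropout_range=(0.0, 0.1), seed=2), 0)
    weak = null_ds["A"]["phase"]
    subject_data = {"A": {"phase": weak}, "B": {"phase": strong}}
    tcfg = TrainConfig(max_epochs=12, patience=11, seed=0)
    res = run_montage_specific(subject_data, TINY, tcfg, seed=0)
    assert res["best_montage"] == "B"
    # the choice is exactly the validation-accuracy argmax (test isolation)
    vals = {k: v.mean_val_accuracy for k, v in res["per_montage"].items()}
    assert res["best_montage"] == max(sorted(vals), key=vals.get)
    for r in res["per_montage"].values():
        r.splits.validate_disjoint()


def test_cross_montage_pools_and_stratifies():
    data = _clean_dataset(montages=2, n_blocks=4)
    res = run_cross_montage(data, TINY, TrainConfig(max_epochs=2, seed=0), seed=0)
    n_pool = 2 * data["A"]["phase"].n_trials
    assert len(res.splits.test_indices) == int(np.ceil(0.2 * n_pool))
    with pytest.raises(ValueError):
        run_cross_montage({"A": data["A"]}, TINY, TrainConfig(max_epochs=1), seed=0)


def test_pretrain_excludes_target_and_zero_epoch_finetune():
    data = _clean_dataset(montages=3, n_blocks=4)
    tcfg = TrainConfig(max_epochs=3, seed=0)
    out = run_pretrain_finetune(data, "B", TINY, tcfg, seed=0,
                                finetune_cfg=TrainConfig(max_epochs=0, seed=0))
    assert "B" not in out["pretrain_montages"]
    assert sorted(out["pretrain_montages"]) == ["A", "C"]
    # 0-epoch fine-tune: every fold reports the same pre-trained-model metrics
    accs = {m.accuracy for m in out["result"].fold_test_metrics}
    assert len(accs) == 1


def test_pretrain_requires_other_montages():
    data = _clean_dataset(montages=1)
    with pytest.raises(ValueError):
        run_pretrain_finetune(data, "A", TINY, TrainConfig(max_epochs=1), seed=0)


def test_nonfinite_loss_aborts():
    data = _clean_dataset()["A"]["phase"]
    splits = make_splits(data.labels, seed=0)
    tr, va = splits.cv_folds[0]
    net = Network(TINY, seed=0)
    X = data.data[tr].copy()
    X[0, 0, 0] = np.nan               # corrupted input must abort, not proceed
    with pytest.raises(FloatingPointError):
        fit(net, X, data.labels[tr], data.data[va], data.labels[va],
            TrainConfig(max_epochs=2, seed=0))
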