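"""Splitting, optimisation plumbing and the evaluation metric suite."""

import dataclasses
import logging

import numpy as np
import pytest

from nucleiguide.network import init_params, one_hot
from nucleiguide.training import (
    EvalReport,
    TrainConfig,
    ablation_table,
    evaluate_predictions,
    run_ablation,
    split_dataset,
    train,
)


# ---------------------------------------------------------------------------
# splitting


def test_split_is_stratified_80_20():
    grades = np.repeat([1, 2, 3], 10)
    tr, te = split_dataset(grades, 0.8, seed=0)
    assert len(tr) == 24 and len(te) == 6
    for g in (1, 2, 3):
        assert (grades[tr] == g).sum() == 8
        assert (grades[te] == g).sum() == 2


def test_split_is_deterministic_and_partitions():
    grades = np.repeat([1, 2, 3], 7)
    tr1, te1 = split_dataset(grades, 0.8, seed=9)
    tr2, te2 = split_dataset(grades, 0.8, seed=9)
    assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
    union = np.sort(np.concatenate([tr1, te1]))
    assert np.array_equal(union, np.arange(grades.size))
    assert not set(tr1) & set(te1)


def test_split_rejects_tiny_classes():
    with pytest.raises(ValueError, match="need >= 2"):
        split_dataset(np.array([1, 1, 2]), 0.8, seed=0)
    with pytest.raises(ValueError, match="split_fraction"):
        TrainConfig(split_fraction=1.0)


# ---------------------------------------------------------------------------
# training loop plumbing


def test_zero_epochs_changes_nothing(tiny_config, rng):
    params = init_params(tiny_config, seed=0)
    before = {k: p.data.copy() for k, p in params.items()}
    xm = rng.random((4, 3, 8, 8))
    history = train(
        params, xm, xm.copy(), np.array([1, 2, 3, 1]), tiny_config,
        TrainConfig.desk(epochs=0, seed=0),
    )
    assert history == []
    for k in params:
        assert np.array_equal(params[k].data, before[k])


def test_training_is_bit_reproducible(tiny_config, rng):
    xm = rng.random((6, 3, 8, 8))
    xn = xm * (rng.random((6, 1, 8, 8)) > 0.5)
    grades = np.array([1, 2, 3, 1, 2, 3])
    runs = []
    for _ in range(2):
        params = init_params(tiny_config, seed=7)
        hist = train(
            params, xm, xn, grades, tiny_config,
            TrainConfig.desk(epochs=3, seed=7, clip_norm=0.5),
        )
        runs.append((hist, {k: p.data.copy() for k, p in params.items()}))
    assert runs[0][0] == runs[1][0]
    for k in runs[0][1]:
        assert np.array_equal(runs[0][1][k], runs[1][1][k])


# ---------------------------------------------------------------------------
# metrics


def test_perfect_two_class_report():
    y = np.array([1] * 5 + [2] * 5)
    probs = one_hot(y, 2)
    rep = evaluate_predictions(y, probs)
    assert np.array_equal(rep.confusion, [[5, 0], [0, 5]])
    assert rep.accuracy == 1.0
    assert rep.macro_sensitivity == 1.0
    assert rep.macro_specificity == 1.0
    assert rep.mean_auc == 1.0


def test_binary_confusion_formulas_by_hand():
    # class 1 as positive: TP=3, FN=1, TN=4, FP=2
    y = np.array([1, 1, 1, 1, 2, 2, 2, 2, 2, 2])
    pred = np.array([1, 1, 1, 2, 1, 1, 2, 2, 2, 2])
    probs = one_hot(pred, 2) * 0.8 + 0.1
    rep = evaluate_predictions(y, probs)
    assert np.array_equal(rep.confusion, [[3, 1], [2, 4]])
    assert rep.per_class_sensitivity[0] == pytest.approx(0.75)
    assert rep.per_class_specificity[0] == pytest.approx(4 / 6)
    assert rep.accuracy == pytest.approx(0.7)


def test_three_class_report_matches_hand_computation():
    # 9 items; predictions wrong on the last item of each grade:
    # true 1 -> [1,1,2]; true 2 -> [2,2,3]; true 3 -> [3,3,1]
    y = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
    pred = np.array([1, 1, 2, 2, 2, 3, 3, 3, 1])
    probs = one_hot(pred, 3) * 0.6 + 0.2
    rep = evaluate_predictions(y, probs)
    assert np.array_equal(rep.confusion, [[2, 1, 0], [0, 2, 1], [1, 0, 2]])
    assert rep.accuracy == pytest.approx(6 / 9)
    # every class: TP=2, FN=1, FP=1, TN=5
    assert np.allclose(rep.per_class_sensitivity, 2 / 3)
    assert np.allclose(rep.per_class_specificity, 5 / 6)
    assert np.allclose(rep.per_class_accuracy, 7 / 9)
    assert rep.macro_sensitivity == pytest.approx(2 / 3)
    assert rep.macro_specificity == pytest.approx(5 / 6)
    assert rep.macro_accuracy == pytest.approx(7 / 9)
    assert rep.n_test == 9


def test_random_scorer_auc_is_half():
    rng = np.random.default_rng(77)
    y = rng.integers(1, 3, size=2000)
    probs = rng.random((2000, 2))
    probs /= probs.sum(axis=1, keepdims=True)
    rep = evaluate_predictions(y, probs)
    assert abs(rep.mean_auc - 0.5) < 0.05


def test_absent_class_reported_as_undefined(caplog):
    y = np.array([1, 1, 2, 2])  # class 3 never occurs
    probs = one_hot(y, 3) * 0.7 + 0.1
    with caplog.at_level(logging.WARNING):
        rep = evaluate_predictions(y, probs)
    assert np.isnan(rep.per_class_sensitivity[2])
    assert np.isnan(rep.per_class_auc[2])
    # macros average only the defined classes
    assert rep.macro_sensitivity == pytest.approx(1.0)
    assert "absent" in caplog.text


def test_eval_report_json_round_trip():
    y = np.array([1, 1, 2, 2, 3, 3])
    probs = one_hot(np.array([1, 2, 2, 2, 3, 1]), 3) * 0.7 + 0.1
    rep = evaluate_predictions(y, probs)
    back = EvalReport.from_dict(rep.to_dict())
    assert np.array_equal(back.confusion, rep.confusion)
    assert back.accuracy == rep.accuracy
    assert np.allclose(back.per_class_auc, rep.per_class_auc, equal_nan=True)


# ---------------------------------------------------------------------------
# ablation harness (miniature smoke; the full-scale run lives in acceptance)


def test_ablation_table_runs_all_six_variants(small_synth):
    cfg = small_synth.config
    tc = TrainConfig.desk(epochs=1, batch_size=16, seed=0, clip_norm=0.5)
    reports = run_ablation(
        small_synth.x_main, small_synth.x_nuclei, small_synth.grades, cfg, tc
    )
    table = ablation_table(reports)
    assert len(table) == 6
    assert {r["variant"] for r in table} == {
        "image_only", "nuclei_only", "no_nga_no_ngf", "no_ngf", "no_nga", "full",
    }
    for row in table:
        for col in ("accuracy", "sensitivity", "specificity", "auc"):
            assert 0.0 <= row[col] <= 1.0


def test_ablation_is_deterministic_under_fixed_seed(small_synth):
    cfg = small_synth.config
    tc = TrainConfig.desk(epochs=1, batch_size=16, seed=3, clip_norm=0.5)
    variants = ("image_only", "full")
    r1 = run_ablation(
        small_synth.x_main, small_synth.x_nuclei, small_synth.grades, cfg, tc,
        variants=variants,
    )
    r2 = run_ablation(
        small_synth.x_main, small_synth.x_nuclei, small_synth.grades, cfg, tc,
        variants=variants,
    )
    for v in variants:
        assert np.array_equal(r1[v].confusion, r2[v].confusion)
        assert r1[v].accuracy == r2[v].accuracy
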