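"""Labeling, splitting, scaling, SVM strategies, evaluation, comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seedling_observer.observer import (
    LabeledSamples,
    ModelEvaluation,
    ObserverStrategy,
    RangeScaler,
    TrainingError,
    compare_strategies,
    default_roster,
    entry_feature_columns,
    evaluate,
    label_growth,
    run_roster,
    scale_features,
    select_final_model,
    split_dataset,
    train_observer,
)

# ------------------------------------------------------------------ labeling


@pytest.mark.parametrize(
    "values,expected",
    [
        ([1, 2, 3], [-1, 1, 1]),          # tie at the mean counts as good
        ([5, 5, 5], [1, 1, 1]),
        ([0, 10], [-1, 1]),
    ],
)
def test_label_growth_examples(values, expected):
    assert label_growth(values).tolist() == expected


@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
def test_labels_always_contain_a_good_sample(values):
    labels = label_growth(values)
    assert set(np.unique(labels)) <= {-1, 1}
    assert (labels == 1).any()  # the maximum is never below the mean


# ----------------------------------------------------------------- splitting


def test_reference_split_sizes():
    trials = np.repeat(np.arange(13), [6] * 8 + [5] * 5)
    train, test = split_dataset(trials, n_train=48, seed=0)
    assert len(train) == 48 and len(test) == 25
    # stratification: every trial appears in training
    assert set(trials[train]) == set(range(13))


def test_split_is_deterministic_and_exhaustive():
    trials = np.repeat(np.arange(5), 8)
    a = split_dataset(trials, n_train=30, seed=42)
    b = split_dataset(trials, n_train=30, seed=42)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    c = split_dataset(trials, n_train=30, seed=43)
    assert not np.array_equal(a[0], c[0])


def test_tiny_split_partition_by_enumeration():
    trials = np.array([1, 1, 2, 2])
    train, test = split_dataset(trials, n_train=2, seed=3)
    assert sorted(np.concatenate([train, test]).tolist()) == [0, 1, 2, 3]
    assert set(train) & set(test) == set()
    assert len(train) == 2


def test_split_rejects_impossible_sizes():
    with pytest.raises(ValueError):
        split_dataset(np.array([1, 1, 2]), n_train=3)


# ------------------------------------------------------------------- scaling


def test_range_scaler_maps_training_extremes_to_unit_interval():
    train = np.array([[0.0, 5.0], [10.0, 15.0]])
    test = np.array([[5.0, 20.0]])
    train_s, test_s, scaler = scale_features(train, test)
    assert np.allclose(train_s, [[-1, -1], [1, 1]])
    assert test_s[0, 0] == pytest.approx(0.0)
    assert test_s[0, 1] == pytest.approx(2.0)  # extrapolation is permitted


def test_zero_range_column_maps_to_zero():
    train = np.array([[3.0, 1.0], [3.0, 2.0]])
    scaler = RangeScaler.fit(train)
    out = scaler.transform(np.array([[3.0, 1.5], [99.0, 1.5]]))
    assert np.allclose(out[:, 0], 0.0)


# ------------------------------------------------------------------ training


def _samples(x, y, target="g"):
    return LabeledSamples(
        np.asarray(x, float), np.asarray(y, int),
        tuple(f"f{j}" for j in range(np.asarray(x).shape[1])), "combo", target,
    )


def test_linearly_separable_data_trains_perfectly():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(80, 2))
    x = x[np.abs(x.sum(axis=1)) > 0.5][:40]  # leave a real margin
    y = np.where(x.sum(axis=1) > 0, 1, -1)
    model = train_observer(_samples(x, y), ObserverStrategy(kind="L", C=100.0))
    assert evaluate(model, _samples(x, y)) == 1.0


def test_xor_defeats_linear_but_not_rbf():
    x = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    y = np.array([-1, 1, 1, -1])
    linear = train_observer(_samples(x, y), ObserverStrategy(kind="L", C=100.0))
    assert evaluate(linear, _samples(x, y)) < 1.0
    rbf = train_observer(
        _samples(x, y), ObserverStrategy(kind="R", C=100.0, gamma=2.0)
    )
    assert evaluate(rbf, _samples(x, y)) == 1.0


def test_auto_tuned_training_is_deterministic():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(30, 3))
    y = np.where(x[:, 0] - 0.5 * x[:, 2] > 0, 1, -1)
    strat = ObserverStrategy(kind="Rac", c_grid=(0.1, 1.0, 10.0),
                             gamma_grid=(0.01, 0.1, 1.0), cv_folds=3)
    m1 = train_observer(_samples(x, y), strat)
    m2 = train_observer(_samples(x, y), strat)
    assert m1.chosen_params == m2.chosen_params
    assert np.array_equal(m1.svc.dual_coef_, m2.svc.dual_coef_)


def test_single_class_training_error_names_target():
    x = np.zeros((5, 2))
    y = np.ones(5, dtype=int)
    with pytest.raises(TrainingError, match="g1_d9"):
        train_observer(_samples(x, y, target="g1_d9"), ObserverStrategy(kind="L"))


def test_strategy_validation():
    with pytest.raises(ValueError):
        ObserverStrategy(kind="poly")
    with pytest.raises(ValueError):
        ObserverStrategy(kind="R", C=-1.0)
    with pytest.raises(ValueError):
        ObserverStrategy(kind="R", gamma=0.0)


# ---------------------------------------------------------------- evaluation


def test_evaluate_counts_correct_fraction():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(30, 2))
    y = np.where(x[:, 0] > 0, 1, -1)
    model = train_observer(_samples(x, y), ObserverStrategy(kind="L", C=100.0))
    test_x = rng.normal(size=(25, 2))
    truth = np.where(test_x[:, 0] > 0, 1, -1)
    pred = model.predict(test_x)
    expected = float(np.mean(pred == truth))
    assert evaluate(model, _samples(test_x, truth)) == pytest.approx(expected)
    # agreeing/opposite labels bound the rate exactly
    assert evaluate(model, _samples(test_x, pred)) == 1.0
    assert evaluate(model, _samples(test_x, -pred)) == 0.0


def test_evaluate_invariant_under_sample_reordering():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(20, 2))
    y = np.where(x.sum(axis=1) > 0, 1, -1)
    model = train_observer(_samples(x, y), ObserverStrategy(kind="L"))
    test_x = rng.normal(size=(15, 2))
    test_y = np.where(test_x.sum(axis=1) > 0, 1, -1)
    base = evaluate(model, _samples(test_x, test_y))
    perm = rng.permutation(15)
    assert evaluate(model, _samples(test_x[perm], test_y[perm])) == base


def test_evaluate_rejects_feature_mismatch():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(10, 2))
    y = np.where(x[:, 0] > 0, 1, -1)
    model = train_observer(_samples(x, y), ObserverStrategy(kind="L"))
    other = LabeledSamples(x, y, ("a", "b"), "combo", "g")
    with pytest.raises(ValueError, match="feature mismatch"):
        evaluate(model, other)


# ---------------------------------------------------------------- comparison


def _ev(strategy, fclass, target_name, rate, nfeat=8, target="g1_d9"):
    return ModelEvaluation(strategy, fclass, target, target_name,
                           "combo", rate, nfeat)


def test_compare_strategies_group_summaries():
    report_evs = [
        _ev("L", "e", "Plant_Height", 0.8),
        _ev("L", "e", "Plant_Height", 0.9),
        _ev("L", "e", "Plant_Height", 1.0),
        _ev("R", "p", "Plant_Height", 0.7),
    ]
    from seedling_observer.observer import EvaluationReport

    with pytest.warns(UserWarning):  # some of the 9 groups are empty
        summary = compare_strategies(EvaluationReport(report_evs))
    group = summary["Plant_Height"]["L(e)"]
    assert (group["min"], group["avg"], group["max"]) == (0.8, 0.9, 1.0)
    single = summary["Plant_Height"]["R(p)"]
    assert single["min"] == single["avg"] == single["max"] == 0.7


def test_select_final_model_tie_breaks():
    evs = [
        _ev("R", "e", "Plant_Height", 0.90, nfeat=8),
        _ev("L", "e", "Plant_Height", 0.95, nfeat=8),
        _ev("Rac", "p", "Plant_Height", 0.95, nfeat=6),
        _ev("L", "p", "Plant_Height", 0.95, nfeat=6),
    ]
    best = select_final_model(evs, "g1_d9")
    assert best.success_rate == 0.95
    assert best.n_features == 6        # fewer features beats more
    assert best.strategy == "Rac"      # then strategy preference
    with pytest.raises(ValueError):
        select_final_model(evs, "g9_d9")


# -------------------------------------------------------------------- roster


def test_roster_enumerates_twenty_observer_families():
    roster = default_roster()
    assert len(roster) == 20
    by_class = {c: sum(e.feature_class == c for e in roster) for c in ("e", "p", "e+p")}
    assert by_class == {"e": 6, "p": 8, "e+p": 6}


def test_entry_feature_columns_resolve_stage_and_combination():
    entry = next(e for e in default_roster() if e.name == "E_6D+P3_8D->G2")
    from seedling_observer.reference import screening_results
    from seedling_observer.screening import derive_preset

    results = screening_results()
    combos = {name: derive_preset(name, results)
              for name in ("E_6D", "P_8D_6_9")}
    cols = entry_feature_columns(entry, combos)
    assert cols[:6] == ["e1", "e2", "e4", "e6", "e7", "e8"]
    assert cols[6:] == [f"{p}_d6" for p in
                        ("p1", "p2", "p3", "p4", "p5", "p7", "p8", "p10")]


def test_run_roster_is_deterministic(default_dataset):
    entries = tuple(e for e in default_roster() if e.name in ("E_8D->G1", "P2->G1"))
    r1 = run_roster(default_dataset, strategies=("L",), seed=9, entries=entries)
    r2 = run_roster(default_dataset, strategies=("L",), seed=9, entries=entries)
    assert [e.success_rate for e in r1.evaluations] == \
        [e.success_rate for e in r2.evaluations]
    assert len(r1.evaluations) == 4  # 2 entries x 2 growth variables (G1)


def test_full_roster_produces_nine_groups_per_target(default_dataset):
    small_rac = ObserverStrategy(kind="Rac", c_grid=(1.0, 100.0),
                                 gamma_grid=(0.01, 0.1), cv_folds=3)
    report = run_roster(
        default_dataset,
        strategies=("L", ObserverStrategy(kind="R"), small_rac),
        seed=0,
    )
    summary = compare_strategies(report)
    # every growth variable gets the full 3 strategies x 3 feature classes
    for target, groups in summary.items():
        assert len(groups) == 9, target
    assert set(summary) == {"Plant_Height", "Leaf_Area", "Fresh_Weight", "Dry_Weight"}
    for groups in summary.values():
        for s in groups.values():
            assert 0.0 <= s["min"] <= s["avg"] <= s["max"] <= 1.0
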