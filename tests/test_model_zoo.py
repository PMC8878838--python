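"""Feature pre-screen, GA subset selection, nested-CV training, the elbow
rule and UpSet intersection counts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metabscreen.model_zoo import (
    MODEL_KINDS,
    GaConfig,
    feature_weight_elbow,
    ga_select,
    prescreen_features,
    train_model,
    upset_intersections,
)

from conftest import planted_matrix


# ---------------------------------------------------------------- prescreen


def test_prescreen_drops_label_mirror_and_constant():
    X, y = planted_matrix(n_per_class=30, p=6, informative=(), seed=1)
    X["mirror"] = (y == "CRC").astype(float)  # correlation 1 with the label
    X["const"] = 3.14
    kept = prescreen_features(X, y)
    assert "mirror" not in kept
    assert "const" not in kept
    assert set(kept) == {c for c in X.columns if c.startswith("F")}


def test_prescreen_matches_brute_force_modal_screen():
    rng = np.random.default_rng(2)
    n = 100
    X = pd.DataFrame(
        {
            "ok": rng.normal(size=n),
            "mostly_zero": np.where(rng.random(n) < 0.97, 0.0, rng.normal(size=n)),
            "half_zero": np.where(rng.random(n) < 0.5, 0.0, rng.normal(size=n)),
            "gappy": np.where(rng.random(n) < 0.4, np.nan, rng.normal(size=n)),
        }
    )
    y = pd.Series(rng.permutation(["CTRL", "CRC"] * (n // 2)))
    kept = prescreen_features(X, y, modal_max=0.95, max_missing=0.2)

    expected = []
    for c in X.columns:
        v = X[c]
        if v.isna().mean() > 0.2:
            continue
        vv = v.dropna()
        if vv.value_counts().iloc[0] / len(vv) > 0.95 or vv.nunique() == 1:
            continue
        expected.append(c)
    assert kept == expected
    assert "mostly_zero" not in kept and "gappy" not in kept


# ---------------------------------------------------------------- GA


def test_ga_single_feature_short_circuits():
    X, y = planted_matrix(n_per_class=20, p=1, informative=(0,), seed=3)
    res = ga_select(X, y, kind="NB", ga=GaConfig(seed=0))
    assert res.features == list(X.columns)
    assert res.n_evaluated == 1


def test_ga_trace_is_monotone_with_elitism():
    X, y = planted_matrix(n_per_class=25, p=10, informative=(0, 1), seed=4)
    res = ga_select(X, y, kind="NB", ga=GaConfig(population=8, generations=12, seed=1))
    assert all(b >= a for a, b in zip(res.trace, res.trace[1:]))


def test_ga_recovers_planted_pair_most_seeds():
    """2 informative + 18 noise features, NB fitness, 30 generations: the
    best subset contains both informative features in nearly every seed
    (smoke-scale version of the full 20-seed recovery check)."""
    hits = 0
    for seed in range(6):
        X, y = planted_matrix(
            n_per_class=100, p=20, informative=(0, 1), shift=1.2, seed=100 + seed
        )
        res = ga_select(
            X, y, kind="NB",
            ga=GaConfig(population=20, generations=30, folds=5, seed=seed),
        )
        hits += {"F00", "F01"} <= set(res.features)
    assert hits >= 5


def test_ga_rejects_tiny_population():
    X, y = planted_matrix(seed=5)
    with pytest.raises(ValueError, match="population"):
        ga_select(X, y, ga=GaConfig(population=1))


# ---------------------------------------------------------------- training


def test_separable_data_gives_perfect_cv_accuracy():
    X, y = planted_matrix(n_per_class=30, p=8, informative=(0, 1), shift=6.0, seed=6)
    for kind in ("SVM", "DT"):
        tm = train_model(kind, X, y, outer_folds=5, inner_folds=3, seed=0)
        assert tm.cv_accuracy == pytest.approx(1.0)


def test_null_labels_give_chance_level_accuracy():
    accs = []
    for seed in range(3):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(60, 10)), columns=[f"F{j}" for j in range(10)]
        )
        y = pd.Series(rng.permutation(["CTRL", "CRC"] * 30))
        for kind in ("NB", "GLM", "DT"):
            tm = train_model(kind, X, y, outer_folds=5, inner_folds=3, seed=seed)
            accs.append(tm.cv_accuracy)
    assert all(0.25 <= a <= 0.75 for a in accs)
    assert 0.35 <= np.mean(accs) <= 0.65


def test_deterministic_kinds_reproduce_exactly():
    X, y = planted_matrix(n_per_class=25, p=10, informative=(0,), seed=7)
    for kind in ("NB", "GLM", "LR", "DT", "PLSDA"):
        a = train_model(kind, X, y, outer_folds=4, inner_folds=3, seed=5)
        b = train_model(kind, X, y, outer_folds=4, inner_folds=3, seed=5)
        assert a.cv_accuracy == b.cv_accuracy
        assert a.hyperparameters == b.hyperparameters
        pd.testing.assert_series_equal(a.feature_weights, b.feature_weights)


def test_confidence_is_winning_class_probability():
    X, y = planted_matrix(n_per_class=30, p=6, informative=(0, 1), seed=8)
    tm = train_model("GLM", X, y, outer_folds=4, inner_folds=3, seed=0)
    preds = tm.predict_samples(X)
    assert ((preds["confidence"] >= 0.5) & (preds["confidence"] <= 1.0)).all()


def test_no_leakage_from_test_labels():
    """Every TrainedModel field is computed from the training split alone;
    shuffling labels of unseen data changes nothing."""
    X, y = planted_matrix(n_per_class=30, p=8, informative=(0, 1), seed=9)
    a = train_model("GLM", X, y, outer_folds=4, inner_folds=3, seed=1)
    b = train_model("GLM", X, y, outer_folds=4, inner_folds=3, seed=1)
    # 'b' then sees a test set with shuffled labels — irrelevant by design
    X_test, _ = planted_matrix(n_per_class=10, p=8, informative=(0, 1), seed=10)
    b.predict_samples(X_test)
    assert a.cv_accuracy == b.cv_accuracy
    assert a.hyperparameters == b.hyperparameters
    pd.testing.assert_series_equal(a.feature_weights, b.feature_weights)


def test_unknown_kind_rejected():
    X, y = planted_matrix(seed=11)
    with pytest.raises(ValueError, match="unknown model kind"):
        train_model("QDA", X, y)


# ---------------------------------------------------------------- elbow


def test_elbow_hand_example():
    w = pd.Series([10, 9, 1, 0.9, 0.8], index=list("abcde"))
    assert feature_weight_elbow(w) == ["a", "b"]


def test_elbow_two_features_returns_both():
    w = pd.Series([5.0, 1.0], index=["a", "b"])
    assert feature_weight_elbow(w) == ["a", "b"]


def test_elbow_equal_weights_returns_all():
    w = pd.Series([2.0, 2.0, 2.0, 2.0], index=list("abcd"))
    assert set(feature_weight_elbow(w)) == set("abcd")


def test_elbow_linear_weights_break_ties_toward_fewer():
    w = pd.Series(np.linspace(10, 1, 8), index=list("abcdefgh"))
    assert feature_weight_elbow(w) == ["a"]


# ---------------------------------------------------------------- UpSet


def test_upset_identical_sets_single_full_intersection():
    sets = {m: {"x", "y", "z"} for m in ("A", "B", "C")}
    counts = upset_intersections(sets)
    assert counts[("A", "B", "C")] == 3
    assert counts.drop(index=[("A", "B", "C")]).sum() == 0


def test_upset_disjoint_sets_have_no_higher_order_overlap():
    sets = {"A": {"x"}, "B": {"y"}, "C": {"z"}}
    counts = upset_intersections(sets)
    for combo, cnt in counts.items():
        if len(combo) >= 2:
            assert cnt == 0


def test_upset_matches_enumeration_oracle():
    rng = np.random.default_rng(12)
    universe = [f"m{i}" for i in range(20)]
    sets = {
        name: set(rng.choice(universe, size=rng.integers(5, 15), replace=False))
        for name in ("A", "B", "C")
    }
    counts = upset_intersections(sets)
    names = sorted(sets)
    for r in range(1, 4):
        for combo in itertools.combinations(names, r):
            expected = sum(
                1
                for el in universe
                if all(el in sets[n] for n in combo)
                and not any(el in sets[n] for n in set(names) - set(combo))
            )
            assert counts[combo] == expected
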