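"""Balancing, MDL discretization, CFS, weighted Bayes, CV harness."""

import numpy as np
import pandas as pd
import pytest

from gaitstage.learn import (
    CPDTable,
    DiscretizationMap,
    EmptyClassError,
    ModelConfig,
    NBModel,
    balance_weights,
    cfs_select,
    cross_validate,
    fit_nb,
    fit_pipeline,
    mdl_discretize,
    predict,
    predict_proba,
    stratified_folds,
    symmetric_uncertainty,
    to_binary_labels,
)

STAGES_8_11_11 = np.array([1] * 8 + [2] * 11 + [3] * 11)


# -- balancing ---------------------------------------------------------------

def test_balance_weights_8_11_11():
    w = balance_weights(STAGES_8_11_11)
    assert w[STAGES_8_11_11 == 1].sum() == pytest.approx(10.0)
    assert w[STAGES_8_11_11 == 2].sum() == pytest.approx(10.0)
    assert set(np.round(w, 6)) == {1.25, round(10 / 11, 6)}


def test_balance_weights_uniform_when_balanced():
    np.testing.assert_allclose(balance_weights([0, 0, 1, 1, 2, 2]), 1.0)


def test_balance_weights_single_class_errors():
    with pytest.raises(EmptyClassError):
        balance_weights([1, 1, 1])


# -- MDL discretization ------------------------------------------------------

def test_mdl_accepts_single_cut_for_separable_classes():
    v = np.array([-2.0, -1.5, -1.0, -0.5, -0.2, 0.2, 0.5, 1.0, 1.5, 2.0])
    y = np.array([0] * 5 + [1] * 5)
    cuts = mdl_discretize(v, y)
    assert len(cuts) == 1
    assert -0.2 < cuts[0] < 0.2


def test_mdl_rejects_class_independent_noise():
    rng = np.random.default_rng(0)
    v = rng.uniform(size=50)
    y = rng.integers(0, 3, size=50)
    assert mdl_discretize(v, y) == []


def test_mdl_three_class_staircase_two_cuts():
    v = np.array([0, 0.1, 0.2, 0.3, 1.0, 1.1, 1.2, 1.3, 2.0, 2.1, 2.2, 2.3])
    y = np.array([0] * 4 + [1] * 4 + [2] * 4)
    cuts = mdl_discretize(v, y)
    assert len(cuts) == 2
    assert 0.3 < cuts[0] < 1.0 and 1.3 < cuts[1] < 2.0


def test_mdl_deterministic_and_missing_tolerant():
    rng = np.random.default_rng(1)
    v = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20), [np.nan] * 5])
    y = np.array([0] * 20 + [1] * 20 + [0, 1, 0, 1, 0])
    w = np.ones(45)
    assert mdl_discretize(v, y, w) == mdl_discretize(v, y, w)
    assert mdl_discretize(np.full(10, np.nan), np.arange(10) % 2) == []


# -- CFS ---------------------------------------------------------------------

def _toy_discrete(seed=1, n=60):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 3, n)
    X = pd.DataFrame({
        "perfect": y.copy(),
        "dup": y.copy(),
        "partial": (y > 0).astype(int),
        "n1": rng.integers(0, 3, n),
        "n2": rng.integers(0, 2, n),
        "n3": rng.integers(0, 4, n),
        "n4": rng.integers(0, 2, n),
        "n5": rng.integers(0, 3, n),
    })
    return X, y


def test_su_perfect_and_independent():
    X, y = _toy_discrete()
    w = np.ones(len(y))
    assert symmetric_uncertainty(X["perfect"].to_numpy(), y, w) == pytest.approx(1.0)
    assert symmetric_uncertainty(X["n1"].to_numpy(), y, w) < 0.15


def test_cfs_single_perfect_feature_merit_one():
    y = np.array([0, 0, 1, 1, 2, 2] * 5)
    X = pd.DataFrame({"f": y.copy()})
    res = cfs_select(X, y, np.ones(len(y)))
    assert res.selected == ["f"]
    assert res.merit == pytest.approx(1.0)


def test_cfs_redundant_copy_not_added():
    X, y = _toy_discrete()
    res = cfs_select(X, y, np.ones(len(y)))
    assert ("perfect" in res.selected) ^ ("dup" in res.selected)


def test_cfs_best_first_matches_exhaustive():
    X, y = _toy_discrete(seed=3)
    w = np.ones(len(y))
    bf = cfs_select(X, y, w, search="best_first")
    ex = cfs_select(X, y, w, search="exhaustive")
    assert bf.merit == pytest.approx(ex.merit)
    assert bf.merit >= max(m for _, m in bf.trace) - 1e-12


def test_cfs_no_informative_feature_returns_empty():
    X = pd.DataFrame({"f": [0] * 10, "g": [1] * 10})
    res = cfs_select(X, [0, 1] * 5, np.ones(10))
    assert res.selected == [] and res.merit == 0.0


# -- Laplace-smoothed Bayes --------------------------------------------------

def test_cpd_reconstructs_two_bin_printed_table():
    """Weighted alpha=0.5 estimator over 8/11/11 classes rebalanced to 10."""
    w = balance_weights(STAGES_8_11_11)
    bins = np.array([1] * 8 + [0] * 7 + [1] * 4 + [0] * 10 + [1] * 1)
    model = fit_nb(pd.DataFrame({"F1": bins}), STAGES_8_11_11, w,
                   DiscretizationMap({"F1": [0.5]}))
    np.testing.assert_allclose(
        np.round(model.cpds[0].probs, 3),
        [[0.045, 0.955], [0.624, 0.376], [0.872, 0.128]],
    )


def test_cpd_reconstructs_three_bin_printed_table():
    w = balance_weights(STAGES_8_11_11)
    bins = np.array([0] * 5 + [1] * 3 + [1] * 10 + [2] * 1 + [0] * 3 + [2] * 8)
    model = fit_nb(pd.DataFrame({"F3": bins}), STAGES_8_11_11, w,
                   DiscretizationMap({"F3": [0.5, 1.5]}))
    np.testing.assert_allclose(
        np.round(model.cpds[0].probs, 3),
        [[0.587, 0.370, 0.043], [0.043, 0.834, 0.123], [0.281, 0.043, 0.676]],
    )


def test_cpd_rows_priors_posterior_normalize():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 3, 40)
    X = pd.DataFrame({"f": rng.normal(size=40), "g": rng.normal(size=40)})
    model = fit_pipeline(X, y, ModelConfig(selector="none"))
    assert model.priors.sum() == pytest.approx(1.0, abs=1e-9)
    for cpd in model.cpds:
        np.testing.assert_allclose(cpd.probs.sum(axis=1), 1.0, atol=1e-9)
    post = predict_proba(model, X.iloc[0])
    assert post.sum() == pytest.approx(1.0, abs=1e-9)


def test_uniform_cpds_give_posterior_equal_prior():
    dmap = DiscretizationMap({"f": [0.0]})
    cpds = [CPDTable("f", [1, 2, 3], np.full((3, 2), 0.5))]
    model = NBModel([1, 2, 3], np.array([0.5, 0.3, 0.2]), cpds, dmap)
    post = predict_proba(model, {"f": 1.0})
    np.testing.assert_allclose(post.to_numpy(), model.priors)


def test_all_features_missing_posterior_equals_prior():
    dmap = DiscretizationMap({"f": [0.0]})
    cpds = [CPDTable("f", [1, 2], np.array([[0.9, 0.1], [0.2, 0.8]]))]
    model = NBModel([1, 2], np.array([0.7, 0.3]), cpds, dmap)
    post = predict_proba(model, {"f": float("nan")})
    np.testing.assert_allclose(post.to_numpy(), model.priors)


def test_printed_cpds_classify_low_f1_high_rest_as_stage3():
    tables = {
        "F1": [[0.045, 0.955], [0.624, 0.376], [0.872, 0.128]],
        "F2": [[0.727, 0.273], [0.707, 0.293], [0.045, 0.955]],
        "F3": [[0.587, 0.370, 0.043], [0.043, 0.834, 0.123], [0.281, 0.043, 0.676]],
        "F4": [[0.955, 0.045], [0.211, 0.789], [0.128, 0.872]],
        "F5": [[0.386, 0.614], [0.045, 0.955], [0.789, 0.211]],
        "F6": [[0.587, 0.043, 0.370], [0.043, 0.913, 0.043], [0.043, 0.518, 0.439]],
        "F7": [[0.955, 0.045], [0.872, 0.128], [0.128, 0.872]],
    }
    cuts = {f: ([0.5, 1.5] if f in ("F3", "F6") else [0.5]) for f in tables}
    cpds = [CPDTable(f, [1, 2, 3], np.array(t)) for f, t in tables.items()]
    model = NBModel([1, 2, 3], np.full(3, 1 / 3), cpds, DiscretizationMap(cuts))
    instance = {"F1": 0.0, "F2": 1.0, "F3": 2.0, "F4": 1.0,
                "F5": 0.0, "F6": 2.0, "F7": 1.0}
    assert predict(model, instance) == 3


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 30)
    X = pd.DataFrame({"f": y + rng.normal(0, 0.1, 30)})
    model = fit_pipeline(X, y, ModelConfig(selector="none"))
    p = tmp_path / "model.json"
    model.to_json(p)
    back = NBModel.from_json(p)
    x0 = X.iloc[0]
    np.testing.assert_allclose(
        predict_proba(model, x0).to_numpy(), predict_proba(back, x0).to_numpy()
    )


# -- cross-validation --------------------------------------------------------

def test_stratified_folds_cover_everything_once():
    labels = STAGES_8_11_11
    rng = np.random.default_rng(0)
    folds = list(stratified_folds(labels, 10, rng))
    all_idx = np.concatenate(folds)
    assert sorted(all_idx.tolist()) == list(range(30))


def test_cv_perfectly_separable_is_100():
    y = np.array([0] * 10 + [1] * 10 + [2] * 10)
    X = pd.DataFrame({"f": np.concatenate([np.zeros(10), np.ones(10), 2 * np.ones(10)])
                      + np.random.default_rng(0).normal(0, 0.01, 30)})
    rep = cross_validate(X, y, ModelConfig(), folds=10, runs=2, base_seed=0)
    assert rep.mean_accuracy == pytest.approx(100.0)


def test_cv_label_permutation_drops_to_chance(cohort30_features):
    X, y = cohort30_features
    rng = np.random.default_rng(123)
    y_perm = rng.permutation(y)
    rep = cross_validate(X, y_perm, ModelConfig(), folds=10, runs=2, base_seed=0)
    assert rep.mean_accuracy < 55.0  # three balanced classes: chance ~33%


def test_cv_rejects_more_folds_than_instances():
    X = pd.DataFrame({"f": [0.0, 1.0, 0.5]})
    with pytest.raises(ValueError):
        cross_validate(X, [0, 1, 0], folds=10, runs=1)


def test_baseline_classifier_adapter_runs(cohort30_features):
    X, y = cohort30_features
    rep = cross_validate(
        X, y, ModelConfig(classifier="tree"), folds=5, runs=1, base_seed=0
    )
    assert 0.0 <= rep.mean_accuracy <= 100.0


def test_binary_mode_collapses_stages():
    labels = np.array(["1", "2", "3", "control"])
    assert to_binary_labels(labels).tolist() == ["PD", "PD", "PD", "control"]
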