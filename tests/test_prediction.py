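import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

import dyntraj as dt
from dyntraj.prediction import (ElasticNetLogistic, default_grids,
                                importance_scores, pr_auc, roc_auc,
                                run_experiment, summarize_records, tune_and_fit)


def test_default_grids_match_protocol():
    alpha, lam = default_grids()
    assert len(alpha) == 10 and alpha[0] == 0.0 and alpha[-1] == 1.0
    assert alpha == (0.00, 0.11, 0.22, 0.33, 0.44, 0.55, 0.66, 0.77, 0.88, 1.00)
    assert lam[0] == 0.0001 and len(lam) == 10
    assert len(list(itertools.product(alpha, lam))) == 100


def test_solver_matches_sklearn_oracle(rng):
    # near-unpenalized ridge: coefficients must agree with an off-the-shelf
    # logistic regression to 1e-3
    n, p = 400, 8
    X = rng.normal(size=(n, p))
    y = (rng.random(n) < 1 / (1 + np.exp(-(1.2 * X[:, 0] - 0.8 * X[:, 3])))).astype(float)
    lam = 1e-4
    ours = ElasticNetLogistic(lam, 0.0, max_iter=8000, tol=1e-12).fit(X, y)
    ref = LogisticRegression(C=1 / (n * lam), max_iter=5000, tol=1e-10).fit(X, y)
    assert np.max(np.abs(ours.coef_ - ref.coef_[0])) < 1e-3
    assert abs(ours.intercept_ - ref.intercept_[0]) < 1e-3


def test_solver_matches_saga_elastic_net(rng):
    n, p = 300, 10
    X = rng.normal(size=(n, p))
    y = (rng.random(n) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
    lam, alpha = 0.11, 0.55
    ours = ElasticNetLogistic(lam, alpha, max_iter=5000, tol=1e-12).fit(X, y)
    ref = LogisticRegression(C=1 / (n * lam), l1_ratio=alpha, solver="saga",
                             max_iter=50000, tol=1e-12).fit(X, y)
    assert np.max(np.abs(ours.coef_ - ref.coef_[0])) < 1e-4


def test_heavy_penalty_zeroes_coefficients(rng):
    X = rng.normal(size=(100, 5))
    y = (rng.random(100) < 0.5).astype(float)
    m = ElasticNetLogistic(1.0, 1.0).fit(X, y)
    assert np.allclose(m.coef_, 0.0)


def test_separable_data_reaches_kappa_one(rng):
    n = 80
    X = np.column_stack([np.r_[np.zeros(n // 2), np.ones(n // 2)] * 4 - 2,
                         rng.normal(size=n)])
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    _, pair, kappa, _ = tune_and_fit(X, y, seed=0)
    assert kappa == 1.0


def test_null_labels_give_near_zero_kappa(rng):
    n = 500
    X = rng.normal(size=(n, 10))
    y = rng.permutation(np.r_[np.zeros(n // 2), np.ones(n // 2)])
    _, _, kappa, _ = tune_and_fit(X, y, seed=1)
    assert abs(kappa) < 0.1


def test_tie_break_prefers_stronger_regularization(rng):
    # pure-noise minority outcome: every pair has kappa 0, so the selected
    # pair must be the sparsest corner of the grid
    n = 200
    X = rng.normal(size=(n, 6))
    y = (rng.random(n) < 0.1).astype(float)
    if y.sum() < 2:
        y[:2] = 1
    _, (alpha, lam), kappa, _ = tune_and_fit(X, y, seed=3)
    assert kappa == 0.0 and lam == 1.0 and alpha == 1.0


def test_single_class_train_raises(rng):
    X = rng.normal(size=(20, 3))
    with pytest.raises(ValueError, match="single class"):
        tune_and_fit(X, np.zeros(20))


# ---------------------------------------------------------------------------
# metrics


def brute_force_roc_auc(scores, labels):
    """Exhaustive Mann-Whitney pair count with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_auc_examples():
    assert roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
    assert roc_auc([0.3, 0.3, 0.3, 0.3], [0, 1, 0, 1]) == 0.5
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75


def test_roc_auc_matches_exhaustive_pair_counting():
    # all label patterns x tied-score alphabets up to length 5, plus random
    # longer vectors with ties up to length 8
    alphabet = (0.2, 0.5, 0.8)
    for n in range(2, 6):
        for labels in itertools.product((0, 1), repeat=n):
            if len(set(labels)) < 2:
                continue
            for scores in itertools.product(alphabet, repeat=n):
                assert np.isclose(roc_auc(scores, labels),
                                  brute_force_roc_auc(scores, labels), atol=1e-12)
    rng = np.random.default_rng(0)
    for _ in range(300):
        n = int(rng.integers(6, 9))
        labels = rng.integers(0, 2, n)
        if len(set(labels)) < 2:
            continue
        scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.9], size=n)
        assert np.isclose(roc_auc(scores, labels),
                          brute_force_roc_auc(scores, labels), atol=1e-12)


def test_pr_auc_of_random_scorer_near_prevalence(rng):
    n, prev = 500, 0.25
    labels = (rng.random(n) < prev).astype(int)
    scores = rng.random(n)
    assert abs(pr_auc(scores, labels) - labels.mean()) < 0.05


def test_metrics_reject_single_class():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])
    with pytest.raises(ValueError):
        pr_auc([0.1, 0.2], [0, 0])


# ---------------------------------------------------------------------------
# importance


def test_importance_scaling():
    assert np.allclose(importance_scores([0.0, 0.5, 0.0]), [0, 100, 0])
    assert np.allclose(importance_scores([-0.3, 0.3]), [100, 100])
    assert np.allclose(importance_scores([0.0, 0.0]), [0, 0])


# ---------------------------------------------------------------------------
# harness


def _toy_feature_matrices(n=120, seed=0):
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    y = pd.Series((rng.random(n) < 0.4).astype(int), index=ids)
    fms = {}
    for cutoff in (1, 21):
        signal = y.to_numpy() * (0.3 if cutoff == 1 else 2.0)
        X = pd.DataFrame({
            "f1": signal + rng.normal(0, 1, n),
            "f2": rng.normal(0, 1, n),
        }, index=ids)
        fms[(cutoff, "ppa")] = dt.FeatureMatrix("I", cutoff, "ppa", X, y,
                                                ["f1", "f2"], [])
    return fms


def test_run_experiment_deterministic_and_split_reuse():
    fms = _toy_feature_matrices()
    config = dt.ExperimentConfig("I", (1, 21), ("ppa",), n_repeats=3, base_seed=5)
    r1 = run_experiment(config, fms)
    r2 = run_experiment(config, fms)
    assert r1.records.to_csv() == r2.records.to_csv()
    assert r1.split_hashes == r2.split_hashes
    assert len(r1.split_hashes) == 3


def test_more_informative_cutoff_scores_higher():
    fms = _toy_feature_matrices(n=200, seed=2)
    config = dt.ExperimentConfig("I", (1, 21), ("ppa",), n_repeats=5, base_seed=0)
    res = run_experiment(config, fms)
    s = res.summary
    out = s[(s["split"] == "out_of_train") & (s["metric"] == "roc_auc")]
    assert (out.loc[out["cutoff"] == 21, "mean"].iloc[0]
            > out.loc[out["cutoff"] == 1, "mean"].iloc[0])


def test_in_train_at_least_out_of_train_on_average():
    fms = _toy_feature_matrices(n=150, seed=3)
    config = dt.ExperimentConfig("I", (21,), ("ppa",), n_repeats=8, base_seed=1)
    res = run_experiment(config, fms)
    s = res.summary
    auc = s[s["metric"] == "roc_auc"].set_index("split")["mean"]
    assert auc["in_train"] >= auc["out_of_train"] - 0.02


def test_single_repeat_ci_is_point():
    records = pd.DataFrame([{"cutoff": 1, "feature_set": "ppa", "repeat": 0,
                             "split": "out_of_train", "metric": "roc_auc",
                             "value": 0.8, "note": ""}])
    s = summarize_records(records, 1)
    assert s["ci_low"].iloc[0] == s["ci_high"].iloc[0] == s["mean"].iloc[0] == 0.8


def test_degenerate_outcome_refused():
    fms = _toy_feature_matrices()
    for fm in fms.values():
        fm.y[:] = 0
    config = dt.ExperimentConfig("I", (1, 21), ("ppa",), n_repeats=2)
    with pytest.raises(ValueError, match="single class"):
        run_experiment(config, fms)


# ---------------------------------------------------------------------------
# property tests


from hypothesis import given, settings, strategies as st


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                          st.integers(0, 1)), min_size=2, max_size=10))
def test_roc_auc_pair_counting_property(pairs):
    scores = [s for s, _ in pairs]
    labels = [l for _, l in pairs]
    if len(set(labels)) < 2:
        return
    assert np.isclose(roc_auc(scores, labels),
                      brute_force_roc_auc(scores, labels), atol=1e-12)
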