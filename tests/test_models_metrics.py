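import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from crossess.errors import CrossessError
from crossess.models import (FAMILIES, ModelSpec, fit, permutation_importance,
                             pr_auc, roc_auc)


def separable_toy(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame({
        "f1": y * 10.0 + rng.normal(0, 0.1, n),
        "f2": rng.standard_normal(n),
    })
    return X, y


def test_roc_auc_worked_example():
    assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75


def test_roc_auc_extremes_and_ties():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5


def test_roc_auc_complement_symmetry():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(4, 40))
        s = rng.choice([0.1, 0.3, 0.5, 0.9], size=n)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        assert roc_auc(s, y) + roc_auc(-s, y) == pytest.approx(1.0, abs=1e-12)


def test_roc_auc_matches_sklearn():
    rng = np.random.default_rng(2)
    for _ in range(30):
        n = int(rng.integers(5, 60))
        s = rng.random(n)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_roc_auc_single_class_errors():
    with pytest.raises(CrossessError):
        roc_auc([0.1, 0.2], [1, 1])


def test_pr_auc_examples():
    assert pr_auc([0.9, 0.1], [1, 0]) == 1.0
    # one positive of n ranked last -> 1/n
    assert pr_auc([0.9, 0.8, 0.7, 0.1], [0, 0, 0, 1]) == pytest.approx(0.25)
    with pytest.raises(CrossessError):
        pr_auc([0.5, 0.6], [0, 0])


def test_pr_auc_random_scores_approach_prevalence():
    rng = np.random.default_rng(3)
    n, prevalence = 20000, 0.2
    y = (rng.random(n) < prevalence).astype(int)
    ap = pr_auc(rng.random(n), y)
    assert ap == pytest.approx(prevalence, abs=0.02)


def test_pr_auc_matches_sklearn_without_ties():
    rng = np.random.default_rng(4)
    for _ in range(30):
        n = int(rng.integers(5, 60))
        s = rng.permutation(np.linspace(0, 1, n))
        y = rng.integers(0, 2, n)
        if y.sum() == 0:
            continue
        assert pr_auc(s, y) == pytest.approx(average_precision_score(y, s), abs=1e-12)


@pytest.mark.parametrize("family", FAMILIES)
def test_every_family_fits_separable_toy(family):
    X, y = separable_toy()
    model = fit(ModelSpec(family, seed=0), X, y, tune=False)
    p = model.predict_proba(X).to_numpy()
    assert roc_auc(p, y) == 1.0
    assert p.min() >= 0.0 and p.max() <= 1.0


@pytest.mark.parametrize("family", ["GLM", "GBM", "XGB", "RF"])
def test_deterministic_families_reproduce(family):
    X, y = separable_toy(seed=5)
    p1 = fit(ModelSpec(family, seed=3), X, y).predict_proba(X)
    p2 = fit(ModelSpec(family, seed=3), X, y).predict_proba(X)
    pd.testing.assert_series_equal(p1, p2)


def test_predict_proba_feature_mismatch_is_named():
    X, y = separable_toy()
    model = fit(ModelSpec("GLM", seed=0), X, y, tune=False)
    bad = X.rename(columns={"f2": "other"})
    with pytest.raises(CrossessError, match="missing \\['f2'\\]"):
        model.predict_proba(bad)


def test_predict_proba_row_order_invariant():
    X, y = separable_toy(seed=6)
    model = fit(ModelSpec("GLM", seed=0), X, y, tune=False)
    p = model.predict_proba(X)
    shuffled = X.sample(frac=1.0, random_state=1)
    ps = model.predict_proba(shuffled)
    pd.testing.assert_series_equal(p.loc[shuffled.index], ps)


def test_glm_monotone_in_planted_feature():
    rng = np.random.default_rng(7)
    X = pd.DataFrame({"f": np.linspace(-3, 3, 200)})
    y = (X["f"] + rng.normal(0, 0.5, 200) > 0).astype(int).to_numpy()
    model = fit(ModelSpec("GLM", seed=0), X, y, tune=False)
    p = model.predict_proba(X).to_numpy()
    assert (np.diff(p) > 0).all()


def test_fit_validation():
    X, y = separable_toy()
    with pytest.raises(CrossessError, match="single-class"):
        fit(ModelSpec("GLM"), X, np.zeros(len(X)))
    with pytest.raises(CrossessError, match="unknown model family"):
        ModelSpec("DEEPNET")


def test_permutation_importance_finds_signal_feature():
    X, y = separable_toy(n=100, seed=8)
    model = fit(ModelSpec("GLM", seed=0), X, y, tune=False)
    imp = permutation_importance(model, X, y, seed=0)
    assert imp.loc["f1"] > imp.loc["f2"]
    assert imp.loc["f1"] > 0.2
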