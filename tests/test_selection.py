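import numpy as np
import pandas as pd
import pytest

from crossess.errors import CrossessError
from crossess.selection import (SelectionConfig, consensus_select,
                                elasticnet_select, ensemble_spls_select,
                                median_importance, spls_fit)


def planted_data(n=500, p_noise=20, effect=2.0, seed=0, n_informative=1):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, p_noise + n_informative)),
                     columns=[f"inf{i}" for i in range(n_informative)]
                     + [f"noise{i}" for i in range(p_noise)])
    z = X.iloc[:, :n_informative].sum(axis=1) * effect + rng.normal(0, 1, n)
    y = (z > np.quantile(z, 0.8)).astype(int).to_numpy()
    return X, y


def test_elasticnet_recovers_planted_feature():
    X, y = planted_data(seed=1)
    cfg = SelectionConfig(alpha_grid=(0.2, 0.5, 0.8), n_lambdas=6, cv_folds=3)
    assert "inf0" in elasticnet_select(X, y, cfg, seed=1)


def test_elasticnet_full_shrinkage_empty():
    X, y = planted_data(seed=2)
    cfg = SelectionConfig(alpha_grid=(0.9,), n_lambdas=(1e-8,), cv_folds=3)
    assert elasticnet_select(X, y, cfg, seed=2) == set()


def test_elasticnet_grouping_keeps_a_duplicated_copy():
    X, y = planted_data(seed=3)
    X["inf0_copy"] = X["inf0"]
    cfg = SelectionConfig(alpha_grid=(0.2, 0.5), n_lambdas=6, cv_folds=3)
    sel = elasticnet_select(X, y, cfg, seed=3)
    assert {"inf0", "inf0_copy"} & sel


def test_elasticnet_rejects_single_class():
    X, _ = planted_data(seed=4)
    with pytest.raises(CrossessError, match="single-class"):
        elasticnet_select(X, np.zeros(len(X)))


def test_spls_dense_limit_is_covariance_direction():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.standard_normal((60, 8)))
    y = rng.integers(0, 2, 60)
    fit = spls_fit(X, y, K=1, eta=0.0)
    yv = 2.0 * y - 1.0
    z = X.to_numpy().T @ (yv - yv.mean())
    np.testing.assert_allclose(fit.weights[:, 0], z / np.linalg.norm(z), atol=1e-10)


def test_spls_extreme_threshold_keeps_only_argmax():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(rng.standard_normal((80, 10)))
    y = rng.integers(0, 2, 80)
    fit = spls_fit(X, y, K=1, eta=0.999)
    assert int(np.count_nonzero(fit.weights[:, 0])) == 1


def test_spls_recovers_planted_set():
    X, y = planted_data(n=500, p_noise=20, n_informative=5, effect=1.5, seed=7)
    fit = spls_fit(X, y, K=2, eta=0.7)
    assert {f"inf{i}" for i in range(5)} <= set(fit.selected)


def test_spls_validation():
    X, y = planted_data(n=50, p_noise=5, seed=8)
    with pytest.raises(CrossessError, match="eta"):
        spls_fit(X, y, K=1, eta=1.0)
    with pytest.raises(CrossessError, match="K"):
        spls_fit(X, y, K=0)
    y_mixed = np.array([0, 1, 0, 1])
    with pytest.raises(CrossessError, match="rank"):
        spls_fit(X.iloc[:4, :3], y_mixed, K=4)


def test_ensemble_spls_threshold_extremes():
    X, y = planted_data(n=200, p_noise=10, n_informative=2, seed=9)
    cfg_union = SelectionConfig(ensemble_B=10, freq_threshold=0.0, spls_K=1)
    union, freqs = ensemble_spls_select(X, y, cfg_union, seed=9)
    assert union == set(freqs.index[freqs > 0])  # union over runs
    cfg_none = SelectionConfig(ensemble_B=10, freq_threshold=1.01, spls_K=1)
    none, _ = ensemble_spls_select(X, y, cfg_none, seed=9)
    assert none == set()
    with pytest.raises(CrossessError, match="ensemble_B"):
        ensemble_spls_select(X, y, SelectionConfig(ensemble_B=0), seed=9)


def test_consensus_select():
    assert consensus_select({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}
    assert consensus_select({"a"}, {"a"}) == {"a"}
    with pytest.warns(UserWarning, match="empty"):
        assert consensus_select({"a"}, {"b"}) == set()


def test_median_importance_aggregation():
    # each model's importances already span [0, 100]; f's median is the
    # middle of its three per-model values
    imps = {
        "m1": pd.Series({"f": 100.0, "g": 20.0}),
        "m2": pd.Series({"f": 60.0, "g": 100.0}),
        "m3": pd.Series({"f": 80.0, "g": 100.0}),
    }
    ranking = median_importance(imps)
    assert ranking.median.loc["f"] == 80.0
    assert ranking.median.loc["g"] == 100.0
    assert ranking.ranking == ["g", "f"]


def test_median_importance_rescales_to_100():
    ranking = median_importance({"m": pd.Series({"a": 0.02, "b": 0.01, "z": 0.0})})
    assert ranking.per_model.loc["a", "m"] == 100.0
    assert ranking.median.loc["z"] == 0.0
    # ties broken lexicographically
    tied = median_importance({"m": pd.Series({"b": 5.0, "a": 5.0})})
    assert tied.ranking == ["a", "b"]


def test_median_importance_requires_input():
    with pytest.raises(CrossessError):
        median_importance({})
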