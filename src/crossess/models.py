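"""The six classifier families behind one contract, plus ranking metrics.

Families: gradient boosting (GBM), extreme gradient boosting (XGB),
penalized logistic regression (GLM), random forest (RF), support vector
machine (SVM) and a single-hidden-layer neural network (NN).  ``fit`` runs a
small inner cross-validated grid search maximizing ROC-AUC and refits on the
full input; all randomness is seeded.  Class imbalance is left as-is — no
resampling — because prevalence is part of the prediction problem.

ROC-AUC and PR-AUC are implemented here in closed form (Mann-Whitney
statistic with half-credit for ties; average precision with tied scores
grouped) so the evaluation contract does not drift with library versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import CrossessError

FAMILIES = ("GBM", "XGB", "GLM", "RF", "SVM", "NN")

#: compact default grids (a handful of configurations per family) so the
#: inner search stays desk-scale; override via ModelSpec.grid
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "GBM": {"n_estimators": [150], "max_depth": [2, 3], "learning_rate": [0.1]},
    "XGB": {"n_estimators": [200], "max_depth": [2, 3], "learning_rate": [0.1, 0.3]},
    "GLM": {"C": [0.1, 1.0, 10.0]},
    "RF": {"n_estimators": [300], "max_features": ["sqrt", 0.3]},
    "SVM": {"C": [1.0, 10.0]},
    "NN": {"alpha": [1e-4, 1e-2]},
}


def _make_estimator(family: str, seed: int):
    if family == "GBM":
        return GradientBoostingClassifier(random_state=seed)
    if family == "XGB":
        return XGBClassifier(tree_method="hist", n_jobs=1, random_state=seed,
                             eval_metric="logloss", verbosity=0)
    if family == "GLM":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "SVM":
        return SVC(probability=True, gamma="scale", random_state=seed)
    if family == "NN":
        return MLPClassifier(hidden_layer_sizes=(32,), early_stopping=True,
                             max_iter=400, random_state=seed)
    raise CrossessError(f"unknown model family {family!r}; choose from {FAMILIES}")


@dataclass
class ModelSpec:
    family: str
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise CrossessError(f"unknown model family {self.family!r}; "
                                f"choose from {FAMILIES}")


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: Any = field(repr=False)
    feature_names: list[str]
    best_params: dict

    def predict_proba(self, X: pd.DataFrame) -> pd.Series:
        """Probability of the essential class per gene; feature order enforced."""
        if list(X.columns) != self.feature_names:
            missing = [f for f in self.feature_names if f not in X.columns]
            extra = [f for f in X.columns if f not in self.feature_names]
            if missing or extra:
                raise CrossessError(
                    f"feature mismatch: missing {missing}, unexpected {extra}"
                )
            X = X[self.feature_names]
        pos = list(self.estimator.classes_).index(1)
        return pd.Series(self.estimator.predict_proba(X.to_numpy())[:, pos],
                         index=X.index)


def _validate_fit_inputs(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if len(y) != len(X):
        raise CrossessError("X and y length mismatch")
    if len(np.unique(y)) < 2:
        raise CrossessError("training labels are single-class")
    return y


def fit(spec: ModelSpec, X: pd.DataFrame, y: np.ndarray,
        tune: bool = True, cv_folds: int = 3) -> TrainedModel:
    """Inner CV grid search maximizing ROC-AUC, refit on the full input.

    ``tune=False`` fits the first grid configuration directly (used inside
    large resampling loops where a per-replicate search is wasteful).
    """
    y = _validate_fit_inputs(X, y)
    est = _make_estimator(spec.family, spec.seed)
    grid = spec.grid if spec.grid is not None else DEFAULT_GRIDS[spec.family]
    n_configs = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if tune and n_configs > 1 and pd.Series(y).value_counts().min() >= cv_folds:
        cv = StratifiedKFold(cv_folds, shuffle=True, random_state=spec.seed)
        search = GridSearchCV(est, grid, scoring="roc_auc", cv=cv, n_jobs=1,
                              refit=True)
        search.fit(X.to_numpy(), y)
        return TrainedModel(spec, search.best_estimator_, list(X.columns),
                            dict(search.best_params_))
    params = {k: v[0] for k, v in grid.items()}
    est = clone(est).set_params(**params)
    est.fit(X.to_numpy(), y)
    return TrainedModel(spec, est, list(X.columns), params)


def roc_auc(scores, labels) -> float:
    """P(random positive outscores random negative), ties counted half.

    The Mann-Whitney form: (sum of positive ranks - n_pos(n_pos+1)/2) /
    (n_pos * n_neg) with average ranks for ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise CrossessError("scores and labels length mismatch")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise CrossessError("roc_auc needs both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_auc(scores, labels) -> float:
    """Average precision: step-wise integral of precision over recall.

    Scores are sorted descending with tied scores grouped (precision and
    recall move together across a tie block); AP = sum over blocks of
    delta-recall times end-of-block precision.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise CrossessError("scores and labels length mismatch")
    n_pos = int(np.sum(y == 1))
    if n_pos == 0:
        raise CrossessError("pr_auc needs at least one positive")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    ap = 0.0
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        block_tp = int(np.sum(y[i:j] == 1))
        prev_tp = tp
        tp += block_tp
        fp += (j - i) - block_tp
        if tp > prev_tp:
            precision = tp / (tp + fp)
            ap += (tp - prev_tp) / n_pos * precision
        i = j
    return float(ap)


def permutation_importance(model: TrainedModel, X: pd.DataFrame, y: np.ndarray,
                           n_repeats: int = 3, seed: int = 0) -> pd.Series:
    """Mean drop in ROC-AUC when each feature column is shuffled on held-out data."""
    y = _validate_fit_inputs(X, y)
    rng = np.random.default_rng(seed)
    base = roc_auc(model.predict_proba(X).to_numpy(), y)
    drops = {}
    for f in X.columns:
        vals = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[f] = rng.permutation(Xp[f].to_numpy())
            vals.append(base - roc_auc(model.predict_proba(Xp).to_numpy(), y))
        drops[f] = float(np.mean(vals))
    return pd.Series(drops)


def fit_all_families(X: pd.DataFrame, y: np.ndarray,
                     families: tuple[str, ...] = FAMILIES, seed: int = 0,
                     grids: Mapping[str, dict] | None = None,
                     tune: bool = True) -> dict[str, TrainedModel]:
    out = {}
    for fam in families:
        grid = (grids or {}).get(fam)
        out[fam] = fit(ModelSpec(fam, grid, seed), X, y, tune=tune)
    return out
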