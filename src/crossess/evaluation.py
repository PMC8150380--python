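"""Within-species evaluation protocols.

Three protocols, all operating on labeled (essential / non-essential) genes
only and all fully seeded:

* ``subsample_grid`` — stratified splits at training fractions 10%..90%,
  feature selection *inside* each training split (no leakage), all requested
  model families fitted and scored on the held-out part, plus a
  permuted-label background model per split as the negative control;
* ``bootstrap_evaluate`` — B stratified 90/10 resamples with per-replicate
  metrics and 5-95% summary intervals;
* ``nonredundant_filter`` — the overfitting control: greedy centroid
  clustering of proteins at >25% pairwise identity, keeping one gene per
  cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from sklearn.model_selection import StratifiedShuffleSplit

from . import models as M
from .errors import CrossessError
from .selection import SelectionConfig, select_features

logger = logging.getLogger(__name__)

GRID_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class EvaluationResult:
    """Long-format metric rows plus, for bootstraps, a summary frame."""

    rows: pd.DataFrame
    summary: pd.DataFrame | None = None


def _derive_seed(master: int, tag: str) -> int:
    import hashlib
    h = hashlib.blake2b(f"{tag}:{master}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2 ** 31)


def _stratified_split(y: np.ndarray, train_frac: float, seed: int):
    splitter = StratifiedShuffleSplit(n_splits=1, train_size=train_frac,
                                      random_state=seed)
    return next(splitter.split(np.zeros(len(y)), y))


def _split_ok(y: np.ndarray, idx: np.ndarray) -> bool:
    c = pd.Series(y[idx]).value_counts()
    return len(c) == 2 and c.min() >= 2


def subsample_grid(X: pd.DataFrame, y: np.ndarray,
                   families: tuple[str, ...] = M.FAMILIES,
                   fractions: tuple[float, ...] = GRID_FRACTIONS,
                   repeats: int = 5,
                   selection: SelectionConfig | None = None,
                   seed: int = 0, tune: bool = True,
                   background: bool = True) -> EvaluationResult:
    """Training-fraction grid with in-split feature selection and background.

    ``selection=None`` skips selection and trains on all features.  The
    background row per split refits a logistic model on permuted training
    labels — its ROC-AUC should hover around 0.5.
    """
    y = np.asarray(y).astype(int)
    rows = []
    for frac in fractions:
        for rep in range(repeats):
            split_seed = _derive_seed(seed, f"grid:{frac}:{rep}")
            try:
                train_idx, test_idx = _stratified_split(y, frac, split_seed)
            except ValueError as exc:
                warnings.warn(f"fraction {frac}, repeat {rep}: split failed ({exc})")
                continue
            if not (_split_ok(y, train_idx) and _split_ok(y, test_idx)):
                warnings.warn(f"fraction {frac}, repeat {rep}: "
                              "<2 members of a class in a split; skipped")
                continue
            X_tr, y_tr = X.iloc[train_idx], y[train_idx]
            X_te, y_te = X.iloc[test_idx], y[test_idx]
            feats = list(X.columns)
            if selection is not None:
                sel = select_features(X_tr, y_tr, selection, seed=split_seed)
                if sel.consensus_set:
                    feats = [f for f in X.columns if f in sel.consensus_set]
                else:
                    warnings.warn(f"fraction {frac}, repeat {rep}: empty consensus; "
                                  "using all features")
            for fam in families:
                model = M.fit(M.ModelSpec(fam, seed=split_seed),
                              X_tr[feats], y_tr, tune=tune)
                p = model.predict_proba(X_te[feats]).to_numpy()
                rows.append({
                    "family": fam, "fraction": frac, "replicate": rep,
                    "seed": split_seed, "n_train": len(train_idx),
                    "n_test": len(test_idx), "roc_auc": M.roc_auc(p, y_te),
                    "pr_auc": M.pr_auc(p, y_te), "n_features": len(feats),
                })
            if background:
                rng = np.random.default_rng(split_seed)
                y_perm = rng.permutation(y_tr)
                if len(np.unique(y_perm)) == 2:
                    bg = M.fit(M.ModelSpec("GLM", seed=split_seed),
                               X_tr[feats], y_perm, tune=False)
                    p = bg.predict_proba(X_te[feats]).to_numpy()
                    rows.append({
                        "family": "background", "fraction": frac, "replicate": rep,
                        "seed": split_seed, "n_train": len(train_idx),
                        "n_test": len(test_idx), "roc_auc": M.roc_auc(p, y_te),
                        "pr_auc": M.pr_auc(p, y_te), "n_features": len(feats),
                    })
    return EvaluationResult(pd.DataFrame(rows))


def bootstrap_evaluate(X: pd.DataFrame, y: np.ndarray,
                       families: tuple[str, ...] = ("XGB", "GBM", "RF"),
                       B: int = 1000, train_frac: float = 0.9,
                       seed: int = 0, permute_labels: bool = False
                       ) -> EvaluationResult:
    """B stratified train/test resamples; per-replicate metrics plus a summary
    with medians and 5-95% intervals.  ``permute_labels`` turns every
    replicate into a background (null) model."""
    y = np.asarray(y).astype(int)
    rows = []
    for b in range(B):
        rep_seed = _derive_seed(seed, f"boot:{b}")
        try:
            train_idx, test_idx = _stratified_split(y, train_frac, rep_seed)
        except ValueError as exc:
            warnings.warn(f"bootstrap replicate {b}: split failed ({exc})")
            continue
        if not (_split_ok(y, train_idx) and _split_ok(y, test_idx)):
            warnings.warn(f"bootstrap replicate {b}: degenerate split; skipped")
            continue
        y_tr = y[train_idx]
        if permute_labels:
            y_tr = np.random.default_rng(rep_seed).permutation(y_tr)
            if len(np.unique(y_tr)) < 2:
                continue
        for fam in families:
            model = M.fit(M.ModelSpec(fam, seed=rep_seed),
                          X.iloc[train_idx], y_tr, tune=False)
            p = model.predict_proba(X.iloc[test_idx]).to_numpy()
            rows.append({
                "family": fam, "replicate": b, "seed": rep_seed,
                "n_train": len(train_idx), "n_test": len(test_idx),
                "roc_auc": M.roc_auc(p, y[test_idx]),
                "pr_auc": M.pr_auc(p, y[test_idx]),
                "n_features": X.shape[1],
            })
    df = pd.DataFrame(rows)
    summary = None
    if len(df):
        summary = df.groupby("family").agg(
            roc_auc_median=("roc_auc", "median"),
            roc_auc_q05=("roc_auc", lambda v: v.quantile(0.05)),
            roc_auc_q95=("roc_auc", lambda v: v.quantile(0.95)),
            pr_auc_median=("pr_auc", "median"),
            pr_auc_q05=("pr_auc", lambda v: v.quantile(0.05)),
            pr_auc_q95=("pr_auc", lambda v: v.quantile(0.95)),
            n=("replicate", "count"),
        ).reset_index()
    return EvaluationResult(df, summary)


_ALIGNER = Align.PairwiseAligner(mode="global", match_score=1,
                                 mismatch_score=-1, open_gap_score=-2,
                                 extend_gap_score=-2)


def pairwise_identity(a: str, b: str) -> float:
    """Matches / alignment length of the optimal global alignment
    (match +1, mismatch -1, gap -2)."""
    if not a or not b:
        raise CrossessError("cannot align an empty sequence")
    aln = _ALIGNER.align(a, b)[0]
    return aln.counts().identities / aln.length


def nonredundant_filter(proteins: dict[str, str],
                        identity_threshold: float = 0.25) -> list[str]:
    """Greedy centroid clustering; returns the retained (centroid) gene ids.

    Sequences are processed in descending length (ties broken by id); each
    joins the first existing centroid whose pairwise identity exceeds the
    threshold, otherwise it founds a new cluster.
    """
    order = sorted(proteins, key=lambda g: (-len(proteins[g]), g))
    centroids: list[str] = []
    for gid in order:
        seq = proteins[gid]
        for c in centroids:
            if pairwise_identity(seq, proteins[c]) > identity_threshold:
                break
        else:
            centroids.append(gid)
    return centroids
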