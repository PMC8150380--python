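"""Cross-species prediction and ranked-list validation.

A classifier trained on all labeled genes of the source species scores every
gene of the target species over the harmonized consensus features.  The
ranked list is validated against an independent lethal-phenotype database by
the cumulative lethal ratio: walking the ranking from the top (and,
symmetrically, from the bottom), the running fraction of database-covered
genes annotated lethal.  A ranking that captures essentiality starts near
the database's lethal rate for true essentials and decays to the overall
prevalence; the bottom-up curve does the opposite, and both directions meet
at the overall prevalence at k = N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from . import models as M
from .errors import CrossessError
from .harmonize import LabelSet
from .io import FeatureTable

TOP_DOWN = "top_down"
BOTTOM_UP = "bottom_up"


@dataclass
class RankedPrediction:
    """Target-species genes ordered by predicted essentiality probability."""

    target_species: str
    table: pd.DataFrame  # columns: gene_id, probability, rank (1 = most likely)
    train_species: str = ""
    model_family: str = ""

    def __post_init__(self) -> None:
        t = self.table
        if list(t["rank"]) != list(range(1, len(t) + 1)):
            raise CrossessError("ranks must be 1..N in order")
        if (np.diff(t["probability"].to_numpy()) > 1e-12).any():
            raise CrossessError("probabilities must be non-increasing with rank")


@dataclass
class ValidationCurve:
    direction: str
    table: pd.DataFrame  # columns: k, gene_id, covered, covered_cum, lethal_cum, ratio

    @property
    def final_ratio(self) -> float:
        return float(self.table["ratio"].iloc[-1])


def rank_predictions(probs: pd.Series, target_species: str, *,
                     train_species: str = "", model_family: str = ""
                     ) -> RankedPrediction:
    """Stable descending sort, ties broken by gene id (reproducible output)."""
    df = pd.DataFrame({"gene_id": probs.index.astype(str),
                       "probability": probs.to_numpy(dtype=float)})
    df = df.sort_values(["probability", "gene_id"],
                        ascending=[False, True], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return RankedPrediction(target_species, df, train_species, model_family)


def cross_predict(train_table: FeatureTable, train_labels: LabelSet,
                  consensus_features: list[str], model_spec: M.ModelSpec,
                  target_table: FeatureTable, tune: bool = True
                  ) -> tuple[RankedPrediction, M.TrainedModel]:
    """Fit on ALL labeled source genes; score and rank every target gene."""
    feats = list(consensus_features)
    X_train = train_table.restrict(feats).data
    X_target = target_table.restrict(feats).data
    y = train_labels.binary()
    labeled = [g for g in train_labels.labeled_genes() if g in X_train.index]
    if not labeled:
        raise CrossessError("no labeled genes present in the training table")
    model = M.fit(model_spec, X_train.loc[labeled], y.loc[labeled].to_numpy(),
                  tune=tune)
    probs = model.predict_proba(X_target)
    ranked = rank_predictions(probs, target_table.species,
                              train_species=train_table.species,
                              model_family=model_spec.family)
    return ranked, model


def spearman(ranking_a: pd.Series, ranking_b: pd.Series) -> float:
    """Tie-aware Spearman rho over the genes shared by both score maps."""
    shared = ranking_a.index.intersection(ranking_b.index)
    if len(shared) < 3:
        raise CrossessError(f"only {len(shared)} shared genes; need >= 3")
    rho = scipy.stats.spearmanr(ranking_a.loc[shared], ranking_b.loc[shared]).statistic
    return float(rho)


def cumulative_lethal_ratio(ranked: RankedPrediction, phenodb: pd.DataFrame,
                            direction: str = TOP_DOWN) -> ValidationCurve:
    """Running lethal fraction among database-covered genes along the ranking.

    ``phenodb`` has columns gene_id and lethal.  Genes absent from the
    database are skipped in both numerator and denominator (their coverage is
    reported in the ``covered`` column); prefixes with zero covered genes
    carry a missing ratio.
    """
    if direction not in (TOP_DOWN, BOTTOM_UP):
        raise CrossessError(f"direction must be {TOP_DOWN!r} or {BOTTOM_UP!r}")
    if len(phenodb) == 0:
        raise CrossessError("phenotype database is empty")
    lethal_map = dict(zip(phenodb["gene_id"].astype(str), phenodb["lethal"].astype(bool)))
    genes = list(ranked.table["gene_id"])
    if direction == BOTTOM_UP:
        genes = genes[::-1]
    covered = np.array([g in lethal_map for g in genes])
    lethal = np.array([bool(lethal_map.get(g, False)) for g in genes])
    covered_cum = np.cumsum(covered)
    lethal_cum = np.cumsum(lethal & covered)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(covered_cum > 0, lethal_cum / np.maximum(covered_cum, 1), np.nan)
    table = pd.DataFrame({
        "k": np.arange(1, len(genes) + 1),
        "gene_id": genes,
        "covered": covered,
        "covered_cum": covered_cum,
        "lethal_cum": lethal_cum,
        "ratio": ratio,
    })
    return ValidationCurve(direction, table)
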