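"""Make two species' feature tables comparable and assign training labels.

Features are matched by name across species, z-scored *within* each species
(no pooled scaling), and genes are labelled from reference essentiality
probabilities with fixed thresholds: essential above ``hi`` (default 0.7),
non-essential below ``lo`` (default 0.1), everything between left unlabeled —
excluded from training but scored at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CrossessError
from .io import FeatureTable

logger = logging.getLogger(__name__)

ESSENTIAL = "essential"
NON_ESSENTIAL = "non_essential"
UNLABELED = "unlabeled"


@dataclass
class LabelSet:
    """Per-gene class assignment with the thresholds that produced it."""

    labels: pd.Series  # gene_id -> {essential, non_essential, unlabeled}
    hi: float
    lo: float

    @property
    def counts(self) -> dict[str, int]:
        c = self.labels.value_counts()
        return {k: int(c.get(k, 0)) for k in (ESSENTIAL, NON_ESSENTIAL, UNLABELED)}

    def labeled_genes(self) -> pd.Index:
        return self.labels.index[self.labels != UNLABELED]

    def binary(self) -> pd.Series:
        """0/1 encoding over labeled genes only (essential = 1)."""
        lab = self.labels[self.labels != UNLABELED]
        return (lab == ESSENTIAL).astype(int)


@dataclass
class HarmonizedPair:
    """Two tables restricted to the shared features, each z-scored within species."""

    table_a: FeatureTable
    table_b: FeatureTable
    shared_features: list[str]
    scaling: dict[str, pd.DataFrame] = field(default_factory=dict)  # species -> (mean, sd)


def assign_labels(ref_probs: pd.Series, hi: float = 0.7, lo: float = 0.1) -> LabelSet:
    """Threshold reference probabilities into essential / non-essential / unlabeled."""
    if hi <= lo:
        raise CrossessError(f"hi={hi} must exceed lo={lo}")
    probs = pd.Series(ref_probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any() or probs.isna().any():
        raise CrossessError("reference probabilities must lie in [0, 1]")
    labels = pd.Series(UNLABELED, index=probs.index, dtype=object)
    labels[probs > hi] = ESSENTIAL
    labels[probs < lo] = NON_ESSENTIAL
    return LabelSet(labels, hi, lo)


def intersect_features(table_a: FeatureTable, table_b: FeatureTable
                       ) -> tuple[FeatureTable, FeatureTable]:
    """Restrict both tables to the name-intersection, identical column order."""
    shared = [f for f in table_a.feature_names if f in set(table_b.feature_names)]
    if not shared:
        raise CrossessError(
            f"no shared features between {table_a.species} and {table_b.species}"
        )
    return table_a.restrict(shared), table_b.restrict(shared)


def standardize(table: FeatureTable, drop_constant: bool = True
                ) -> tuple[FeatureTable, pd.DataFrame]:
    """Z-score every feature within the species; constant features dropped.

    Returns the transformed table and a (mean, sd) frame for the retained
    features.  Idempotent up to floating error.
    """
    if len(table.data) < 2:
        raise CrossessError("standardization needs at least 2 genes")
    mean = table.data.mean()
    sd = table.data.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant and drop_constant:
        logger.info("standardize(%s): dropping %d constant features",
                    table.species, len(constant))
    keep = [f for f in table.feature_names if f not in constant]
    if not keep:
        raise CrossessError(f"all features constant in {table.species}")
    z = (table.data[keep] - mean[keep]) / sd[keep]
    params = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    out = FeatureTable(table.species, z, {f: table.provenance.get(f, "unknown")
                                          for f in keep})
    return out, params


def harmonize_pair(table_a: FeatureTable, table_b: FeatureTable) -> HarmonizedPair:
    """Shared features, constant-in-either features dropped from both, then
    per-species z-scoring.  Symmetric in its two arguments."""
    a, b = intersect_features(table_a, table_b)
    const = set()
    for t in (a, b):
        sd = t.data.std(ddof=0)
        const |= set(sd[sd == 0].index)
    keep = [f for f in a.feature_names if f not in const]
    if not keep:
        raise CrossessError("no non-constant shared features")
    if const:
        logger.info("harmonize_pair: dropped %d features constant in at least "
                    "one species", len(const))
    a_std, pa = standardize(a.restrict(keep))
    b_std, pb = standardize(b.restrict(keep))
    return HarmonizedPair(a_std, b_std, keep,
                          {a.species: pa, b.species: pb})
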