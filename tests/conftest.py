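import warnings

import numpy as np
import pytest

from crossess import harmonize as H
from crossess import synthetic as SYN

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


SMALL_CONFIG = dict(n_genes_a=400, n_genes_b=400, n_shared_features=30,
                    n_private_features_per_species=4, n_informative=6,
                    n_chromosomes=3, chrom_length_bp=2_000_000)


@pytest.fixture(scope="session")
def small_world():
    """A quick world for unit tests (400 genes, 30 shared features)."""
    return SYN.generate_world(SYN.GeneratorConfig(seed=11, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def default_world():
    """The standard study conditions (3000 genes/species, 20 of 120 informative)."""
    return SYN.generate_world(SYN.GeneratorConfig(seed=1))


def labeled_xy(world, species="A"):
    """Harmonized standardized features and 0/1 labels for labeled genes."""
    pair = H.harmonize_pair(world.species["A"].features, world.species["B"].features)
    table = {"A": pair.table_a, "B": pair.table_b}[species]
    labels = H.assign_labels(world.species[species].ref_probs)
    genes = list(labels.labeled_genes())
    return table.data.loc[genes], labels.binary().loc[genes].to_numpy(), pair, labels


@pytest.fixture(scope="session")
def default_world_xy(default_world):
    return labeled_xy(default_world, "A")


def rng(seed=0):
    return np.random.default_rng(seed)
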