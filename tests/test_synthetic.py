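import numpy as np
import pandas as pd
import pytest

from conftest import SMALL_CONFIG
from crossess import models as M
from crossess import synthetic as SYN
from crossess.errors import ConfigError
from crossess.harmonize import assign_labels
from crossess.synthetic import GeneratorConfig, generate_phenotype_db, generate_world


def test_same_seed_is_bit_identical(tmp_path):
    cfg = GeneratorConfig(seed=7, **SMALL_CONFIG)
    w1, w2 = generate_world(cfg), generate_world(cfg)
    for sp in ("A", "B"):
        pd.testing.assert_frame_equal(w1.species[sp].features.data,
                                      w2.species[sp].features.data)
        assert w1.species[sp].proteins == w2.species[sp].proteins
        pd.testing.assert_frame_equal(w1.species[sp].phenotypes,
                                      w2.species[sp].phenotypes)
    d1 = SYN.write_world(w1, tmp_path / "one")
    d2 = SYN.write_world(w2, tmp_path / "two")
    for f in sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f


def test_prevalence_band_is_exact():
    """The rescaling pins the >0.7 band to the configured prevalence."""
    cfg = GeneratorConfig(n_genes_a=2000, n_genes_b=200, n_informative=20,
                          effect_size=1.0, noise_sd=0.5,
                          essential_prevalence=0.04, seed=1)
    w = generate_world(cfg)
    n_hi = int((w.species["A"].ref_probs > 0.7).sum())
    assert abs(n_hi - round(2000 * 0.04)) <= 1
    assert (w.species["A"].truth_essential.sum() == n_hi)
    # the bottom band sits below 0.1
    n_lo = int((w.species["A"].ref_probs < 0.1).sum())
    assert n_lo == 2000 - n_hi - round(2000 * cfg.unlabeled_fraction)


def test_zero_effect_size_gives_no_signal():
    cfg = GeneratorConfig(seed=3, effect_size=0.0, **SMALL_CONFIG)
    w = generate_world(cfg)
    ds = w.species["A"]
    labels = assign_labels(ds.ref_probs)
    genes = list(labels.labeled_genes())
    X = ds.features.data.loc[genes]
    y = labels.binary().loc[genes].to_numpy()
    rng = np.random.default_rng(0)
    train = rng.random(len(y)) < 0.5
    if y[train].sum() == 0 or y[~train].sum() == 0:  # pragma: no cover
        train[:] = np.arange(len(y)) % 2 == 0
    model = M.fit(M.ModelSpec("GLM", seed=0), X[train], y[train], tune=False)
    auc = M.roc_auc(model.predict_proba(X[~train]).to_numpy(), y[~train])
    assert 0.3 < auc < 0.7


def test_heterochromatin_depletion_extremes():
    base = dict(SMALL_CONFIG)
    w0 = generate_world(GeneratorConfig(seed=5, het_depletion=0.0, **base))
    ds = w0.species["A"]
    het = {a.chromosome: [b for b in ds.heterochromatin if b.chromosome == a.chromosome]
           for a in ds.annotations}
    ess = set(ds.truth_essential.index[ds.truth_essential])
    inside = [a.gene_id for a in ds.annotations
              if a.gene_id in ess and any(b.start < a.midpoint <= b.end
                                          for b in het[a.chromosome])]
    assert inside == []

    w1 = generate_world(GeneratorConfig(seed=5, het_depletion=1.0, **base))
    ds = w1.species["A"]
    ess = set(ds.truth_essential.index[ds.truth_essential])
    n_inside = sum(
        1 for a in ds.annotations if a.gene_id in ess
        and any(b.start < a.midpoint <= b.end for b in ds.heterochromatin
                if b.chromosome == a.chromosome))
    n_ess = len(ess)
    # unbiased placement: inside fraction ~ het_fraction (0.2), binomial noise
    se = np.sqrt(0.2 * 0.8 / n_ess)
    assert abs(n_inside / n_ess - 0.2) < 5 * se


def test_phenotype_db_degenerate_settings():
    cfg = GeneratorConfig(seed=9, phen_coverage=1.0, p_lethal_given_essential=1.0,
                          p_lethal_given_nonessential=0.0, **SMALL_CONFIG)
    w = generate_world(cfg)
    db = w.species["A"].phenotypes
    lethal = set(db.loc[db.lethal, "gene_id"])
    truth = set(w.species["A"].truth_essential.index[w.species["A"].truth_essential])
    assert lethal == truth

    cfg0 = GeneratorConfig(seed=9, phen_coverage=0.0, **SMALL_CONFIG)
    w0 = generate_world(cfg0)
    assert len(w0.species["A"].phenotypes) == 0


def test_phenotype_db_mixture_prevalence():
    """Lethal prevalence among covered genes matches the closed-form mixture."""
    cfg = GeneratorConfig(seed=13, phen_coverage=0.6, p_lethal_given_essential=0.9,
                          p_lethal_given_nonessential=0.05)
    w = generate_world(cfg)
    db = generate_phenotype_db(w, "A")
    prev = cfg.essential_prevalence
    expected = prev * 0.9 + (1 - prev) * 0.05
    observed = db.lethal.mean()
    se = np.sqrt(expected * (1 - expected) / len(db))
    assert abs(observed - expected) < 4 * se


def test_world_invariants(small_world):
    w = small_world
    assert set(w.informative_features) <= set(w.shared_features)
    for ds in w.species.values():
        ann_ids = {a.gene_id for a in ds.annotations}
        assert ann_ids == set(ds.features.data.index)
        for a in ds.annotations:
            assert 1 <= a.start <= a.end <= ds.chrom_lengths[a.chromosome]


def test_config_validation():
    with pytest.raises(ConfigError, match="n_informative"):
        GeneratorConfig(n_informative=50, n_shared_features=20)
    with pytest.raises(ConfigError, match="p_lethal_given_essential"):
        GeneratorConfig(p_lethal_given_essential=0.1, p_lethal_given_nonessential=0.5)
    with pytest.raises(ConfigError, match="outside"):
        GeneratorConfig(het_fraction=1.5)
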