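"""Twin-species synthetic data generator.

Builds a pair of species datasets with planted cross-species signal so the
whole pipeline — harmonization, consensus feature selection, within-species
evaluation, transfer prediction and ranked-list validation — can be exercised
end to end without any external download.

The generative model
--------------------
Each species has a genes x features table.  A configurable subset of the
*shared* features is informative: a per-gene latent essentiality score is

    z = X_informative . (c + jitter_species) + Normal(0, noise_sd)

where ``c`` are shared coefficients of magnitude ``effect_size`` with random
sign and each species perturbs them with an independent relative jitter,
``c * (1 + Normal(0, coef_jitter_sd))``, so a null shared effect stays null
in both species.  Jittering (rather than resampling) the coefficients
makes cross-species transfer learnable by construction; increasing the jitter
dials the transferable signal down to nothing.  All remaining features are
independent standard-normal noise.

Reference essentiality probabilities are logistic(z), then monotonically
rescaled (piecewise-affine within rank bands) so that exactly the top
``essential_prevalence`` fraction of genes exceeds 0.7 and the bottom
(1 - prevalence - unlabeled_fraction) falls below 0.1 — the label thresholds
downstream are fixed, so the generator guarantees non-empty classes.  The
true essential flag is the top ``essential_prevalence`` fraction by latent
score, hence coincides with the >0.7 band.

Genome layout: genes are placed uniformly on ``n_chromosomes`` chromosomes;
each chromosome carries terminal heterochromatin blocks covering
``het_fraction`` of its length, and essential genes landing inside
heterochromatin are re-drawn outside with probability ``1 - het_depletion``
(so ``het_depletion=0`` empties heterochromatin of essential genes and
``het_depletion=1`` leaves placement unbiased).

Proteins are random sequences over the 20 canonical residues, with a
configurable fraction of near-duplicate pairs (~90% identity) to exercise the
>25%-identity redundancy filter.  The phenotype database covers each gene
with probability ``phen_coverage`` and assigns a lethal flag from
class-conditional Bernoulli rates — a noisy, incomplete stand-in for an
independent functional-genomics database.

Everything is reproducible bit-for-bit from ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError
from .io import (FeatureTable, GeneAnnotation, Interval, write_bed,
                 write_fasta, write_gff3, write_feature_table)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: thresholds the reference probabilities are rescaled around; these mirror
#: the fixed label cut-offs used downstream (essential > 0.7, non-essential < 0.1)
PROB_HI = 0.7
PROB_LO = 0.1


@dataclass
class GeneratorConfig:
    """All knobs of the twin-species generator; defaults are the package's
    standard study conditions (see docs/methods.md for the rationale)."""

    n_genes_a: int = 3000
    n_genes_b: int = 3000
    n_shared_features: int = 120
    n_private_features_per_species: int = 15
    n_informative: int = 20
    effect_size: float = 1.0
    coef_jitter_sd: float = 0.3
    noise_sd: float = 0.5
    essential_prevalence: float = 0.04
    unlabeled_fraction: float = 0.11
    n_chromosomes: int = 5
    chrom_length_bp: int = 20_000_000
    het_fraction: float = 0.2
    het_depletion: float = 0.2
    phen_coverage: float = 0.6
    p_lethal_given_essential: float = 0.9
    p_lethal_given_nonessential: float = 0.02
    protein_length_range: tuple[int, int] = (80, 160)
    near_duplicate_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "essential_prevalence": self.essential_prevalence,
            "unlabeled_fraction": self.unlabeled_fraction,
            "het_fraction": self.het_fraction,
            "het_depletion": self.het_depletion,
            "phen_coverage": self.phen_coverage,
            "p_lethal_given_essential": self.p_lethal_given_essential,
            "p_lethal_given_nonessential": self.p_lethal_given_nonessential,
            "near_duplicate_fraction": self.near_duplicate_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if not 0.0 < self.essential_prevalence < 1.0:
            raise ConfigError("essential_prevalence must lie strictly in (0, 1)")
        if self.essential_prevalence + self.unlabeled_fraction >= 1.0:
            raise ConfigError("essential_prevalence + unlabeled_fraction must be < 1")
        if self.n_informative > self.n_shared_features:
            raise ConfigError(
                f"n_informative={self.n_informative} exceeds "
                f"n_shared_features={self.n_shared_features}"
            )
        if self.p_lethal_given_essential <= self.p_lethal_given_nonessential:
            raise ConfigError(
                "p_lethal_given_essential must exceed p_lethal_given_nonessential"
            )
        if min(self.n_genes_a, self.n_genes_b) < 10:
            raise ConfigError("need at least 10 genes per species")


@dataclass
class SpeciesDataset:
    """One species' worth of synthetic inputs plus its ground truth."""

    name: str
    features: FeatureTable
    ref_probs: pd.Series              # gene_id -> reference essentiality probability
    annotations: list[GeneAnnotation]
    proteins: dict[str, str]
    heterochromatin: list[Interval]
    phenotypes: pd.DataFrame          # columns: gene_id, lethal (bool)
    truth_essential: pd.Series        # gene_id -> bool
    coefficients: pd.Series           # informative feature -> species coefficient
    chrom_lengths: dict[str, int]


@dataclass
class SyntheticWorld:
    config: GeneratorConfig
    species: dict[str, SpeciesDataset]
    shared_features: list[str]
    informative_features: list[str]
    shared_coefficients: pd.Series = field(repr=False, default=None)


def _rescale_probabilities(latent: np.ndarray, prevalence: float,
                           unlabeled_fraction: float) -> np.ndarray:
    """Monotone map latent -> probability honouring the 0.7/0.1 bands.

    logistic(latent) is rescaled piecewise-affinely within three rank bands so
    that exactly round(n * prevalence) genes land above PROB_HI and all genes
    below the unlabeled band land below PROB_LO; ordering is preserved.
    """
    n = latent.size
    n_hi = int(round(n * prevalence))
    n_mid = int(round(n * unlabeled_fraction))
    n_lo = n - n_hi - n_mid
    order = np.argsort(latent, kind="stable")
    raw = expit(latent)
    out = np.empty(n)
    bands = [
        (order[:n_lo], 0.001, PROB_LO - 0.001),
        (order[n_lo:n_lo + n_mid], PROB_LO + 0.001, PROB_HI - 0.001),
        (order[n_lo + n_mid:], PROB_HI + 0.001, 0.999),
    ]
    for idx, lo, hi in bands:
        if idx.size == 0:
            continue
        vals = raw[idx]
        span = vals.max() - vals.min()
        if span < 1e-12:
            out[idx] = np.linspace(lo, hi, idx.size)
        else:
            out[idx] = lo + (vals - vals.min()) / span * (hi - lo)
    return out


def _heterochromatin_blocks(chrom: str, length: int, het_fraction: float) -> list[Interval]:
    # two terminal blocks, mimicking telomeric/pericentric heterochromatin
    if het_fraction <= 0:
        return []
    block = int(length * het_fraction / 2)
    if block == 0:
        return []
    return [Interval(chrom, 0, block), Interval(chrom, length - block, length)]


def _inside_any(pos: float, blocks: list[Interval]) -> bool:
    # pos is a 1-based coordinate; blocks are BED half-open
    return any(b.start < pos <= b.end for b in blocks)


def _random_protein(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float = 0.1) -> str:
    chars = np.array(list(seq))
    mask = rng.random(chars.size) < rate
    chars[mask] = rng.choice(AMINO_ACIDS, size=int(mask.sum()))
    return "".join(chars)


def _generate_species(name: str, n_genes: int, cfg: GeneratorConfig,
                      shared_names: list[str], informative: list[str],
                      base_coefs: np.ndarray,
                      rng: np.random.Generator) -> SpeciesDataset:
    gene_ids = [f"{name}_g{i:05d}" for i in range(n_genes)]
    private_names = [f"{name}_priv_{j:03d}" for j in range(cfg.n_private_features_per_species)]
    all_names = shared_names + private_names

    X = rng.standard_normal((n_genes, len(all_names)))
    inf_idx = [shared_names.index(f) for f in informative]
    # jitter is proportional to the shared effect: a null effect stays null
    # in both species, and at |coef| = effect_size the perturbation has sd
    # coef_jitter_sd * effect_size exactly as an additive jitter would
    coefs = base_coefs * (1.0 + rng.normal(0.0, cfg.coef_jitter_sd,
                                           size=base_coefs.size))
    latent = X[:, inf_idx] @ coefs + rng.normal(0.0, cfg.noise_sd, size=n_genes)

    probs = _rescale_probabilities(latent, cfg.essential_prevalence, cfg.unlabeled_fraction)
    n_ess = int(round(n_genes * cfg.essential_prevalence))
    essential = np.zeros(n_genes, dtype=bool)
    essential[np.argsort(latent, kind="stable")[n_genes - n_ess:]] = True

    # genome layout: uniform placement, essential genes depleted in heterochromatin
    chrom_names = [f"chr{k + 1}" for k in range(cfg.n_chromosomes)]
    chrom_lengths = {c: cfg.chrom_length_bp for c in chrom_names}
    het: list[Interval] = []
    for c in chrom_names:
        het.extend(_heterochromatin_blocks(c, cfg.chrom_length_bp, cfg.het_fraction))
    het_by_chrom = {c: [b for b in het if b.chromosome == c] for c in chrom_names}

    annotations: list[GeneAnnotation] = []
    for i, gid in enumerate(gene_ids):
        chrom = chrom_names[int(rng.integers(cfg.n_chromosomes))]
        glen = int(rng.integers(500, 5001))
        start = int(rng.integers(1, cfg.chrom_length_bp - glen))
        if essential[i] and _inside_any((2 * start + glen) / 2, het_by_chrom[chrom]):
            if rng.random() < (1.0 - cfg.het_depletion):
                # redraw midpoints until outside heterochromatin
                for _ in range(1000):
                    start = int(rng.integers(1, cfg.chrom_length_bp - glen))
                    if not _inside_any((2 * start + glen) / 2, het_by_chrom[chrom]):
                        break
        end = start + glen - 1
        n_exons = int(rng.integers(1, 7))
        cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exons - 1, replace=False)) \
            if glen > 2 * n_exons else np.arange(1, 2 * n_exons)
        bounds = np.concatenate([[0], cuts, [glen]])
        exons = tuple((start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]) - 1)
                      for k in range(n_exons))
        strand = "+" if rng.random() < 0.5 else "-"
        annotations.append(GeneAnnotation(gid, chrom, start, end, strand, exons))

    # proteins: random residues + a fraction of near-duplicate pairs
    proteins: dict[str, str] = {}
    for gid in gene_ids:
        proteins[gid] = _random_protein(rng, cfg.protein_length_range)
    n_dup = int(round(n_genes * cfg.near_duplicate_fraction))
    if n_dup:
        dup_targets = rng.choice(n_genes, size=n_dup, replace=False)
        for t in dup_targets:
            src = int(rng.integers(n_genes))
            if src == t:
                continue
            proteins[gene_ids[t]] = _mutate_protein(rng, proteins[gene_ids[src]])

    features = FeatureTable(
        name,
        pd.DataFrame(X, index=pd.Index(gene_ids, name="gene_id"), columns=all_names),
        {f: "passthrough" for f in all_names},
    )
    return SpeciesDataset(
        name=name,
        features=features,
        ref_probs=pd.Series(probs, index=gene_ids, name="ref_prob"),
        annotations=annotations,
        proteins=proteins,
        heterochromatin=het,
        phenotypes=pd.DataFrame(),  # filled by generate_phenotype_db
        truth_essential=pd.Series(essential, index=gene_ids, name="essential"),
        coefficients=pd.Series(coefs, index=informative),
        chrom_lengths=chrom_lengths,
    )


def generate_world(config: GeneratorConfig) -> SyntheticWorld:
    """Generate the twin-species world; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    shared_names = [f"shared_{i:03d}" for i in range(config.n_shared_features)]
    informative = sorted(rng.choice(shared_names, size=config.n_informative,
                                    replace=False).tolist())
    base_coefs = config.effect_size * rng.choice([-1.0, 1.0], size=config.n_informative)

    species = {
        "A": _generate_species("A", config.n_genes_a, config, shared_names,
                               informative, base_coefs, rng),
        "B": _generate_species("B", config.n_genes_b, config, shared_names,
                               informative, base_coefs, rng),
    }
    world = SyntheticWorld(config, species, shared_names, informative,
                           pd.Series(base_coefs, index=informative))
    for sp in species:
        species[sp].phenotypes = generate_phenotype_db(world, sp)
    return world


def generate_phenotype_db(world: SyntheticWorld, species: str) -> pd.DataFrame:
    """Noisy, incomplete lethal-phenotype database for one species.

    Each gene is covered with probability ``phen_coverage``; covered genes get
    a lethal flag drawn from the class-conditional rates given the gene's true
    essentiality.  Deterministic given the world's seed and the species name.
    """
    cfg = world.config
    ds = world.species[species]
    rng = np.random.default_rng([cfg.seed, 7919, sum(species.encode())])
    covered = rng.random(len(ds.truth_essential)) < cfg.phen_coverage
    p = np.where(ds.truth_essential.to_numpy(),
                 cfg.p_lethal_given_essential, cfg.p_lethal_given_nonessential)
    lethal = rng.random(len(ds.truth_essential)) < p
    db = pd.DataFrame({
        "gene_id": ds.truth_essential.index[covered],
        "lethal": lethal[covered],
    })
    return db.reset_index(drop=True)


def write_world(world: SyntheticWorld, outdir: str | Path) -> Path:
    """Write one directory per species plus a manifest echoing the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, ds in world.species.items():
        d = outdir / f"species_{name}"
        d.mkdir(parents=True, exist_ok=True)
        write_feature_table(ds.features, d / "features.tsv")
        probs = ds.ref_probs.rename_axis("gene_id").reset_index()
        probs.to_csv(d / "ref_probs.tsv", sep="\t", index=False)
        write_gff3(ds.annotations, d / "genes.gff3")
        write_fasta(ds.proteins, d / "proteins.fasta")
        write_bed(ds.heterochromatin, d / "het.bed")
        ds.phenotypes.to_csv(d / "phenotypes.tsv", sep="\t", index=False)
        truth = {
            "essential_genes": ds.truth_essential.index[ds.truth_essential].tolist(),
            "informative_features": world.informative_features,
            "coefficients": {k: float(v) for k, v in ds.coefficients.items()},
            "chrom_lengths": ds.chrom_lengths,
        }
        (d / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    manifest = {
        "config": dataclasses.asdict(world.config),
        "seed": world.config.seed,
        "species": sorted(world.species),
        "shared_features": world.shared_features,
        "informative_features": world.informative_features,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
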