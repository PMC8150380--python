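"""End-to-end orchestration: simulate -> featurize -> harmonize -> select ->
evaluate -> transfer -> validate -> landscape, from a single YAML config.

Every stage draws its seed from the master seed by hashing the stage name,
so adding or re-ordering stages never perturbs the randomness of existing
ones.  A ``manifest.json`` records the config echo, per-stage seeds and
checksums of the key outputs; each stage writes plain TSV/JSON/BED so any
stage can be re-run in isolation from the intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import evaluation as E
from . import features as F
from . import harmonize as H
from . import landscape as L
from . import models as M
from . import selection as S
from . import synthetic as SYN
from . import transfer as T
from .errors import ConfigError, CrossessError
from .io import read_bed, read_fasta, read_feature_table, read_gff3, write_feature_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "featurize", "harmonize", "select", "evaluate",
          "transfer", "validate", "landscape")


def derive_seed(master: int, stage: str) -> int:
    """Stage seed = blake2b(stage:master) reduced below 2^31."""
    h = hashlib.blake2b(f"{stage}:{master}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Everything a full run needs; loadable from YAML."""

    generator: dict = field(default_factory=dict)   # GeneratorConfig overrides
    species_dirs: dict[str, str] | None = None      # pre-existing world layout
    hi: float = 0.7
    lo: float = 0.1
    identity_threshold: float = 0.25
    evalue_cutoff: float = 1e-10
    families: tuple[str, ...] = M.FAMILIES
    grid_fractions: tuple[float, ...] = E.GRID_FRACTIONS
    grid_repeats: int = 5
    bootstrap_B: int = 1000
    bootstrap_families: tuple[str, ...] = ("XGB", "GBM", "RF")
    transfer_model: str = "XGB"
    selection: S.SelectionConfig = field(default_factory=S.SelectionConfig)
    grid_selection: bool = True
    tune: bool = True
    bin_size: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ConfigError(f"need 0 <= lo < hi <= 1, got lo={self.lo} hi={self.hi}")
        if not 0.0 < self.identity_threshold < 1.0:
            raise ConfigError("identity_threshold must lie in (0, 1)")
        if self.evalue_cutoff <= 0:
            raise ConfigError("evalue_cutoff must be positive")
        unknown = set(self.families) | set(self.bootstrap_families) | {self.transfer_model}
        unknown -= set(M.FAMILIES)
        if unknown:
            raise ConfigError(f"unknown model families {sorted(unknown)}")

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        raw = dict(raw)
        sel = raw.pop("selection", None)
        cfg = RunConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                           for k, v in raw.items()})
        if sel:
            cfg.selection = S.SelectionConfig(
                **{k: (tuple(v) if isinstance(v, list) else v) for k, v in sel.items()})
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_world_from_dirs(species_dirs: dict[str, str], seed: int) -> SYN.SyntheticWorld:
    """Reconstruct a world-shaped object from on-disk species directories."""
    species = {}
    shared: set[str] | None = None
    for name, d in species_dirs.items():
        d = Path(d)
        for fname in ("features.tsv", "ref_probs.tsv", "genes.gff3",
                      "proteins.fasta", "phenotypes.tsv"):
            if not (d / fname).exists():
                raise CrossessError(f"species dir {d} lacks {fname}")
        feats = read_feature_table(d / "features.tsv", species=name)
        probs = pd.read_csv(d / "ref_probs.tsv", sep="\t").set_index("gene_id")["ref_prob"]
        ann = read_gff3(d / "genes.gff3")
        proteins = read_fasta(d / "proteins.fasta")
        het = read_bed(d / "het.bed") if (d / "het.bed").exists() else []
        phen = pd.read_csv(d / "phenotypes.tsv", sep="\t")
        truth_path = d / "truth.json"
        chrom_lengths = {}
        truth_ess = pd.Series(False, index=feats.data.index)
        if truth_path.exists():
            truth = json.loads(truth_path.read_text())
            chrom_lengths = {k: int(v) for k, v in truth.get("chrom_lengths", {}).items()}
            ess = set(truth.get("essential_genes", []))
            truth_ess = pd.Series([g in ess for g in feats.data.index],
                                  index=feats.data.index)
        if not chrom_lengths:
            for a in ann:
                chrom_lengths[a.chromosome] = max(chrom_lengths.get(a.chromosome, 0), a.end)
        species[name] = SYN.SpeciesDataset(
            name=name, features=feats, ref_probs=probs, annotations=ann,
            proteins=proteins, heterochromatin=het, phenotypes=phen,
            truth_essential=truth_ess, coefficients=pd.Series(dtype=float),
            chrom_lengths=chrom_lengths)
        names = set(feats.feature_names)
        shared = names if shared is None else (shared & names)
    return SYN.SyntheticWorld(SYN.GeneratorConfig(seed=seed), species,
                              sorted(shared or []), [])


def run_all(config: RunConfig, outdir: str | Path,
            skip_bootstrap: bool = False) -> Path:
    """Execute every stage; returns the run directory.

    A stage failure aborts with the stage named; outputs of completed stages
    are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items()
               if k != "selection"},
            "selection": dataclasses.asdict(config.selection),
        },
        "stage_seeds": {s: derive_seed(config.seed, s) for s in STAGES},
        "checksums": {},
    }
    stage = "simulate"
    try:
        # ---- simulate / load --------------------------------------------
        if config.species_dirs:
            world = _load_world_from_dirs(config.species_dirs, config.seed)
        else:
            gen_cfg = SYN.GeneratorConfig(**{
                **config.generator, "seed": config.generator.get(
                    "seed", derive_seed(config.seed, "simulate"))})
            world = SYN.generate_world(gen_cfg)
            SYN.write_world(world, outdir / "world")
        sp_names = sorted(world.species)
        if len(sp_names) != 2:
            raise CrossessError(f"need exactly 2 species, got {sp_names}")
        a_name, b_name = sp_names

        # ---- featurize ---------------------------------------------------
        stage = "featurize"
        full = {}
        feat_dir = outdir / "features"
        feat_dir.mkdir(exist_ok=True)
        for name in sp_names:
            ds = world.species[name]
            full[name] = F.build_feature_table(
                name, ds.annotations, ds.chrom_lengths, proteins=ds.proteins,
                passthrough=ds.features)
            write_feature_table(full[name], feat_dir / f"{name}_full.tsv")

        # ---- harmonize ---------------------------------------------------
        stage = "harmonize"
        pair = H.harmonize_pair(full[a_name], full[b_name])
        harm_dir = outdir / "harmonized"
        harm_dir.mkdir(exist_ok=True)
        harm = {a_name: pair.table_a, b_name: pair.table_b}
        labels: dict[str, H.LabelSet] = {}
        for name in sp_names:
            write_feature_table(harm[name], harm_dir / f"{name}.tsv")
            labels[name] = H.assign_labels(world.species[name].ref_probs,
                                           hi=config.hi, lo=config.lo)
            lab_df = labels[name].labels.rename("label").rename_axis("gene_id").reset_index()
            lab_df.to_csv(harm_dir / f"labels_{name}.tsv", sep="\t", index=False)

        # ---- select ------------------------------------------------------
        stage = "select"
        sel_dir = outdir / "selection"
        sel_dir.mkdir(exist_ok=True)
        sel_seed = derive_seed(config.seed, "select")
        consensus: dict[str, set[str]] = {}
        for name in sp_names:
            lab = labels[name]
            genes = [g for g in lab.labeled_genes() if g in harm[name].data.index]
            Xl = harm[name].data.loc[genes]
            yl = lab.binary().loc[genes].to_numpy()
            res = S.select_features(Xl, yl, config.selection, seed=sel_seed)
            consensus[name] = res.consensus_set
            (sel_dir / f"{name}.json").write_text(json.dumps({
                "elasticnet": sorted(res.elasticnet_set),
                "spls": sorted(res.spls_set),
                "consensus": sorted(res.consensus_set),
                "spls_frequencies": {k: float(v)
                                     for k, v in res.spls_frequencies.items()},
            }, indent=1, sort_keys=True))
        transfer_features = sorted(consensus[a_name] & consensus[b_name])
        if not transfer_features:
            logger.warning("cross-species consensus empty; falling back to the "
                           "union of per-species consensus sets")
            transfer_features = sorted(consensus[a_name] | consensus[b_name])
        if not transfer_features:
            transfer_features = list(pair.shared_features)
        (sel_dir / "transfer_features.json").write_text(
            json.dumps(transfer_features, indent=1))

        # ---- evaluate ----------------------------------------------------
        stage = "evaluate"
        eval_dir = outdir / "evaluation"
        eval_dir.mkdir(exist_ok=True)
        for name in sp_names:
            lab = labels[name]
            genes = [g for g in lab.labeled_genes() if g in harm[name].data.index]
            Xl = harm[name].data.loc[genes]
            yl = lab.binary().loc[genes].to_numpy()
            grid = E.subsample_grid(
                Xl, yl, families=config.families,
                fractions=config.grid_fractions, repeats=config.grid_repeats,
                selection=config.selection if config.grid_selection else None,
                seed=derive_seed(config.seed, f"evaluate:grid:{name}"),
                tune=config.tune)
            grid.rows.to_csv(eval_dir / f"grid_{name}.tsv", sep="\t", index=False)
            if not skip_bootstrap:
                feats = transfer_features if transfer_features else list(Xl.columns)
                boot = E.bootstrap_evaluate(
                    Xl[feats], yl, families=config.bootstrap_families,
                    B=config.bootstrap_B,
                    seed=derive_seed(config.seed, f"evaluate:boot:{name}"))
                boot.rows.to_csv(eval_dir / f"bootstrap_{name}.tsv", sep="\t", index=False)
                if boot.summary is not None:
                    boot.summary.to_csv(eval_dir / f"bootstrap_summary_{name}.tsv",
                                        sep="\t", index=False)

        # ---- transfer ----------------------------------------------------
        stage = "transfer"
        tr_dir = outdir / "transfer"
        tr_dir.mkdir(exist_ok=True)
        ranked: dict[str, T.RankedPrediction] = {}
        for train, target in ((a_name, b_name), (b_name, a_name)):
            spec = M.ModelSpec(config.transfer_model,
                               seed=derive_seed(config.seed, f"transfer:{train}"))
            rk, _ = T.cross_predict(harm[train], labels[train], transfer_features,
                                    spec, harm[target], tune=config.tune)
            ranked[target] = rk
            rk.table.to_csv(tr_dir / f"ranked_{target}_from_{train}.tsv",
                            sep="\t", index=False)

        # ---- validate ----------------------------------------------------
        stage = "validate"
        val_dir = outdir / "validation"
        val_dir.mkdir(exist_ok=True)
        for target, rk in ranked.items():
            phen = world.species[target].phenotypes
            frames = []
            for direction in (T.TOP_DOWN, T.BOTTOM_UP):
                curve = T.cumulative_lethal_ratio(rk, phen, direction)
                df = curve.table.copy()
                df.insert(0, "direction", direction)
                frames.append(df)
            pd.concat(frames).to_csv(val_dir / f"curves_{target}.tsv",
                                     sep="\t", index=False)

        # ---- landscape ---------------------------------------------------
        stage = "landscape"
        land_dir = outdir / "landscape"
        land_dir.mkdir(exist_ok=True)
        het_summaries = {}
        for target, rk in ranked.items():
            ds = world.species[target]
            tracks, bedgraph = L.probability_track(
                rk, ds.annotations, ds.chrom_lengths,
                het_intervals=ds.heterochromatin, bin_size=config.bin_size)
            L.write_bedgraph(bedgraph, land_dir / f"{target}.bedgraph")
            het_summaries[target] = L.heterochromatin_summary(tracks)
        (land_dir / "het_summary.json").write_text(
            json.dumps(het_summaries, indent=1, sort_keys=True))
    except CrossessError as exc:
        raise CrossessError(f"stage {stage!r} failed: {exc}") from exc

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["checksums"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
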