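"""Per-gene feature computation from standard inputs.

The recomputable features: nucleotide/protein composition and
autocorrelation descriptors, exon counts and total exonic length, distance
of the gene midpoint from the chromosome centre, ChIP peak overlap counts,
PPI network centralities, ortholog-group sizes and EST-alignment hit counts.
Everything else (scRNA-seq, Ribo-seq, SNP-derived columns, ...) enters as
passthrough columns of a precomputed table.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CrossessError
from .io import FeatureTable, GeneAnnotation, Interval

logger = logging.getLogger(__name__)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydrophobicity, the default residue property scale for
#: autocorrelation descriptors
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class FeatureSpec:
    """Names a computed feature and where it comes from."""

    name: str
    source: str  # sequence | annotation | peaks | graph | orthologs | est_hits | passthrough
    parameters: dict = field(default_factory=dict)


def gc_content(dna_sequence: str) -> float:
    """(G+C) / (A+C+G+T); N (and other ambiguity codes) excluded from both sides."""
    seq = dna_sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise CrossessError("gc_content undefined: no unambiguous bases in sequence")
    return (counts["G"] + counts["C"]) / denom


def aa_composition(protein_sequence: str) -> dict[str, float]:
    """Fractions of the 20 canonical residues, keys ``AAC_A`` ... ``AAC_Y``.

    Non-canonical residues are ignored (logged); fractions sum to 1 over the
    residues counted.
    """
    seq = protein_sequence.upper()
    kept = [c for c in seq if c in CANONICAL_AA]
    if not kept:
        raise CrossessError("aa_composition undefined: empty protein sequence")
    n_dropped = len(seq) - len(kept)
    if n_dropped:
        logger.info("aa_composition: ignored %d non-canonical residues", n_dropped)
    n = len(kept)
    return {f"AAC_{a}": kept.count(a) / n for a in CANONICAL_AA}


def _standardized_scale(property_scale: Mapping[str, float]) -> dict[str, float]:
    vals = np.array([property_scale[a] for a in CANONICAL_AA], dtype=float)
    sd = vals.std()
    if sd == 0:
        raise CrossessError("autocorrelation property scale is constant")
    z = (vals - vals.mean()) / sd
    return dict(zip(CANONICAL_AA, z))


def autocorrelation(protein_sequence: str,
                    property_scale: Mapping[str, float] | None = None,
                    max_lag: int = 3) -> list[float]:
    """Normalized Moreau-Broto autocorrelation at lags 1..max_lag.

    AC(d) = (1/(L-d)) * sum_i P(s_i) P(s_{i+d}) with the residue property
    scale standardized to mean 0 / sd 1 over the 20 canonical residues
    (Kyte-Doolittle hydrophobicity by default).  Non-canonical residues are
    dropped before the lagged products are formed.
    """
    if max_lag < 1:
        raise CrossessError("max_lag must be >= 1")
    scale = _standardized_scale(property_scale or KYTE_DOOLITTLE)
    vals = np.array([scale[c] for c in protein_sequence.upper() if c in scale])
    if vals.size <= max_lag:
        raise CrossessError(
            f"sequence of usable length {vals.size} too short for max_lag={max_lag}"
        )
    return [float(np.dot(vals[:-d], vals[d:]) / (vals.size - d))
            for d in range(1, max_lag + 1)]


def exon_features(annotation: GeneAnnotation) -> tuple[int, int]:
    """(number of exons, total exonic length in bp); lengths are end-start+1."""
    total = sum(e - s + 1 for s, e in annotation.exons)
    return len(annotation.exons), total


def distance_from_centre(annotation: GeneAnnotation, chrom_length: int) -> float:
    """|midpoint - L/2| / (L/2): 0 at the chromosome centre, ->1 at the ends."""
    if chrom_length <= 0:
        raise CrossessError(f"invalid chromosome length {chrom_length}")
    half = chrom_length / 2.0
    return abs(annotation.midpoint - half) / half


def count_peak_overlaps(genes: Sequence[GeneAnnotation],
                        peaks: Sequence[Interval]) -> pd.Series:
    """Per-gene count of peaks with >=1 bp overlap with the gene span.

    Gene spans are 1-based inclusive, peaks BED half-open; strand is ignored.
    A peak [ps, pe) overlaps gene [gs, ge] iff ps < ge and pe > gs - 1 (in
    0-based terms), so an abutting peak does not count.
    """
    starts_by_chrom: dict[str, list[int]] = defaultdict(list)
    ends_by_chrom: dict[str, list[int]] = defaultdict(list)
    for p in peaks:
        starts_by_chrom[p.chromosome].append(p.start)
        ends_by_chrom[p.chromosome].append(p.end)
    sorted_starts = {c: np.sort(v) for c, v in starts_by_chrom.items()}
    sorted_ends = {c: np.sort(v) for c, v in ends_by_chrom.items()}

    counts = np.zeros(len(genes), dtype=int)
    for i, g in enumerate(genes):
        if g.chromosome not in sorted_starts:
            continue
        g0, g1 = g.start - 1, g.end  # 0-based half-open gene span
        n_start_before_end = np.searchsorted(sorted_starts[g.chromosome], g1, side="left")
        n_end_before_start = np.searchsorted(sorted_ends[g.chromosome], g0, side="right")
        counts[i] = int(n_start_before_end - n_end_before_start)
    return pd.Series(counts, index=[g.gene_id for g in genes])


def graph_centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness centrality per node.

    Betweenness is unnormalized over unordered pairs (Brandes accumulation);
    closeness is (n_reachable - 1) / sum(distances) within the node's
    component, 0 for isolates.  Self-loops are dropped.
    """
    g = graph.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    nodes = list(g.nodes())
    return pd.DataFrame({
        "degree": [degree[n] for n in nodes],
        "betweenness": [betweenness[n] for n in nodes],
        "closeness": [closeness[n] for n in nodes],
    }, index=nodes)


def ortholog_group_sizes(groups: Mapping[str, set[str]],
                         gene_ids: Iterable[str]) -> pd.Series:
    """Size of the ortholog group containing each gene; 0 for ungrouped genes.

    A gene found in several groups gets the largest group's size (logged).
    """
    membership: dict[str, list[int]] = defaultdict(list)
    for members in groups.values():
        for gid in members:
            membership[gid].append(len(members))
    gene_ids = list(gene_ids)
    sizes = []
    n_multi = 0
    for gid in gene_ids:
        gsizes = membership.get(gid, [])
        if len(gsizes) > 1:
            n_multi += 1
        sizes.append(max(gsizes) if gsizes else 0)
    if n_multi:
        logger.info("ortholog_group_sizes: %d genes in multiple groups; "
                    "largest group used", n_multi)
    return pd.Series(sizes, index=gene_ids)


def est_hit_counts(hits: pd.DataFrame, gene_ids: Iterable[str],
                   evalue_cutoff: float = 1e-10) -> pd.Series:
    """Per-gene count of EST BLAST hits with evalue <= cutoff.

    ESTs are the queries, genes the subjects; the <= convention means a hit
    exactly at the cutoff is counted.
    """
    gene_ids = list(gene_ids)
    if len(hits) == 0:
        return pd.Series(0, index=gene_ids)
    sig = hits.loc[hits["evalue"] <= evalue_cutoff, "subject"]
    counts = sig.value_counts()
    return pd.Series([int(counts.get(g, 0)) for g in gene_ids], index=gene_ids)


def sequence_feature_table(proteins: Mapping[str, str], max_lag: int = 3) -> pd.DataFrame:
    """Protein composition + autocorrelation descriptors for a set of genes."""
    rows = {}
    for gid, seq in proteins.items():
        row = aa_composition(seq)
        row["protein_length"] = float(len(seq))
        for d, v in enumerate(autocorrelation(seq, max_lag=max_lag), start=1):
            row[f"autocorr_hydro_lag{d}"] = v
        rows[gid] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)


def build_feature_table(species: str,
                        annotations: Sequence[GeneAnnotation],
                        chrom_lengths: Mapping[str, int],
                        proteins: Mapping[str, str] | None = None,
                        peak_sets: Mapping[str, Sequence[Interval]] | None = None,
                        graph: nx.Graph | None = None,
                        ortholog_groups: Mapping[str, set[str]] | None = None,
                        est_hits: pd.DataFrame | None = None,
                        passthrough: FeatureTable | None = None) -> FeatureTable:
    """Assemble the per-gene feature table from whichever inputs are present.

    Genes are the annotated genes; passthrough columns are joined on gene id
    (genes absent from the passthrough table get that table's median, logged).
    """
    gene_ids = [g.gene_id for g in annotations]
    data: dict[str, pd.Series] = {}
    provenance: dict[str, str] = {}

    exon_counts, exon_lengths, distances = [], [], []
    for g in annotations:
        n, total = exon_features(g)
        exon_counts.append(n)
        exon_lengths.append(total)
        distances.append(distance_from_centre(g, chrom_lengths[g.chromosome]))
    data["exons"] = pd.Series(exon_counts, index=gene_ids, dtype=float)
    data["exons_total_length"] = pd.Series(exon_lengths, index=gene_ids, dtype=float)
    data["distance"] = pd.Series(distances, index=gene_ids)
    provenance.update({"exons": "annotation", "exons_total_length": "annotation",
                       "distance": "annotation"})

    if proteins is not None:
        seq_df = sequence_feature_table(proteins).reindex(gene_ids)
        for col in seq_df.columns:
            data[col] = seq_df[col]
            provenance[col] = "sequence"

    for name, peaks in (peak_sets or {}).items():
        col = f"ChIP_{name}" if not name.startswith("ChIP_") else name
        data[col] = count_peak_overlaps(annotations, peaks).astype(float)
        provenance[col] = "peaks"

    if graph is not None:
        cent = graph_centralities(graph).reindex(gene_ids).fillna(0.0)
        for col in cent.columns:
            data[col] = cent[col]
            provenance[col] = "graph"

    if ortholog_groups is not None:
        data["OMA_orthologs"] = ortholog_group_sizes(ortholog_groups, gene_ids).astype(float)
        provenance["OMA_orthologs"] = "orthologs"

    if est_hits is not None:
        data["EST_BLAST"] = est_hit_counts(est_hits, gene_ids).astype(float)
        provenance["EST_BLAST"] = "est_hits"

    df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    if passthrough is not None:
        extra = passthrough.data.reindex(gene_ids)
        n_missing = int(extra.isna().any(axis=1).sum())
        if n_missing:
            logger.info("build_feature_table: %d genes missing from passthrough "
                        "table; median-imputed", n_missing)
            extra = extra.fillna(extra.median())
        clash = set(extra.columns) & set(df.columns)
        if clash:
            raise CrossessError(f"passthrough features clash with computed ones: {sorted(clash)}")
        df = pd.concat([df, extra], axis=1)
        provenance.update({c: "passthrough" for c in extra.columns})
    return FeatureTable(species, df, provenance)
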