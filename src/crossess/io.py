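"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
The internal canonical convention is **1-based, fully inclusive**, the native
convention of GFF3, because gene models enter the pipeline from GFF3.  BED
input (0-based, half-open) is converted on read and back-converted on write;
:class:`Interval` stores BED-native coordinates and offers the conversion.

Feature tables are plain TSV: header row, first column the gene identifier,
remaining columns named numeric features.  Round-trips are lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import networkx as nx
import pandas as pd
from Bio import SeqIO

from .errors import FormatError

logger = logging.getLogger(__name__)

BLAST_TAB_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene model in 1-based inclusive coordinates (GFF3 native)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end}]"
            )
        for (s, e) in self.exons:
            if s > e:
                raise FormatError(f"gene {self.gene_id}: degenerate exon ({s}, {e})")
            if s < self.start or e > self.end:
                raise FormatError(
                    f"gene {self.gene_id}: exon ({s}, {e}) outside gene span"
                )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class Interval:
    """A BED-convention interval: 0-based start, exclusive end."""

    chromosome: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"interval on {self.chromosome}: negative start {self.start}")
        if self.start >= self.end:
            raise FormatError(
                f"interval on {self.chromosome}: start {self.start} >= end {self.end}"
            )

    def to_1based(self) -> tuple[int, int]:
        """Return the same bases as a 1-based inclusive (start, end) pair."""
        return self.start + 1, self.end

    @staticmethod
    def from_1based(chromosome: str, start: int, end: int, **kw) -> "Interval":
        return Interval(chromosome, start - 1, end, **kw)


@dataclass
class FeatureTable:
    """Genes x named numeric features for one species.

    ``data`` is indexed by gene id with one column per feature; ``provenance``
    maps a feature name to a source tag (sequence, annotation, peaks, graph,
    orthologs, est_hits, passthrough, ...).  ``imputation_log`` records, per
    feature, how many missing values were replaced by the within-species
    median on read.
    """

    species: str
    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)
    imputation_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in feature table")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate feature name {dup!r} in feature table")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def restrict(self, features: Iterable[str]) -> "FeatureTable":
        feats = list(features)
        missing = [f for f in feats if f not in self.data.columns]
        if missing:
            raise FormatError(
                f"features absent from {self.species} table: {missing}"
            )
        return FeatureTable(self.species, self.data[feats].copy(),
                            {f: self.provenance.get(f, "unknown") for f in feats})


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map (duplicate ids rejected)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _validate_gff3_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise FormatError(f"{path}:{lineno}: invalid span [{start}, {end}]")


def read_gff3(path: str | Path, id_attr: str = "ID") -> list[GeneAnnotation]:
    """Parse gene models (``gene`` features plus their ``exon`` children).

    Coordinates stay 1-based inclusive.  The gene identifier comes from the
    ``id_attr`` GFF3 attribute (default ``ID``).
    """
    _validate_gff3_lines(path)
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        if id_attr not in g.attributes:
            raise FormatError(f"{path}: gene at {g.seqid}:{g.start} lacks attribute {id_attr!r}")
        gid = g.attributes[id_attr][0]
        if gid in seen:
            raise FormatError(f"{path}: duplicate gene id {gid!r}")
        seen.add(gid)
        exons = tuple(sorted((e.start, e.end) for e in db.children(g, featuretype="exon")))
        genes.append(GeneAnnotation(gid, g.seqid, g.start, g.end, g.strand or ".", exons))
    return genes


def write_gff3(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chromosome}\tcrossess\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chromosome}\tcrossess\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3+ intervals, kept 0-based half-open."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from None
            try:
                out.append(Interval(fields[0], start, end, name, score))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            extra = ""
            if iv.name is not None:
                extra = f"\t{iv.name}"
                if iv.score is not None:
                    extra += f"\t{iv.score:g}"
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}{extra}\n")


def read_feature_table(path: str | Path, species: str = "",
                       impute: bool = True) -> FeatureTable:
    """Read a genes x features TSV; missing values imputed to the feature median.

    Imputation counts are recorded in ``imputation_log``; features that are
    entirely missing are rejected (no median exists).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas error messages carry position info
        raise FormatError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    non_numeric = [c for c in df.columns
                   if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise FormatError(f"{path}: non-numeric feature columns {non_numeric}")
    log: dict[str, int] = {}
    if impute:
        for col in df.columns:
            n_missing = int(df[col].isna().sum())
            if n_missing == len(df):
                raise FormatError(f"{path}: feature {col!r} has no observed values")
            if n_missing:
                df[col] = df[col].fillna(df[col].median())
                log[col] = n_missing
                logger.info("imputed %d missing values in %s with the median", n_missing, col)
    table = FeatureTable(species or Path(path).stem, df)
    table.imputation_log = log
    return table


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column TSV edge list into an undirected graph (self-loops dropped)."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated node ids")
            a, b = fields[0], fields[1]
            if a == b:
                continue
            g.add_edge(a, b)
    return g


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read 12-column BLAST tabular output (``-outfmt 6``)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=BLAST_TAB_COLUMNS)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] != len(BLAST_TAB_COLUMNS):
        raise FormatError(f"{path}: expected 12 columns, found {df.shape[1]}")
    if len(df) and not pd.api.types.is_numeric_dtype(df["evalue"]):
        raise FormatError(f"{path}: non-numeric evalue column")
    return df


def read_two_column_groups(path: str | Path) -> dict[str, set[str]]:
    """Read a group<TAB>gene file into a group -> gene-set map."""
    groups: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected group<TAB>gene")
            groups.setdefault(fields[0], set()).add(fields[1])
    return groups
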