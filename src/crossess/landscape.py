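"""Chromosome-level essentiality-probability tracks and heterochromatin summaries.

Each gene becomes one BedGraph record (its 0-based half-open span scored by
the predicted probability) and one (midpoint, probability) point on its
chromosome; per-bin gene densities give the coarse landscape.  The
heterochromatin summary asks whether high-probability genes (> 0.5) avoid
heterochromatin: it reports inside/outside fractions by gene midpoint plus a
two-sided rank-sum comparison (normal approximation) of the probabilities of
genes inside versus outside the intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io import GeneAnnotation, Interval
from .transfer import RankedPrediction

logger = logging.getLogger(__name__)

HIGH_PROBABILITY = 0.5


@dataclass
class ChromTrack:
    chromosome: str
    genes: pd.DataFrame        # columns: gene_id, midpoint, probability
    bin_size: int
    bin_counts: np.ndarray     # per-bin gene counts along the chromosome
    het_intervals: list[Interval]


def _midpoint_inside(mid: float, intervals: Sequence[Interval]) -> bool:
    # mid is 1-based; BED intervals half-open: inside iff start < mid <= end
    return any(iv.start < mid <= iv.end for iv in intervals)


def probability_track(ranked: RankedPrediction,
                      annotations: Sequence[GeneAnnotation],
                      chrom_lengths: Mapping[str, int],
                      het_intervals: Sequence[Interval] = (),
                      bin_size: int = 100_000
                      ) -> tuple[dict[str, ChromTrack], list[str]]:
    """Per-chromosome tracks plus BedGraph lines (one record per gene).

    Ranked genes lacking an annotation are logged and skipped.  BedGraph uses
    0-based half-open spans; records are sorted by chromosome then start.
    """
    ann = {a.gene_id: a for a in annotations}
    probs = dict(zip(ranked.table["gene_id"], ranked.table["probability"]))
    missing = [g for g in probs if g not in ann]
    if missing:
        logger.info("probability_track: %d ranked genes lack annotations; skipped",
                    len(missing))
    per_chrom: dict[str, list] = {c: [] for c in chrom_lengths}
    records = []
    for gid, p in probs.items():
        a = ann.get(gid)
        if a is None or a.chromosome not in per_chrom:
            continue
        per_chrom[a.chromosome].append((gid, a.midpoint, p))
        records.append((a.chromosome, a.start - 1, a.end, p))
    records.sort(key=lambda r: (r[0], r[1]))
    bedgraph = [f"{c}\t{s}\t{e}\t{p:.6g}" for c, s, e, p in records]

    tracks = {}
    for chrom, length in chrom_lengths.items():
        rows = pd.DataFrame(per_chrom[chrom],
                            columns=["gene_id", "midpoint", "probability"])
        n_bins = int(np.ceil(length / bin_size))
        counts = np.zeros(n_bins, dtype=int)
        if len(rows):
            idx = np.minimum((rows["midpoint"].to_numpy() // bin_size).astype(int),
                             n_bins - 1)
            np.add.at(counts, idx, 1)
        tracks[chrom] = ChromTrack(
            chrom, rows, bin_size, counts,
            [iv for iv in het_intervals if iv.chromosome == chrom])
    return tracks, bedgraph


def write_bedgraph(lines: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def heterochromatin_summary(tracks: Mapping[str, ChromTrack]) -> dict:
    """Do high-probability genes avoid heterochromatin?

    Returns inside/outside gene counts, the fraction of high-probability
    (> 0.5) genes falling inside heterochromatin by midpoint, and a
    two-sided rank-sum test (normal approximation) comparing probabilities
    of genes inside vs outside.  With no heterochromatin intervals the
    inside fraction is undefined and flagged.
    """
    inside_probs, outside_probs = [], []
    has_het = any(t.het_intervals for t in tracks.values())
    for t in tracks.values():
        for _, mid, p in t.genes.itertuples(index=False):
            (inside_probs if _midpoint_inside(mid, t.het_intervals)
             else outside_probs).append(p)
    inside = np.asarray(inside_probs)
    outside = np.asarray(outside_probs)
    high_inside = int((inside > HIGH_PROBABILITY).sum())
    high_outside = int((outside > HIGH_PROBABILITY).sum())
    n_high = high_inside + high_outside
    out = {
        "n_inside": int(inside.size),
        "n_outside": int(outside.size),
        "n_high": n_high,
        "high_inside": high_inside,
        "high_outside": high_outside,
        "high_inside_fraction": (high_inside / n_high) if n_high else float("nan"),
        "inside_fraction_defined": bool(has_het),
        "ranksum_statistic": float("nan"),
        "ranksum_pvalue": float("nan"),
    }
    if not has_het:
        out["flag"] = "no heterochromatin intervals supplied"
        out["high_inside_fraction"] = float("nan")
        return out
    if inside.size and outside.size:
        stat, p = scipy.stats.ranksums(inside, outside)
        out["ranksum_statistic"] = float(stat)
        out["ranksum_pvalue"] = float(p)
    return out
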