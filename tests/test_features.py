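import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossess.errors import CrossessError
from crossess.features import (CANONICAL_AA, aa_composition, autocorrelation,
                               build_feature_table, count_peak_overlaps,
                               distance_from_centre, est_hit_counts,
                               exon_features, gc_content, graph_centralities,
                               ortholog_group_sizes)
from crossess.io import GeneAnnotation, Interval


@pytest.mark.parametrize("seq,expected", [
    ("ATGC", 0.5), ("GGCC", 1.0), ("ATNGC", 0.5), ("atgc", 0.5),
])
def test_gc_content(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


@pytest.mark.parametrize("seq", ["", "NNN"])
def test_gc_content_undefined(seq):
    with pytest.raises(CrossessError):
        gc_content(seq)


def test_aa_composition_examples():
    assert aa_composition("SSSS")["AAC_S"] == 1.0
    comp = aa_composition("SASA")
    assert comp["AAC_S"] == 0.5 and comp["AAC_A"] == 0.5
    with pytest.raises(CrossessError):
        aa_composition("")


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet=CANONICAL_AA, min_size=1, max_size=200))
def test_aa_composition_sums_to_one(seq):
    assert sum(aa_composition(seq).values()) == pytest.approx(1.0)


def test_autocorrelation_homopolymer_is_constant():
    vals = autocorrelation("A" * 50, max_lag=3)
    assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])
    # equals P(A)^2 for the standardized scale
    from crossess.features import KYTE_DOOLITTLE, _standardized_scale
    pa = _standardized_scale(KYTE_DOOLITTLE)["A"]
    assert vals[0] == pytest.approx(pa * pa)


def test_autocorrelation_alternating_signs():
    """Opposite-property residues alternate: same-parity lags score higher."""
    seq = "IR" * 30  # hydrophobic / charged, opposite scale signs
    ac = autocorrelation(seq, max_lag=2)
    assert ac[1] > ac[0]


def test_autocorrelation_short_sequence_errors():
    with pytest.raises(CrossessError, match="too short"):
        autocorrelation("AC", max_lag=3)


@pytest.mark.parametrize("exons,expected", [
    (((1, 10),), (1, 10)),
    (((100, 150), (200, 260)), (2, 112)),
    ((), (0, 0)),
])
def test_exon_features(exons, expected):
    start = min((s for s, _ in exons), default=1)
    end = max((e for _, e in exons), default=1000)
    g = GeneAnnotation("g", "c", start, end, "+", exons)
    assert exon_features(g) == expected


def test_distance_from_centre():
    assert distance_from_centre(GeneAnnotation("g", "c", 45, 55), 100) == 0.0
    assert distance_from_centre(GeneAnnotation("g", "c", 20, 30), 100) == pytest.approx(0.5)
    assert distance_from_centre(GeneAnnotation("g", "c", 1, 1), 100) == pytest.approx(0.98)
    with pytest.raises(CrossessError):
        distance_from_centre(GeneAnnotation("g", "c", 1, 2), 0)


def test_count_peak_overlaps_conventions():
    gene = GeneAnnotation("g1", "chr1", 100, 200)
    peaks = [Interval("chr1", 149, 160), Interval("chr1", 299, 400)]
    assert count_peak_overlaps([gene], peaks).loc["g1"] == 1
    # abutting peak (BED start == gene end in 0-based) does not overlap
    assert count_peak_overlaps([gene], [Interval("chr1", 200, 210)]).loc["g1"] == 0
    # peak ending exactly at gene start does overlap its first base
    assert count_peak_overlaps([gene], [Interval("chr1", 90, 100)]).loc["g1"] == 1
    assert count_peak_overlaps([gene], []).loc["g1"] == 0


def test_count_peak_overlaps_matches_bruteforce():
    rng = np.random.default_rng(0)
    for _ in range(20):
        genes = [GeneAnnotation(f"g{i}", f"chr{rng.integers(2)}",
                                int(s := rng.integers(1, 500)),
                                int(s + rng.integers(1, 100)))
                 for i in range(30)]
        peaks = [Interval(f"chr{rng.integers(2)}", int(s := rng.integers(0, 500)),
                          int(s + rng.integers(1, 80))) for _ in range(40)]
        fast = count_peak_overlaps(genes, peaks)
        for g in genes:
            brute = sum(1 for p in peaks if p.chromosome == g.chromosome
                        and p.start < g.end and p.end > g.start - 1)
            assert fast.loc[g.gene_id] == brute


def test_graph_centralities_examples():
    path = nx.path_graph(["a", "b", "c"])
    c = graph_centralities(path)
    assert c.loc["b", "betweenness"] == 1.0 and c.loc["a", "betweenness"] == 0.0
    k4 = nx.complete_graph(4)
    c4 = graph_centralities(k4)
    assert (c4["betweenness"] == 0).all() and (c4["degree"] == 3).all()
    g = nx.Graph()
    g.add_node("solo")
    g.add_edge("x", "x")  # self-loop dropped
    ci = graph_centralities(g)
    assert ci.loc["solo", "degree"] == 0 and ci.loc["solo", "closeness"] == 0.0
    assert ci.loc["x", "degree"] == 0


def test_ortholog_group_sizes():
    groups = {"OG1": {f"g{i}" for i in range(7)}, "OG2": {"g0", "x"}, "OG3": {"solo"}}
    sizes = ortholog_group_sizes(groups, ["g1", "g0", "solo", "absent"])
    assert sizes.loc["g1"] == 7
    assert sizes.loc["g0"] == 7  # multi-group gene takes the largest group
    assert sizes.loc["solo"] == 1
    assert sizes.loc["absent"] == 0


def test_est_hit_counts():
    hits = pd.DataFrame({
        "subject": ["g1", "g1", "g1", "g1", "g2"],
        "evalue": [1e-20, 1e-20, 1e-20, 1e-5, 1e-10],
    })
    counts = est_hit_counts(hits, ["g1", "g2", "g3"])
    assert counts.loc["g1"] == 3         # the 1e-5 hit is filtered out
    assert counts.loc["g2"] == 1         # exactly at the cutoff counts (<=)
    assert counts.loc["g3"] == 0
    empty = est_hit_counts(hits.iloc[:0], ["g1"])
    assert empty.loc["g1"] == 0


def test_build_feature_table_merges_sources(small_world):
    ds = small_world.species["A"]
    table = build_feature_table("A", ds.annotations[:50], ds.chrom_lengths,
                                proteins={a.gene_id: ds.proteins[a.gene_id]
                                          for a in ds.annotations[:50]})
    assert {"exons", "exons_total_length", "distance"} <= set(table.feature_names)
    assert any(f.startswith("AAC_") for f in table.feature_names)
    assert table.provenance["exons"] == "annotation"
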