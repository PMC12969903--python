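import numpy as np
import pandas as pd
import pytest

from pangsv import (
    NRUIRecord,
    Segment,
    cluster_assemblies,
    extract_nruis,
    find_bubbles,
    frequency_summary,
    genotype_pav,
    merge_panels,
    partition_segments,
)
from pangsv.nrui_panel import cophenetic_matrix

from conftest import linear_graph, path_for


def _insertion_graph(alt_len=100, with_carrier=True):
    """s1-s2-s3 reference; X inserted between s2 and s3."""
    graph = linear_graph(3)
    graph.add_segment(Segment("X", "T" * alt_len))
    graph.add_link("s2", "+", "X", "+")
    graph.add_link("X", "+", "s3", "+")
    ref = graph.reference_path["chr1"]
    paths = [path_for(graph, "ref_like", ref, breed="A")]
    if with_carrier:
        paths.append(
            path_for(graph, "carrier", [("s1", "+"), ("s2", "+"), ("X", "+"), ("s3", "+")], breed="B")
        )
    return graph, paths


def test_long_biallelic_insertion_is_retained():
    graph, paths = _insertion_graph(alt_len=100)
    bubbles = find_bubbles(graph, paths)
    part = partition_segments(graph, paths)
    nruis = extract_nruis(graph, bubbles, part, paths)
    assert len(nruis) == 1
    assert nruis[0].length == 100
    assert nruis[0].carriers == {"carrier"}


def test_exactly_50nt_insertion_is_excluded():
    graph, paths = _insertion_graph(alt_len=50)
    bubbles = find_bubbles(graph, paths)
    part = partition_segments(graph, paths)
    assert extract_nruis(graph, bubbles, part, paths) == []


def test_untraversed_alternate_is_excluded():
    """Filter 1: a constructed bubble whose alternate segment is on no
    assembly walk (nested) must not become an NRUI."""
    from pangsv.bubble_sv import Bubble

    graph, paths = _insertion_graph(alt_len=100, with_carrier=False)
    part = partition_segments(graph, paths)
    assert "X" in part.untraversed
    bubble = Bubble(
        chrom="chr1", source="s2", sink="s3", ref_segments=(), ref_seq="",
        alt_traversals=[(("X",), "T" * 100)], start0=120, end0=120,
    )
    assert extract_nruis(graph, [bubble], part, paths) == []


def test_reference_path_segment_is_excluded():
    """Filter 2: an alternate traversal that reuses a reference segment is
    not a non-reference insertion."""
    from pangsv.bubble_sv import Bubble

    graph, paths = _insertion_graph(alt_len=100)
    part = partition_segments(graph, paths)
    bubble = Bubble(
        chrom="chr1", source="s1", sink="s3", ref_segments=(), ref_seq="",
        alt_traversals=[(("s2",), graph.segments["s2"].sequence)], start0=60, end0=60,
    )
    assert extract_nruis(graph, [bubble], part, paths) == []


def test_extraction_matches_truth(bundle, called):
    panel = called["panel"]
    truth_ids = {e.nrui_id for e in bundle.truth.nrui_events()}
    assert {r.id for r in panel} == truth_ids
    by_id = {r.id: r for r in panel}
    for e in bundle.truth.nrui_events():
        assert by_id[e.nrui_id].carriers == set(e.carriers)
        assert by_id[e.nrui_id].sequence == e.alts[0]


def _mk(i, chrom, pos, length, panel="a"):
    return NRUIRecord(
        id=f"{panel}{i}", chrom=chrom, pos=pos, sequence="A" * length,
        panel=panel, carriers=frozenset(),
    )


def test_merge_identical_panels_is_idempotent():
    panel = [_mk(i, "chr1", 1000 * (i + 1), 100) for i in range(10)]
    merged, stats = merge_panels(panel, panel)
    assert len(merged) == 10
    assert stats["n_common_identical"] == 10
    assert stats["identical_fraction"] == 1.0


def test_merge_disjoint_panels_concatenates():
    a = [_mk(i, "chr1", 1000 * (i + 1), 100, "a") for i in range(10)]
    b = [_mk(i, "chr2", 1000 * (i + 1), 100, "b") for i in range(5)]
    merged, stats = merge_panels(a, b)
    assert len(merged) == 15
    assert stats["n_common"] == 0


def test_merge_reciprocal_overlap_rule():
    a = [_mk(0, "chr1", 10_000, 100, "a")]
    close_similar = [_mk(0, "chr1", 10_030, 95, "b")]   # within 50 bp, 95% length
    close_dissimilar = [_mk(1, "chr1", 10_030, 50, "b")]  # within 50 bp, 50% length
    far_similar = [_mk(2, "chr1", 10_100, 100, "b")]    # >50 bp away
    merged, stats = merge_panels(a, close_similar)
    assert stats["n_common_overlap"] == 1 and len(merged) == 1
    assert merged[0].panel == "common-overlap"
    merged, stats = merge_panels(a, close_dissimilar)
    assert stats["n_common"] == 0 and len(merged) == 2
    merged, stats = merge_panels(a, far_similar)
    assert stats["n_common"] == 0 and len(merged) == 2


def test_merge_count_arithmetic_is_commutative():
    a = [_mk(i, "chr1", 1000 * (i + 1), 100, "a") for i in range(8)]
    b = [_mk(i, "chr1", 1000 * (i + 1), 100, "b") for i in range(4)] + [
        _mk(9, "chr2", 500, 80, "b")
    ]
    _, ab = merge_panels(a, b)
    _, ba = merge_panels(b, a)
    assert ab["n_merged"] == ba["n_merged"] == 8 + 5 - 4
    assert ab["n_common_identical"] == ba["n_common_identical"] == 4


def test_pav_matrix_matches_truth_carriers(bundle, called):
    pav = called["pav"]
    for e in bundle.truth.nrui_events():
        carriers = set(pav.index[pav[e.nrui_id] == 1.0])
        assert carriers == set(e.carriers)
    # reference walk itself carries no NRUI by definition
    assert pav.to_numpy().max() <= 1.0


def test_genotype_pav_missing_chromosome():
    graph, paths = _insertion_graph()
    bubbles = find_bubbles(graph, paths)
    part = partition_segments(graph, paths)
    panel = extract_nruis(graph, bubbles, part, paths)
    from pangsv import AssemblyPath

    empty = AssemblyPath(sample="no_chrom", breed="C", walks={})
    pav = genotype_pav(panel, paths + [empty])
    assert np.isnan(pav.loc["no_chrom"].to_numpy()).all()
    assert pav.loc["carrier"].to_numpy().item() == 1.0
    assert pav.loc["ref_like"].to_numpy().item() == 0.0


def test_frequency_summary_thresholds_and_private(bundle, called):
    pav = called["pav"]
    breed_map = {p.sample: p.breed for p in bundle.paths}
    summary = frequency_summary(pav, breed_map, called["panel"])
    freqs = summary["frequencies"]
    assert ((freqs >= 0) & (freqs <= 1)).all()
    truth_private = {
        e.nrui_id for e in bundle.truth.nrui_events() if e.breed_private
    }
    assert set(summary["private"]["nrui"]) == truth_private
    # private implies frequency bounded by the largest breed share
    n_total = len(bundle.paths)
    max_breed = max(n for _, n in bundle.config.breeds)
    assert (freqs[list(truth_private)] <= max_breed / n_total + 1e-12).all()


def test_fully_carried_nrui_is_near_fixed():
    matrix = pd.DataFrame(
        {"n1": [1.0, 1.0, 1.0], "n2": [1.0, 0.0, 0.0]},
        index=["a", "b", "c"],
    )
    summary = frequency_summary(matrix, {"a": "A", "b": "A", "c": "B"})
    assert summary["n_near_fixed"] == 1
    assert summary["frequencies"]["n1"] == 1.0


def test_identical_assemblies_merge_at_height_zero():
    matrix = pd.DataFrame(
        {"n1": [1.0, 1.0, 0.0], "n2": [0.0, 0.0, 1.0]},
        index=["a", "b", "c"],
    )
    result = cluster_assemblies(matrix, k=2)
    coph = cophenetic_matrix(result)
    assert coph.loc["a", "b"] == 0.0
    assert result.flat["a"] == result.flat["b"] != result.flat["c"]


def test_cophenetic_matrix_is_row_order_invariant(called):
    pav = called["pav"]
    r1 = cluster_assemblies(pav)
    shuffled = pav.sample(frac=1.0, random_state=0)
    r2 = cluster_assemblies(shuffled)
    c1 = cophenetic_matrix(r1)
    c2 = cophenetic_matrix(r2).loc[c1.index, c1.columns]
    assert np.allclose(c1.to_numpy(), c2.to_numpy())


def test_clustering_recovers_planted_breeds():
    """With strong breed-private signal the flat cut at k = number of
    breeds reproduces the breed partition exactly (adjusted Rand = 1)."""
    from sklearn.metrics import adjusted_rand_score

    from pangsv import SimConfig, simulate_all

    cfg = SimConfig(
        seed=23,
        n_chromosomes=3,
        chrom_length=400_000,
        sv_rates={"strict_insertion": 120.0},
        insertion_length_modes=(225.0,),
        insertion_length_weights=(1.0,),
        breed_private_rate=0.8,
    )
    b = simulate_all(cfg, with_population=False)
    bubbles = find_bubbles(b.graph, b.paths)
    part = partition_segments(b.graph, b.paths)
    panel = extract_nruis(b.graph, bubbles, part, b.paths)
    pav = genotype_pav(panel, b.paths)
    k = len(cfg.breeds)
    result = cluster_assemblies(pav, k=k)
    breeds = [s.rsplit("_h", 1)[0] for s in result.labels]
    ari = adjusted_rand_score(breeds, result.flat.loc[result.labels])
    assert ari == 1.0


def test_cluster_requires_two_assemblies():
    with pytest.raises(ValueError):
        cluster_assemblies(pd.DataFrame({"n1": [1.0]}, index=["a"]))
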