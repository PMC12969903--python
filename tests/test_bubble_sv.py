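import numpy as np
import pytest

from pangsv import (
    Segment,
    call_alleles,
    classify_sv,
    find_bubbles,
    read_vcf,
    records_from_bubbles,
    size_spectrum,
    sv_table,
    write_vcf,
)
from pangsv.bubble_sv import InvalidRecordError

from conftest import linear_graph, path_for


def test_identical_walks_yield_no_bubbles():
    graph = linear_graph(4)
    paths = [path_for(graph, f"a{i}", graph.reference_path["chr1"]) for i in range(3)]
    assert find_bubbles(graph, paths) == []


def test_single_insertion_bubble_has_empty_reference_allele():
    graph = linear_graph(3)
    graph.add_segment(Segment("X", "T" * 80))
    graph.add_link("s2", "+", "X", "+")
    graph.add_link("X", "+", "s3", "+")
    ref = graph.reference_path["chr1"]
    a = path_for(graph, "a", ref)
    b = path_for(graph, "b", [("s1", "+"), ("s2", "+"), ("X", "+"), ("s3", "+")])
    bubbles = find_bubbles(graph, [a, b])
    assert len(bubbles) == 1
    bub = bubbles[0]
    assert bub.source == "s2" and bub.sink == "s3"
    assert bub.ref_seq == ""
    assert bub.alt_traversals[0][1] == "T" * 80
    calls = call_alleles(bub, [a, b])
    assert calls == {"a": 0, "b": 1}


def test_three_alternate_spellings_are_multiallelic():
    graph = linear_graph(3)
    for i, base in enumerate("TCA", start=1):
        graph.add_segment(Segment(f"x{i}", base * (60 + i)))
        graph.add_link("s1", "+", f"x{i}", "+")
        graph.add_link(f"x{i}", "+", "s3", "+")
    ref = graph.reference_path["chr1"]
    paths = [path_for(graph, "ref_like", ref)] + [
        path_for(graph, f"p{i}", [("s1", "+"), (f"x{i}", "+"), ("s3", "+")])
        for i in (1, 2, 3)
    ]
    bubbles = find_bubbles(graph, paths)
    assert len(bubbles) == 1
    calls = call_alleles(bubbles[0], paths)
    assert calls["ref_like"] == 0
    assert {calls["p1"], calls["p2"], calls["p3"]} == {1, 2, 3}
    records = records_from_bubbles(bubbles, paths)
    assert records[0].zygosity_class == "multiallelic"


def test_sample_missing_chromosome_is_called_missing():
    graph = linear_graph(3)
    graph.add_segment(Segment("X", "T" * 80))
    graph.add_link("s2", "+", "X", "+")
    graph.add_link("X", "+", "s3", "+")
    a = path_for(graph, "a", [("s1", "+"), ("s2", "+"), ("X", "+"), ("s3", "+")])
    from pangsv import AssemblyPath

    no_chrom = AssemblyPath(sample="b", breed="X", walks={})
    bubbles = find_bubbles(graph, [a, no_chrom])
    calls = call_alleles(bubbles[0], [a, no_chrom])
    assert calls["b"] is None


@pytest.mark.parametrize(
    "ref_len,alt_len,expected",
    [
        (0, 300, "strict_insertion"),
        (3, 200, "relaxed_insertion"),
        (200, 0, "strict_deletion"),
        (200, 3, "relaxed_deletion"),
        (100, 100, "other"),
        (5, 49, "other"),  # residual allele but alt below the relaxed floor
        (40, 3, "other"),  # short allele but ref below the relaxed floor
    ],
)
def test_classification_rules(ref_len, alt_len, expected):
    allele_class, zygosity = classify_sv("A" * ref_len, ["C" * alt_len])
    assert allele_class == expected
    assert zygosity == "biallelic"


def test_classification_is_a_partition(bundle, called):
    classes = {
        "strict_insertion",
        "relaxed_insertion",
        "strict_deletion",
        "relaxed_deletion",
        "other",
    }
    for rec in called["records"]:
        assert rec.allele_class in classes
        assert rec.zygosity_class == ("biallelic" if len(rec.alts) == 1 else "multiallelic")


def test_multiallelic_class_requires_unanimous_rule():
    assert classify_sv("", ["A" * 100, "C" * 200]) == ("strict_insertion", "multiallelic")
    # one alt satisfies the relaxed-insertion rule, the other neither rule
    assert classify_sv("AAA", ["C" * 100, "GG"]) == ("other", "multiallelic")


def test_both_alleles_empty_is_invalid():
    with pytest.raises(InvalidRecordError):
        classify_sv("", [""])


def test_reference_allele_spelling_conservation(bundle, called):
    for bub in called["bubbles"]:
        assert bub.ref_seq == bundle.reference[bub.chrom][bub.start0 : bub.end0]


def test_min_length_floor(called):
    assert all(rec.max_allele_len >= 50 for rec in called["records"])


def test_truth_recovery_on_synthetic_graph(bundle, called):
    """Bubble calling + classification reproduces the implanted truth
    exactly: coordinates, alleles, classes and carrier sets."""
    records = called["records"]
    truth = bundle.truth
    assert len(records) == len(truth.events)
    rec_by_key = {(r.chrom, r.pos): r for r in records}
    for e in truth.events:
        r = rec_by_key[(e.chrom, e.pos)]
        assert r.ref == e.ref
        assert set(r.alts) == set(e.alts)
        if e.class_label == "multiallelic":
            assert r.zygosity_class == "multiallelic"
        elif e.class_label == "substitution":
            assert r.allele_class == "other"
        else:
            assert r.allele_class == e.class_label
        truth_carriers = {h: e.alts[i - 1] for h, i in e.carriers.items()}
        rec_carriers = {
            s: r.alts[a - 1] for s, a in r.genotypes.items() if a is not None and a >= 1
        }
        assert rec_carriers == truth_carriers


def test_sv_table_marginals(called):
    table = sv_table(called["records"])
    assert table.loc["total", "total"] == len(called["records"])
    assert (
        table.loc["insertion", "biallelic"]
        == table.loc["insertion", "biallelic_strict"] + table.loc["insertion", "biallelic_relaxed"]
    )
    assert table.loc["total", "total"] == (
        table.loc["total", "biallelic"] + table.loc["total", "multiallelic"]
    )


def test_sv_table_empty():
    table = sv_table([])
    assert (table.to_numpy() == 0).all()


def test_size_spectrum_bins_and_conservation(called):
    from pangsv.bubble_sv import SVRecord

    one = SVRecord(
        chrom="chr1", pos=10, start0=10, end0=10, ref="", alts=("A" * 150,),
        allele_class="strict_insertion", zygosity_class="biallelic",
    )
    spec = size_spectrum([one], bin_width=50)
    hit = spec[spec["insertions"] > 0]
    assert list(hit["bin_start"]) == [150]

    records = called["records"]
    spec = size_spectrum(records, bin_width=50)
    n_indels = sum(
        1 for r in records if r.allele_class != "other"
    )
    assert spec["insertions"].sum() + spec["deletions"].sum() == n_indels


def test_vcf_round_trip(bundle, called, tmp_path):
    records = called["records"]
    samples = [p.sample for p in bundle.paths]
    vcf = tmp_path / "calls.vcf"
    contigs = {c: len(s) for c, s in bundle.reference.items()}
    write_vcf(records, samples, str(vcf), reference=bundle.reference, contigs=contigs)
    back, samples2 = read_vcf(str(vcf))
    assert samples2 == samples
    assert len(back) == len(records)
    for a, b in zip(records, back):
        assert (a.chrom, a.pos, a.ref, a.alts) == (b.chrom, b.pos, b.ref, b.alts)
        assert a.allele_class == b.allele_class
        assert a.zygosity_class == b.zygosity_class
        assert a.genotypes == b.genotypes


def test_vcf_insertion_uses_left_anchor_base(bundle, called, tmp_path):
    records = [r for r in called["records"] if r.ref == ""]
    assert records
    vcf = tmp_path / "ins.vcf"
    samples = [p.sample for p in bundle.paths]
    write_vcf(records, samples, str(vcf), reference=bundle.reference)
    body = [l for l in vcf.read_text().splitlines() if not l.startswith("#")]
    for line, rec in zip(body, records):
        fields = line.split("\t")
        assert int(fields[1]) == rec.pos  # left-anchored insertion position
        anchor = bundle.reference[rec.chrom][rec.pos - 1]
        assert fields[3] == anchor
        assert all(alt.startswith(anchor) for alt in fields[4].split(","))
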