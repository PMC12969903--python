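"""Bubble detection on reference-anchored walks, per-sample allele
calling, length-rule SV classification, summary tables and VCF output.

A *bubble* is a maximal interval of the reference walk where at least one
assembly walk departs between a shared preceding segment (the source
anchor) and the next shared segment (the sink anchor).  Comparing walks
replaces graph realignment: each assembly's sub-walk between the anchors
spells one allele of the bubble, the reference sub-walk spells allele 0.

Classification follows allele-length rules on biallelic records:

==================  =========================  =========================
class               reference allele length    alternate allele length
==================  =========================  =========================
strict_insertion    0                          any
relaxed_insertion   1-5                        >= 50
strict_deletion     any                        0
relaxed_deletion    >= 50                      1-5
other               everything else (both alleles non-zero length)
==================  =========================  =========================

Multi-allelic records take an insertion/deletion class only when every
alternate satisfies the same rule; otherwise they are ``other``.  Only
records whose longest allele is at least ``min_len`` (default 50 nt)
are emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .graph_core import AssemblyPath, PangenomeGraph, Walk, _natural_key

logger = logging.getLogger(__name__)

DEFAULT_MIN_SV_LEN = 50


class InvalidRecordError(ValueError):
    pass


@dataclass
class Bubble:
    chrom: str
    source: str  # anchor segment id on the reference walk
    sink: str
    ref_segments: tuple[str, ...]
    ref_seq: str
    alt_traversals: list[tuple[tuple[str, ...], str]]  # (segment ids, spelled sequence)
    start0: int  # 0-based half-open varying interval on the reference
    end0: int

    @property
    def pos(self) -> int:
        """1-based position: left-anchor base for pure insertions, first
        varying base otherwise."""
        return self.start0 if not self.ref_seq else self.start0 + 1

    def alleles(self) -> list[str]:
        return [self.ref_seq] + [seq for _, seq in self.alt_traversals]


@dataclass
class SVRecord:
    chrom: str
    pos: int
    start0: int
    end0: int
    ref: str
    alts: tuple[str, ...]
    allele_class: str
    zygosity_class: str  # biallelic | multiallelic
    genotypes: dict[str, int | None] = field(default_factory=dict)
    alt_segments: tuple[tuple[str, ...], ...] = ()

    @property
    def max_allele_len(self) -> int:
        return max(len(self.ref), max(len(a) for a in self.alts))


# ---------------------------------------------------------------------------
# bubble detection
# ---------------------------------------------------------------------------

def find_bubbles(
    graph: PangenomeGraph, assembly_paths: Sequence[AssemblyPath]
) -> list[Bubble]:
    """Detect bubbles by comparing each assembly walk to the reference walk.

    For every maximal reference-walk interval where any walk departs, one
    bubble is emitted with all distinct alternate spellings observed.
    Walks sharing no anchor segments with the reference are skipped with
    a warning.
    """
    bubbles: list[Bubble] = []
    for chrom in sorted(graph.reference_path, key=_natural_key):
        ref_walk = graph.reference_path[chrom]
        ref_ids = [sid for sid, _ in ref_walk]
        ref_index = {sid: i for i, sid in enumerate(ref_ids)}
        offsets = np.zeros(len(ref_ids) + 1, dtype=np.int64)
        for i, sid in enumerate(ref_ids):
            offsets[i + 1] = offsets[i] + graph.segments[sid].length

        intervals: set[tuple[int, int]] = set()
        subwalks: dict[str, list[tuple[int, int, Walk]]] = {}
        for ap in assembly_paths:
            walk = ap.walks.get(chrom)
            if not walk:
                continue
            anchors = [
                (wi, ref_index[sid]) for wi, (sid, _) in enumerate(walk) if sid in ref_index
            ]
            if not anchors:
                logger.warning(
                    "assembly %s shares no anchors with the reference on %s; skipped",
                    ap.sample,
                    chrom,
                )
                continue
            sample_divs = []
            for (wi, ri), (wj, rj) in zip(anchors, anchors[1:]):
                if rj != ri + 1 or wj != wi + 1:
                    intervals.add((ri, rj))
                    sample_divs.append((ri, rj, walk[wi + 1 : wj]))
            subwalks[ap.sample] = sample_divs

        for ri, rj in _merge_intervals(intervals):
            ref_segments = tuple(ref_ids[ri + 1 : rj])
            ref_seq = graph.spell(ref_walk[ri + 1 : rj])
            start0 = int(offsets[ri + 1])
            end0 = int(offsets[rj])
            bubble = Bubble(
                chrom=chrom,
                source=ref_ids[ri],
                sink=ref_ids[rj],
                ref_segments=ref_segments,
                ref_seq=ref_seq,
                alt_traversals=[],
                start0=start0,
                end0=end0,
            )
            seen = {ref_seq}
            for ap in assembly_paths:
                for a, b, sub in subwalks.get(ap.sample, ()):  # walks inside this bubble
                    if ri <= a and b <= rj:
                        seq = graph.spell(sub)
                        if seq not in seen:
                            seen.add(seq)
                            bubble.alt_traversals.append((tuple(s for s, _ in sub), seq))
            bubbles.append(bubble)
    bubbles.sort(key=lambda b: (_natural_key(b.chrom), b.start0))
    return bubbles


def _merge_intervals(intervals: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of open intervals on reference-walk indices; intervals that
    merely share an endpoint stay separate."""
    merged: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if merged and a < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def call_alleles(
    bubble: Bubble,
    assembly_paths: Sequence[AssemblyPath],
    graph: PangenomeGraph | None = None,
) -> dict[str, int | None]:
    """Per-sample allele index through a bubble (0 = reference).

    Samples whose walk does not span source -> sink on the bubble's
    chromosome are called missing.  A walk spelling an allele not yet in
    the bubble's list appends it (discovery) and returns its index;
    spelling a novel traversal requires ``graph``.
    """
    calls: dict[str, int | None] = {}
    for ap in assembly_paths:
        walk = ap.walks.get(bubble.chrom)
        if not walk:
            calls[ap.sample] = None
            continue
        ids = [sid for sid, _ in walk]
        try:
            i = ids.index(bubble.source)
            j = ids.index(bubble.sink, i + 1)
        except ValueError:
            calls[ap.sample] = None
            continue
        sub = walk[i + 1 : j]
        seq = _spell_sub(bubble, sub, graph)
        alleles = bubble.alleles()
        if seq in alleles:
            calls[ap.sample] = alleles.index(seq)
        else:
            bubble.alt_traversals.append((tuple(sid for sid, _ in sub), seq))
            calls[ap.sample] = len(bubble.alt_traversals)
    return calls


def _spell_sub(bubble: Bubble, sub: Walk, graph: PangenomeGraph | None) -> str:
    key = tuple(sid for sid, _ in sub)
    if key == bubble.ref_segments:
        return bubble.ref_seq
    for segs, seq in bubble.alt_traversals:
        if segs == key:
            return seq
    if graph is not None:
        return graph.spell(sub)
    raise InvalidRecordError(
        f"walk spells an unknown traversal {key} in bubble "
        f"{bubble.chrom}:{bubble.pos}; pass graph= to spell novel alleles"
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _biallelic_class(ref_len: int, alt_len: int) -> str:
    if ref_len == 0 and alt_len == 0:
        raise InvalidRecordError("both alleles empty")
    if ref_len == 0:
        return "strict_insertion"
    if 1 <= ref_len <= 5 and alt_len >= 50:
        return "relaxed_insertion"
    if alt_len == 0:
        return "strict_deletion"
    if 1 <= alt_len <= 5 and ref_len >= 50:
        return "relaxed_deletion"
    return "other"


def classify_sv(ref: str, alts: Sequence[str]) -> tuple[str, str]:
    """(allele_class, zygosity_class) from allele lengths alone."""
    if not alts:
        raise InvalidRecordError("at least one alternate allele is required")
    classes = [_biallelic_class(len(ref), len(a)) for a in alts]
    if len(alts) == 1:
        return classes[0], "biallelic"
    allele_class = classes[0] if len(set(classes)) == 1 else "other"
    return allele_class, "multiallelic"


def records_from_bubbles(
    bubbles: Sequence[Bubble],
    assembly_paths: Sequence[AssemblyPath],
    min_len: int = DEFAULT_MIN_SV_LEN,
) -> list[SVRecord]:
    """Call alleles in every bubble, classify, apply the SV length floor
    (max allele length >= ``min_len``) and sort records."""
    records = []
    for bubble in bubbles:
        genotypes = call_alleles(bubble, assembly_paths)
        alts = tuple(seq for _, seq in bubble.alt_traversals)
        if not alts:
            continue
        allele_class, zygosity = classify_sv(bubble.ref_seq, alts)
        rec = SVRecord(
            chrom=bubble.chrom,
            pos=bubble.pos,
            start0=bubble.start0,
            end0=bubble.end0,
            ref=bubble.ref_seq,
            alts=alts,
            allele_class=allele_class,
            zygosity_class=zygosity,
            genotypes=genotypes,
            alt_segments=tuple(segs for segs, _ in bubble.alt_traversals),
        )
        if rec.max_allele_len >= min_len:
            records.append(rec)
    records.sort(
        key=lambda r: (
            _natural_key(r.chrom),
            r.pos,
            len(r.ref),
            r.alts[0],
        )
    )
    return records


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

_ROW_OF = {
    "strict_insertion": "insertion",
    "relaxed_insertion": "insertion",
    "strict_deletion": "deletion",
    "relaxed_deletion": "deletion",
    "other": "other",
}


def sv_table(records: Sequence[SVRecord]) -> pd.DataFrame:
    """Counts by SV type x allele count, in the layout of a
    type-by-zygosity distribution table: rows insertion / deletion /
    other / total; columns biallelic (with strict and relaxed
    sub-columns), multiallelic, total."""
    rows = ["insertion", "deletion", "other"]
    table = pd.DataFrame(
        0,
        index=rows + ["total"],
        columns=["biallelic", "biallelic_strict", "biallelic_relaxed", "multiallelic", "total"],
    )
    for rec in records:
        row = _ROW_OF[rec.allele_class]
        if rec.zygosity_class == "biallelic":
            table.loc[row, "biallelic"] += 1
            if rec.allele_class.startswith("strict"):
                table.loc[row, "biallelic_strict"] += 1
            elif rec.allele_class.startswith("relaxed"):
                table.loc[row, "biallelic_relaxed"] += 1
        else:
            table.loc[row, "multiallelic"] += 1
        table.loc[row, "total"] += 1
    table.loc["total"] = table.loc[rows].sum(axis=0)
    return table


def sv_table_from_counts(counts: dict[tuple[str, str], int]) -> pd.DataFrame:
    """Same layout as :func:`sv_table` from precomputed
    (allele_class, zygosity_class) -> count data, for checking published
    marginal arithmetic."""
    records = []
    for (allele_class, zygosity), n in counts.items():
        records.extend(
            [
                SVRecord(
                    chrom="x",
                    pos=1,
                    start0=0,
                    end0=0,
                    ref="" if "insertion" in allele_class else "N" * 60,
                    alts=("N" * 60,) if "insertion" in allele_class else ("",),
                    allele_class=allele_class,
                    zygosity_class=zygosity,
                )
            ]
            * n
        )
    return sv_table(records)


def size_spectrum(records: Sequence[SVRecord], bin_width: int = 50) -> pd.DataFrame:
    """Histogram of insertion (longest alt - ref) and deletion
    (ref - shortest alt) lengths; bins are [k*w, (k+1)*w)."""
    ins_lengths, del_lengths = [], []
    for rec in records:
        row = _ROW_OF[rec.allele_class]
        if row == "insertion":
            ins_lengths.append(max(len(a) for a in rec.alts) - len(rec.ref))
        elif row == "deletion":
            del_lengths.append(len(rec.ref) - min(len(a) for a in rec.alts))
    if not ins_lengths and not del_lengths:
        return pd.DataFrame(columns=["bin_start", "insertions", "deletions"]).astype(int)
    top = max(ins_lengths + del_lengths)
    edges = np.arange(0, top + 2 * bin_width, bin_width)
    ins_counts, _ = np.histogram(ins_lengths, bins=edges)
    del_counts, _ = np.histogram(del_lengths, bins=edges)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1].astype(int),
            "insertions": ins_counts.astype(int),
            "deletions": del_counts.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(
    records: Sequence[SVRecord],
    samples: Sequence[str],
    path: str,
    reference: dict[str, str] | None = None,
    contigs: dict[str, int] | None = None,
) -> None:
    """VCF 4.2 with explicit alleles and haploid per-sample GT (each
    assembly is one haplotype).

    Empty alleles receive standard left-anchor padding: the record is
    emitted at the base before the event with that base prepended to
    every allele.  The anchor base comes from ``reference`` when given,
    otherwise ``N``.
    """
    recs = list(records)
    if any(
        (a.chrom, a.pos) > (b.chrom, b.pos) for a, b in zip(recs, recs[1:])
    ):
        logger.warning("records were not sorted; sorting before writing")
        recs.sort(key=lambda r: (_natural_key(r.chrom), r.pos, len(r.ref), r.alts[0]))
    lines = ["##fileformat=VCFv4.2", "##source=pangsv"]
    if contigs:
        for chrom in sorted(contigs, key=_natural_key):
            lines.append(f"##contig=<ID={chrom},length={contigs[chrom]}>")
    else:
        for chrom in sorted({r.chrom for r in recs}, key=_natural_key):
            lines.append(f"##contig=<ID={chrom}>")
    lines += [
        '##INFO=<ID=SVCLASS,Number=1,Type=String,Description="Allele-length SV class">',
        '##INFO=<ID=ZYG,Number=1,Type=String,Description="biallelic or multiallelic">',
        '##INFO=<ID=SVLEN,Number=A,Type=Integer,Description="Alt length minus ref length">',
        '##INFO=<ID=PAD,Number=0,Type=Flag,Description="Alleles carry a left anchor base">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for i, rec in enumerate(recs, start=1):
        needs_pad = len(rec.ref) == 0 or any(len(a) == 0 for a in rec.alts)
        if needs_pad:
            vcf_pos = rec.start0  # 1-based position of the base before the event
            anchor = (
                reference[rec.chrom][rec.start0 - 1]
                if reference is not None and rec.start0 >= 1
                else "N"
            )
            ref_out = anchor + rec.ref
            alts_out = [anchor + a for a in rec.alts]
        else:
            vcf_pos = rec.start0 + 1
            ref_out = rec.ref
            alts_out = list(rec.alts)
        svlen = ",".join(str(len(a) - len(rec.ref)) for a in rec.alts)
        info = f"SVCLASS={rec.allele_class};ZYG={rec.zygosity_class};SVLEN={svlen}"
        if needs_pad:
            info += ";PAD"
        gts = [
            "." if rec.genotypes.get(s) is None else str(rec.genotypes[s]) for s in samples
        ]
        lines.append(
            f"{rec.chrom}\t{vcf_pos}\tsv{i}\t{ref_out}\t{','.join(alts_out)}"
            f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gts)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> tuple[list[SVRecord], list[str]]:
    """Read a VCF written by :func:`write_vcf` back into records,
    stripping anchor padding."""
    import pysam

    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    records = []
    for v in vf:
        ref = v.ref or ""
        alts = list(v.alts or ())
        info_class = v.info.get("SVCLASS")
        info_zyg = v.info.get("ZYG")
        if v.info.get("PAD", False):
            start0 = v.pos  # padded records sit at the base before the event
            ref_core = ref[1:]
            alts_core = tuple(a[1:] for a in alts)
        else:
            start0 = v.pos - 1
            ref_core = ref
            alts_core = tuple(alts)
        pos = start0 if not ref_core else start0 + 1
        genotypes: dict[str, int | None] = {}
        for s in samples:
            gt = v.samples[s].get("GT")
            allele = gt[0] if gt else None
            genotypes[s] = None if allele is None else int(allele)
        records.append(
            SVRecord(
                chrom=v.chrom,
                pos=pos,
                start0=start0,
                end0=start0 + len(ref_core),
                ref=ref_core,
                alts=alts_core,
                allele_class=str(info_class),
                zygosity_class=str(info_zyg),
                genotypes=genotypes,
            )
        )
    return records, samples
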