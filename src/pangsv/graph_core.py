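"""Pangenome graph containers, GFA 1.0 / path-file IO, and the
core / flexible / untraversed segment partition.

The graph model is deliberately minimal: segments (nodes) carrying their
nucleotide sequence, oriented links (edges), and one designated reference
walk per chromosome.  Assembly haplotypes are represented as ordered,
oriented walks over the segments ("paths"), one walk per chromosome.

A segment is *core* when every traversal (the reference walk plus every
assembly walk) visits it, *flexible* when at least one but not all
traversals visit it, and *untraversed* when no traversal visits it.
Untraversed segments typically sit inside highly nested bubbles and are
excluded from downstream variant analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GraphFormatError(ValueError):
    """Malformed GFA or path file."""


class PreconditionError(ValueError):
    """An operation was called on inputs that violate its contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

Step = tuple[str, str]  # (segment id, '+'/'-')
Walk = list[Step]


@dataclass
class Segment:
    """A graph node: an identifier plus its nucleotide sequence.

    ``tags`` carries optional rGFA-style origin metadata (SN/SO/SR),
    passed through verbatim on write.
    """

    id: str
    sequence: str
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PangenomeGraph:
    segments: dict[str, Segment] = field(default_factory=dict)
    links: set[tuple[str, str, str, str]] = field(default_factory=set)
    # chromosome name -> ordered reference walk
    reference_path: dict[str, Walk] = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def total_bases(self) -> int:
        return sum(s.length for s in self.segments.values())

    def add_segment(self, seg: Segment) -> None:
        if seg.id in self.segments:
            raise GraphFormatError(f"duplicate segment id {seg.id!r}")
        if seg.length < 1:
            raise GraphFormatError(f"segment {seg.id!r} has empty sequence")
        self.segments[seg.id] = seg

    def add_link(self, a: str, ao: str, b: str, bo: str) -> None:
        for sid in (a, b):
            if sid not in self.segments:
                raise GraphFormatError(f"link endpoint {sid!r} is not a declared segment")
        self.links.add((a, ao, b, bo))

    def spell(self, walk: Iterable[Step]) -> str:
        """Concatenate the oriented sequences along a walk."""
        parts = []
        for sid, orient in walk:
            seq = self.segments[sid].sequence
            parts.append(seq if orient == "+" else reverse_complement(seq))
        return "".join(parts)


@dataclass
class AssemblyPath:
    """One haplotype assembly's walk through the graph, per chromosome."""

    sample: str
    breed: str
    walks: dict[str, Walk] = field(default_factory=dict)


@dataclass
class SegmentPartition:
    core: frozenset[str]
    flexible: frozenset[str]
    untraversed: frozenset[str]
    node_counts: dict[str, int]
    base_totals: dict[str, int]


# ---------------------------------------------------------------------------
# GFA and path-file IO
# ---------------------------------------------------------------------------

def write_gfa(graph: PangenomeGraph, path: str) -> None:
    """Write GFA 1.0: S lines with inline sequences (plus any rGFA tags),
    L lines with 0M overlaps, and one P line per reference chromosome."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for sid in sorted(graph.segments, key=_natural_key):
            seg = graph.segments[sid]
            tags = "".join(
                f"\t{k}:{'i' if k in ('SO', 'SR') else 'Z'}:{v}" for k, v in sorted(seg.tags.items())
            )
            fh.write(f"S\t{sid}\t{seg.sequence}{tags}\n")
        for a, ao, b, bo in sorted(graph.links):
            fh.write(f"L\t{a}\t{ao}\t{b}\t{bo}\t0M\n")
        for chrom in sorted(graph.reference_path, key=_natural_key):
            steps = ",".join(f"{sid}{o}" for sid, o in graph.reference_path[chrom])
            fh.write(f"P\t{chrom}\t{steps}\t*\n")


def parse_gfa(path: str) -> PangenomeGraph:
    graph = PangenomeGraph()
    pending_links: list[tuple[int, tuple[str, str, str, str]]] = []
    pending_paths: list[tuple[int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("H") or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "S":
                if len(fields) < 3:
                    raise GraphFormatError(f"line {lineno}: truncated S line")
                tags = {}
                for tag in fields[3:]:
                    name, _typ, value = tag.split(":", 2)
                    tags[name] = value
                graph.add_segment(Segment(fields[1], fields[2], tags))
            elif kind == "L":
                if len(fields) < 5:
                    raise GraphFormatError(f"line {lineno}: truncated L line")
                pending_links.append((lineno, (fields[1], fields[2], fields[3], fields[4])))
            elif kind == "P":
                if len(fields) < 3:
                    raise GraphFormatError(f"line {lineno}: truncated P line")
                pending_paths.append((lineno, fields[1], fields[2]))
    for lineno, (a, ao, b, bo) in pending_links:
        try:
            graph.add_link(a, ao, b, bo)
        except GraphFormatError as exc:
            raise GraphFormatError(f"line {lineno}: {exc}") from None
    for lineno, chrom, steps in pending_paths:
        walk = _parse_steps(steps)
        for sid, _ in walk:
            if sid not in graph.segments:
                raise GraphFormatError(
                    f"line {lineno}: path {chrom!r} references undeclared segment {sid!r}"
                )
        graph.reference_path[chrom] = walk
    return graph


def _parse_steps(text: str) -> Walk:
    walk: Walk = []
    for step in text.split(","):
        step = step.strip()
        if not step:
            continue
        sid, orient = step[:-1], step[-1]
        if orient not in "+-" or not sid:
            raise GraphFormatError(f"malformed walk step {step!r}")
        walk.append((sid, orient))
    return walk


def write_paths(paths: Sequence[AssemblyPath], directory: str) -> list[str]:
    """One tab-separated file per assembly: ``chrom <TAB> s1+,s2+,...``
    with ``#sample=`` / ``#breed=`` header lines."""
    import os

    written = []
    for ap in paths:
        fname = os.path.join(directory, f"{ap.sample}.paths.tsv")
        with open(fname, "w") as fh:
            fh.write(f"#sample={ap.sample}\n#breed={ap.breed}\n")
            for chrom in sorted(ap.walks, key=_natural_key):
                steps = ",".join(f"{sid}{o}" for sid, o in ap.walks[chrom])
                fh.write(f"{chrom}\t{steps}\n")
        written.append(fname)
    return written


def parse_path_file(path: str, graph: PangenomeGraph | None = None) -> AssemblyPath:
    sample = breed = ""
    walks: dict[str, Walk] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key == "sample":
                    sample = value
                elif key == "breed":
                    breed = value
                continue
            chrom, _, steps = line.partition("\t")
            walk = _parse_steps(steps)
            if graph is not None:
                for sid, _ in walk:
                    if sid not in graph.segments:
                        raise GraphFormatError(
                            f"{path}:{lineno}: walk references undeclared segment {sid!r}"
                        )
            walks[chrom] = walk
    import os

    if not sample:
        sample = os.path.basename(path).replace(".paths.tsv", "")
    return AssemblyPath(sample=sample, breed=breed, walks=walks)


def parse_graph(
    gfa_path: str, path_files: Sequence[str]
) -> tuple[PangenomeGraph, list[AssemblyPath]]:
    """Read a GFA plus its sidecar assembly path files, validating that
    every walk step references a declared segment."""
    graph = parse_gfa(gfa_path)
    paths = [parse_path_file(p, graph) for p in path_files]
    return graph, paths


# ---------------------------------------------------------------------------
# partition and statistics
# ---------------------------------------------------------------------------

def _traversed_sets(
    graph: PangenomeGraph,
    paths: Sequence[AssemblyPath],
    chromosomes: Iterable[str] | None = None,
) -> list[set[str]]:
    allow = set(chromosomes) if chromosomes is not None else None
    out: list[set[str]] = []
    ref: set[str] = set()
    for chrom, walk in graph.reference_path.items():
        if allow is None or chrom in allow:
            ref.update(sid for sid, _ in walk)
    out.append(ref)
    for ap in paths:
        seen: set[str] = set()
        for chrom, walk in ap.walks.items():
            if allow is None or chrom in allow:
                seen.update(sid for sid, _ in walk)
        out.append(seen)
    return out


def partition_segments(
    graph: PangenomeGraph,
    paths: Sequence[AssemblyPath],
    chromosomes: Iterable[str] | None = None,
) -> SegmentPartition:
    """Partition segments into core / flexible / untraversed.

    The reference walk counts as one traversal alongside every assembly
    walk; membership ignores orientation.  ``chromosomes`` optionally
    restricts the traversals to an allow-list (e.g. autosomes only) —
    segments are still all partitioned, but only allowed chromosomes
    contribute traversal evidence.
    """
    if not paths:
        raise PreconditionError("partition requires at least one assembly path")
    traversals = _traversed_sets(graph, paths, chromosomes)
    n = len(traversals)
    counts: dict[str, int] = {sid: 0 for sid in graph.segments}
    for seen in traversals:
        for sid in seen:
            if sid in counts:
                counts[sid] += 1
    core = frozenset(sid for sid, c in counts.items() if c == n)
    untraversed = frozenset(sid for sid, c in counts.items() if c == 0)
    flexible = frozenset(sid for sid, c in counts.items() if 0 < c < n)
    node_counts = {
        "core": len(core),
        "flexible": len(flexible),
        "untraversed": len(untraversed),
    }
    base_totals = {
        "core": sum(graph.segments[s].length for s in core),
        "flexible": sum(graph.segments[s].length for s in flexible),
        "untraversed": sum(graph.segments[s].length for s in untraversed),
    }
    return SegmentPartition(core, flexible, untraversed, node_counts, base_totals)


def graph_stats(
    graph: PangenomeGraph,
    paths: Sequence[AssemblyPath],
    chromosomes: Iterable[str] | None = None,
) -> dict:
    """Summary statistics: node/edge counts, total bases, and the
    per-class breakdown.  Untraversed segment ids are listed so that
    downstream stages can exclude them."""
    if graph.n_segments == 0:
        return {
            "n_nodes": 0,
            "n_edges": 0,
            "total_bases": 0,
            "node_counts": {"core": 0, "flexible": 0, "untraversed": 0},
            "base_totals": {"core": 0, "flexible": 0, "untraversed": 0},
            "excluded_untraversed": [],
        }
    part = partition_segments(graph, paths, chromosomes)
    return {
        "n_nodes": graph.n_segments,
        "n_edges": graph.n_links,
        "total_bases": graph.total_bases,
        "node_counts": dict(part.node_counts),
        "base_totals": dict(part.base_totals),
        "excluded_untraversed": sorted(part.untraversed, key=_natural_key),
    }


def _natural_key(token: str):
    import re

    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", token)]
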