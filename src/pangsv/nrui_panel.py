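"""Non-reference unique insertions (NRUIs): extraction, panel merging,
presence/absence genotyping, frequency summaries and breed clustering.

An NRUI is a biallelic insertion whose reference allele is empty and
whose inserted sequence exceeds 50 nt, carried by graph segments that are
traversed by at least one assembly (not nested/untraversed) and absent
from the reference walk.  Genotyping an assembly for an NRUI reduces to
asking whether its walk traverses the insertion's segment(s), which
yields a binary presence/absence (PAV) matrix over assemblies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .bubble_sv import Bubble, call_alleles
from .graph_core import AssemblyPath, PangenomeGraph, SegmentPartition, _natural_key

logger = logging.getLogger(__name__)

NRUI_MIN_LEN = 50  # inserted sequence must EXCEED this many nucleotides


@dataclass
class NRUIRecord:
    id: str
    chrom: str
    pos: int  # 1-based base immediately left of the insertion
    sequence: str
    panel: str  # provenance tag
    carriers: frozenset[str]
    alt_segments: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_nruis(
    graph: PangenomeGraph,
    bubbles: Sequence[Bubble],
    partition: SegmentPartition,
    assembly_paths: Sequence[AssemblyPath],
    panel: str = "panel_a",
    min_len: int = NRUI_MIN_LEN,
) -> list[NRUIRecord]:
    """Three-filter NRUI extraction.

    1. insertion segments traversed by no assembly (nested nodes) are
       excluded;
    2. segments on the reference walk are excluded;
    3. biallelic bubbles with an empty reference allele and an alternate
       allele exceeding ``min_len`` nucleotides are retained.
    """
    ref_segments = {
        sid for walk in graph.reference_path.values() for sid, _ in walk
    }
    records = []
    for bubble in bubbles:
        if len(bubble.alt_traversals) != 1:
            continue
        segs, seq = bubble.alt_traversals[0]
        if bubble.ref_seq != "" or len(seq) <= min_len:
            continue
        if any(sid in partition.untraversed for sid in segs):
            continue  # filter 1: nested, untraversed insertion
        if any(sid in ref_segments for sid in segs):
            continue  # filter 2: sequence already on the reference walk
        calls = call_alleles(bubble, assembly_paths, graph)
        carriers = frozenset(s for s, a in calls.items() if a == 1)
        if not carriers:
            continue
        records.append(
            NRUIRecord(
                id=f"{bubble.chrom}_{bubble.pos}_{len(seq)}",
                chrom=bubble.chrom,
                pos=bubble.pos,
                sequence=seq,
                panel=panel,
                carriers=carriers,
                alt_segments=segs,
            )
        )
    records.sort(key=lambda r: (_natural_key(r.chrom), r.pos))
    return records


# ---------------------------------------------------------------------------
# panel merging
# ---------------------------------------------------------------------------

def merge_panels(
    panel_a: Sequence[NRUIRecord],
    panel_b: Sequence[NRUIRecord],
    max_shift: int = 50,
    reciprocal_overlap: float = 0.90,
) -> tuple[list[NRUIRecord], dict]:
    """Merge two NRUI panels on shared reference coordinates.

    Records with identical (chrom, position) and equal length collapse to
    one (``common-identical``); otherwise records anchored within
    ``max_shift`` bp whose insertion lengths reciprocally overlap by at
    least ``reciprocal_overlap`` collapse to panel_a's representative
    (``common-overlap``).  Everything else passes through tagged with its
    source panel.  Returns (merged records, statistics).
    """
    from bisect import bisect_left, bisect_right

    merged: list[NRUIRecord] = []
    matched_b: set[int] = set()
    n_identical = 0
    n_overlap = 0

    exact_index: dict[tuple[str, int, int], list[int]] = {}
    b_positions: dict[str, list[tuple[int, int]]] = {}
    for bi, r in enumerate(panel_b):
        exact_index.setdefault((r.chrom, r.pos, r.length), []).append(bi)
        b_positions.setdefault(r.chrom, []).append((r.pos, bi))
    for chrom in b_positions:
        b_positions[chrom].sort()

    out_a: list[NRUIRecord] = []
    for r in panel_a:
        tag = r.panel
        exact = next(
            (bi for bi in exact_index.get((r.chrom, r.pos, r.length), ()) if bi not in matched_b),
            None,
        )
        if exact is not None:
            matched_b.add(exact)
            n_identical += 1
            tag = "common-identical"
        else:
            nearby = b_positions.get(r.chrom, [])
            lo = bisect_left(nearby, (r.pos - max_shift, -1))
            hi = bisect_right(nearby, (r.pos + max_shift, len(panel_b)))
            for _, bi in nearby[lo:hi]:
                if bi in matched_b:
                    continue
                rb = panel_b[bi]
                small, big = sorted((rb.length, r.length))
                if big > 0 and small / big >= reciprocal_overlap:
                    matched_b.add(bi)
                    n_overlap += 1
                    tag = "common-overlap"
                    break
        out_a.append(
            NRUIRecord(
                id=r.id,
                chrom=r.chrom,
                pos=r.pos,
                sequence=r.sequence,
                panel=tag,
                carriers=r.carriers,
                alt_segments=r.alt_segments,
            )
        )
    merged.extend(out_a)
    for bi, r in enumerate(panel_b):
        if bi not in matched_b:
            merged.append(r)
    merged.sort(key=lambda r: (_natural_key(r.chrom), r.pos))
    n_common = n_identical + n_overlap
    stats = {
        "n_a": len(panel_a),
        "n_b": len(panel_b),
        "n_common": n_common,
        "n_common_identical": n_identical,
        "n_common_overlap": n_overlap,
        "identical_fraction": (n_identical / n_common) if n_common else float("nan"),
        "n_merged": len(merged),
    }
    assert stats["n_merged"] == stats["n_a"] + stats["n_b"] - n_common
    return merged, stats


# ---------------------------------------------------------------------------
# PAV genotyping
# ---------------------------------------------------------------------------

def genotype_pav(
    panel: Sequence[NRUIRecord], assembly_paths: Sequence[AssemblyPath]
) -> pd.DataFrame:
    """Binary presence/absence matrix: rows = assemblies, columns = NRUI
    ids; 1 when the assembly walk traverses every insertion segment of
    the NRUI, NaN when the assembly lacks the chromosome.  NRUIs with no
    recorded graph segments are dropped with a warning."""
    usable = []
    for r in panel:
        if r.alt_segments:
            usable.append(r)
        else:
            logger.warning("NRUI %s has no graph segment mapping; column dropped", r.id)
    matrix = pd.DataFrame(
        index=[ap.sample for ap in assembly_paths],
        columns=[r.id for r in usable],
        dtype=float,
    )
    for ap in assembly_paths:
        seg_sets = {
            chrom: {sid for sid, _ in walk} for chrom, walk in ap.walks.items()
        }
        for r in usable:
            if r.chrom not in seg_sets:
                matrix.loc[ap.sample, r.id] = np.nan
            else:
                matrix.loc[ap.sample, r.id] = float(
                    all(sid in seg_sets[r.chrom] for sid in r.alt_segments)
                )
    return matrix


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def frequency_summary(
    matrix: pd.DataFrame,
    breed_map: Mapping[str, str],
    panel: Sequence[NRUIRecord] | None = None,
    low_threshold: float = 0.05,
    high_threshold: float = 0.99,
) -> dict:
    """Per-NRUI frequency spectrum, rare/near-fixed counts and the
    private-per-breed table.

    Frequencies are carriers over non-missing assemblies (haplotypes).
    An NRUI is private when it has at least one carrier and all carriers
    belong to one breed.
    """
    if matrix.empty:
        return {
            "frequencies": pd.Series(dtype=float),
            "n_low": 0,
            "n_near_fixed": 0,
            "private": pd.DataFrame(columns=["nrui", "breed", "length"]),
            "private_per_breed": pd.DataFrame(columns=["n", "bases"]),
        }
    freqs = matrix.mean(axis=0, skipna=True)
    lengths = {r.id: r.length for r in panel} if panel is not None else {}
    breeds = pd.Series({s: breed_map.get(s, "?") for s in matrix.index})
    private_rows = []
    for col in matrix.columns:
        carriers = matrix.index[matrix[col] == 1.0]
        if len(carriers) == 0:
            continue
        carrier_breeds = set(breeds.loc[carriers])
        if len(carrier_breeds) == 1:
            private_rows.append(
                {
                    "nrui": col,
                    "breed": next(iter(carrier_breeds)),
                    "length": lengths.get(col, np.nan),
                }
            )
    private = pd.DataFrame(private_rows, columns=["nrui", "breed", "length"])
    per_breed = (
        private.groupby("breed").agg(n=("nrui", "size"), bases=("length", "sum"))
        if not private.empty
        else pd.DataFrame(columns=["n", "bases"])
    )
    return {
        "frequencies": freqs,
        "n_low": int((freqs <= low_threshold).sum()),
        "n_near_fixed": int((freqs >= high_threshold).sum()),
        "private": private,
        "private_per_breed": per_breed,
    }


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    flat: pd.Series | None
    crosstab: pd.DataFrame | None
    newick: str


def cluster_assemblies(
    matrix: pd.DataFrame,
    k: int | None = None,
    breed_map: Mapping[str, str] | None = None,
) -> ClusterResult:
    """Agglomerative clustering of assemblies on the PAV matrix:
    Jaccard distance on binary columns, average (UPGMA) linkage.
    Missing cells are treated as absence for the distance computation."""
    if matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ValueError("clustering needs >= 2 assemblies and >= 1 NRUI column")
    X = matrix.fillna(0.0).to_numpy(dtype=bool)
    dist = pdist(X, metric="jaccard")
    dist = np.nan_to_num(dist, nan=0.0)  # identical all-zero rows
    Z = hierarchy.linkage(dist, method="average")
    labels = list(matrix.index)
    flat = None
    crosstab = None
    if k is not None:
        assignments = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        flat = pd.Series(assignments, index=labels, name="cluster")
        if breed_map is not None:
            crosstab = pd.crosstab(
                flat, pd.Series({s: breed_map.get(s, "?") for s in labels})
            )
    newick = _to_newick(hierarchy.to_tree(Z), labels)
    return ClusterResult(linkage=Z, labels=labels, flat=flat, crosstab=crosstab, newick=newick)


def cophenetic_matrix(result: ClusterResult) -> pd.DataFrame:
    coph = hierarchy.cophenet(result.linkage)
    return pd.DataFrame(
        squareform(coph), index=result.labels, columns=result.labels
    )


def _to_newick(node, labels: list[str]) -> str:
    def walk(n, parent_height: float) -> str:
        length = parent_height - n.dist
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.6g}"
        left = walk(n.left, n.dist)
        right = walk(n.right, n.dist)
        return f"({left},{right}):{length:.6g}"

    if node.is_leaf():
        return f"{labels[node.id]};"
    left = walk(node.left, node.dist)
    right = walk(node.right, node.dist)
    return f"({left},{right});"


# ---------------------------------------------------------------------------
# IO helpers
# ---------------------------------------------------------------------------

def panel_to_frame(panel: Sequence[NRUIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "chrom": r.chrom,
                "pos": r.pos,
                "length": r.length,
                "panel": r.panel,
                "carriers": ";".join(sorted(r.carriers)),
            }
            for r in panel
        ],
        columns=["id", "chrom", "pos", "length", "panel", "carriers"],
    )


def write_panel_fasta(panel: Sequence[NRUIRecord], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in panel:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")
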