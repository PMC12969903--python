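"""Genomic-context assignment for NRUIs and interval-set enrichment.

Context is assigned at the insertion point (a single reference base,
since an NRUI occupies zero reference bases) with precedence
CDS > UTR > exon > intron > intergenic, where *intron* means inside a
gene span without touching any exon, and the two UTR kinds are reported
as one category.

Enrichment of NRUIs in an interval set (a QTL trait, a functional term)
uses a hypergeometric upper-tail test on genomic bins: with the genome
cut into N fixed-width bins of which K overlap the term's intervals,
observing k of n NRUIs inside the term is scored as
P(X >= k), X ~ Hypergeom(N, K, n).  P-values are Benjamini-Hochberg
adjusted across terms; a term is enriched when the adjusted p-value
falls below the threshold (default 0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONTEXT_PRECEDENCE = ("CDS", "UTR", "exon", "intron", "intergenic")
_UTR_KINDS = {"five_prime_utr", "three_prime_utr", "UTR"}
DEFAULT_FDR = 0.001
DEFAULT_BIN_WIDTH = 200


# ---------------------------------------------------------------------------
# feature loading
# ---------------------------------------------------------------------------

def load_gtf(path: str) -> pd.DataFrame:
    """Read a GTF (Ensembl dialect) into a feature table with 1-based
    inclusive coordinates and columns chrom/start/end/kind/gene_id."""
    import pyranges as pr

    gr = pr.read_gtf(path)
    df = gr.df
    out = pd.DataFrame(
        {
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int) + 1,  # pyranges stores 0-based starts
            "end": df["End"].astype(int),
            "kind": df["Feature"].astype(str),
            "gene_id": df["gene_id"].astype(str) if "gene_id" in df else "",
        }
    )
    return out[out["kind"].isin(["gene", "exon", "CDS", *sorted(_UTR_KINDS)])].reset_index(
        drop=True
    )


class FeatureIndex:
    """Interval trees per (chromosome, feature kind), 1-based inclusive."""

    def __init__(self, features: pd.DataFrame) -> None:
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        for row in features.itertuples(index=False):
            kind = "UTR" if row.kind in _UTR_KINDS else row.kind
            tree = self.trees.setdefault((row.chrom, kind), IntervalTree())
            tree.addi(int(row.start), int(row.end) + 1, row.gene_id)
        self.chroms = {c for c, _ in self.trees}

    def hits(self, chrom: str, pos: int, kind: str) -> list[tuple[int, str]]:
        tree = self.trees.get((chrom, kind))
        if tree is None:
            return []
        return sorted((iv.begin, iv.data) for iv in tree[pos])


# ---------------------------------------------------------------------------
# context assignment
# ---------------------------------------------------------------------------

@dataclass
class ContextAssignment:
    nrui_id: str
    context: str
    gene_ids: tuple[str, ...]


def assign_context(
    nruis: Sequence, features: pd.DataFrame | FeatureIndex
) -> pd.DataFrame:
    """One context per NRUI, tested at its insertion point.

    ``nruis`` may be NRUIRecord-like objects (``id``/``chrom``/``pos``)
    or a DataFrame with those columns.  Chromosomes absent from the
    annotation yield ``intergenic`` with a warning.  Returns a DataFrame
    with nrui_id / context / gene_id (precedence hit, leftmost) /
    gene_ids (all genes spanning the point).
    """
    index = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    if isinstance(nruis, pd.DataFrame):
        items = list(nruis[["id", "chrom", "pos"]].itertuples(index=False))
    else:
        items = [(r.id, r.chrom, r.pos) for r in nruis]
    rows = []
    warned: set[str] = set()
    for nid, chrom, pos in items:
        genes = index.hits(chrom, pos, "gene")
        if chrom not in index.chroms and chrom not in warned and index.trees:
            logger.warning("chromosome %s absent from annotation; intergenic", chrom)
            warned.add(chrom)
        context = "intergenic"
        gene_id = ""
        if genes:
            for kind in ("CDS", "UTR", "exon"):
                hits = index.hits(chrom, pos, kind)
                if hits:
                    context = kind
                    gene_id = hits[0][1]
                    break
            else:
                context = "intron"
                gene_id = genes[0][1]
        rows.append(
            {
                "nrui_id": nid,
                "context": context,
                "gene_id": gene_id,
                "gene_ids": ",".join(sorted({g for _, g in genes})),
            }
        )
    return pd.DataFrame(rows, columns=["nrui_id", "context", "gene_id", "gene_ids"])


def context_counts(assignments: pd.DataFrame) -> pd.Series:
    counts = assignments["context"].value_counts()
    return counts.reindex(CONTEXT_PRECEDENCE, fill_value=0)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) for k successes
    among n draws from a universe of N containing K successes.
    K = 0 yields p = 1 by convention."""
    if K == 0 or k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _term_bins(
    intervals: pd.DataFrame, genome: Mapping[str, int], bin_width: int
) -> dict[str, set[tuple[str, int]]]:
    out: dict[str, set[tuple[str, int]]] = {}
    for row in intervals.itertuples(index=False):
        bins = out.setdefault(row.term, set())
        lo = (int(row.start) - 1) // bin_width
        hi = (int(row.end) - 1) // bin_width
        limit = (genome[row.chrom] - 1) // bin_width
        for b in range(lo, min(hi, limit) + 1):
            bins.add((row.chrom, b))
    return out


def enrich(
    nruis: Sequence,
    terms: pd.DataFrame,
    genome: Mapping[str, int],
    bin_width: int = DEFAULT_BIN_WIDTH,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Hypergeometric enrichment of NRUI insertion points in interval
    sets.

    ``terms`` is a table with columns term/chrom/start/end (1-based
    inclusive; convert BED input first).  ``genome`` maps chromosome to
    length.  The universe is the set of ``bin_width``-sized genomic bins
    (N in total, K overlapping the term); the draw is the NRUI panel
    (n insertions, k inside the term).  Returns one row per term with
    k/K/n/N, raw p, BH-adjusted p and the enriched flag at ``fdr``.
    """
    if isinstance(nruis, pd.DataFrame):
        points = list(nruis[["chrom", "pos"]].itertuples(index=False))
    else:
        points = [(r.chrom, r.pos) for r in nruis]
    n = len(points)
    N = sum((length + bin_width - 1) // bin_width for length in genome.values())
    if N < n:
        raise ValueError("universe smaller than the number of NRUIs; decrease bin_width")
    per_term = _term_bins(terms, genome, bin_width)
    nrui_bins = [(chrom, (int(pos) - 1) // bin_width) for chrom, pos in points]
    rows = []
    for term in sorted(per_term):
        bins = per_term[term]
        K = len(bins)
        k = sum(b in bins for b in nrui_bins)
        rows.append(
            {
                "term": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_pvalue(min(k, K), K, n, N),
            }
        )
    result = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if not result.empty:
        result["p_adj"] = bh_adjust(result["p"])
        result["enriched"] = result["p_adj"] < fdr
    else:
        result["p_adj"] = []
        result["enriched"] = []
    return result
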