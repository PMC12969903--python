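"""Tag-haplotype discovery and genotype-class effect estimation.

Given sequence-resolved carriers (cases) and non-carriers (controls) of a
candidate insertion, the tag search enumerates contiguous marker windows
on phased array genotypes and, per window, every distinct haplotype
allele string, keeping candidates carried by every case (filter 1) and
among them the one carried by the fewest controls (filter 2).  Linkage
between the winning haplotype and the insertion is quantified as the
squared Pearson correlation (r^2) of the two binary carrier vectors.

Effects of the tag haplotype on traits are estimated on yield deviations
(phenotypes pre-adjusted for non-genetic effects) by least squares with
genotype class (0/1/2 copies) and year of birth as categorical fixed
effects; class contrasts are rescaled to genetic standard deviations
(GSD) and compared pairwise with Welch t-tests, Benjamini-Hochberg
adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_enrichment import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BOUNDS = (2, 10)
DEFAULT_MIN_CLASS_SIZE = 30


@dataclass
class PhasedPanel:
    """Phased biallelic marker genotypes: ``haplotypes`` has shape
    (n_animals, 2, n_markers) with alleles coded 0/1."""

    animals: list[str]
    markers: pd.DataFrame  # columns chrom, pos, id
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        n, two, m = self.haplotypes.shape
        if two != 2 or n != len(self.animals) or m != len(self.markers):
            raise ValueError("haplotype array shape does not match animals/markers")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("marker alleles must be coded 0/1")

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def index_of(self, animals: Sequence[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animals)}
        return np.array([lookup[a] for a in animals], dtype=int)

    def to_matrix_tsv(self, path: str) -> None:
        cols = self.markers["id"].tolist()
        rows = []
        for i, animal in enumerate(self.animals):
            for h in (0, 1):
                rows.append([animal, h + 1] + self.haplotypes[i, h].tolist())
        pd.DataFrame(rows, columns=["animal", "haplotype"] + cols).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_matrix_tsv(cls, path: str, markers: pd.DataFrame | None = None) -> "PhasedPanel":
        df = pd.read_csv(path, sep="\t")
        marker_ids = [c for c in df.columns if c not in ("animal", "haplotype")]
        animals = df["animal"].drop_duplicates().tolist()
        n, m = len(animals), len(marker_ids)
        haps = np.zeros((n, 2, m), dtype=np.int8)
        pos = {a: i for i, a in enumerate(animals)}
        for row in df.itertuples(index=False):
            haps[pos[row.animal], int(row.haplotype) - 1] = [
                getattr(row, c) for c in marker_ids
            ]
        if markers is None:
            markers = pd.DataFrame(
                {"chrom": "?", "pos": range(1, m + 1), "id": marker_ids}
            )
        return cls(animals=animals, markers=markers, haplotypes=haps)


@dataclass
class TagHaplotypeResult:
    found: bool
    window_start: int = -1  # marker index, inclusive
    window_end: int = -1  # marker index, inclusive
    allele_string: str = ""
    case_carriers: int = 0
    control_carriers: int = 0
    r2: float = float("nan")
    genotype_class: pd.Series | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# tag search
# ---------------------------------------------------------------------------

def _window_codes(haps: np.ndarray, start: int, end: int) -> np.ndarray:
    """(n_animals, 2) integer codes of the window haplotype strings.

    For a fixed window width, numeric order of the binary code equals
    lexicographic order of the 0/1 allele string, so code comparisons
    reproduce string tie-breaking."""
    sub = haps[:, :, start : end + 1].astype(np.int64)
    width = sub.shape[2]
    powers = 1 << np.arange(width - 1, -1, -1, dtype=np.int64)
    return sub @ powers


def find_tag_haplotype(
    panel: PhasedPanel,
    cases: Sequence[str],
    controls: Sequence[str],
    window_bounds: tuple[int, int] = DEFAULT_WINDOW_BOUNDS,
    center_index: int | None = None,
) -> TagHaplotypeResult:
    """Two-filter tag-haplotype search.

    Enumerates contiguous windows with sizes in ``window_bounds``
    (optionally required to cover ``center_index``, the marker nearest
    the insertion).  A candidate allele string survives filter 1 when
    every case carries at least one copy; filter 2 selects the survivor
    with the fewest control carriers, breaking ties by shorter window,
    leftmost start, then lexicographic string.  When no candidate
    survives filter 1 anywhere, a not-found result is returned.
    """
    cases = list(cases)
    controls = list(controls)
    if not cases or not controls:
        raise ValueError("cases and controls must both be non-empty")
    if set(cases) & set(controls):
        raise ValueError("cases and controls must be disjoint")
    min_w, max_w = window_bounds
    if min_w < 1 or max_w < min_w:
        raise ValueError("invalid window bounds")
    m = panel.n_markers
    case_idx = panel.index_of(cases)
    control_idx = panel.index_of(controls)

    best = None  # (n_controls, width, start, code)
    for width in range(min_w, min(max_w, m) + 1):
        for start in range(0, m - width + 1):
            end = start + width - 1
            if center_index is not None and not (start <= center_index <= end):
                continue
            codes = _window_codes(panel.haplotypes, start, end)
            candidates = set(codes[case_idx[0]].tolist())
            for ci in case_idx[1:]:
                candidates &= set(codes[ci].tolist())
                if not candidates:
                    break
            control_codes = codes[control_idx]
            for cand in sorted(candidates):
                n_controls = int((control_codes == cand).any(axis=1).sum())
                key = (n_controls, width, start, cand)
                if best is None or key < best:
                    best = key
    if best is None:
        return TagHaplotypeResult(found=False)
    n_controls, width, start, cand = best
    end = start + width - 1
    codes = _window_codes(panel.haplotypes, start, end)
    copies = (codes == cand).sum(axis=1)
    gclass = pd.Series(copies, index=panel.animals, name="genotype_class")
    status_animals = cases + controls
    carrier_vec = (gclass.loc[status_animals] > 0).to_numpy(dtype=float)
    case_vec = np.array([1.0] * len(cases) + [0.0] * len(controls))
    return TagHaplotypeResult(
        found=True,
        window_start=start,
        window_end=end,
        allele_string=format(cand, f"0{width}b"),
        case_carriers=len(cases),
        control_carriers=n_controls,
        r2=ld_r2(carrier_vec, case_vec),
        genotype_class=gclass,
    )


def ld_r2(a: Sequence[float], b: Sequence[float]) -> float:
    """Squared Pearson correlation of two equal-length binary vectors;
    NaN when either vector is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# effect estimation
# ---------------------------------------------------------------------------

def estimate_effects(
    phenotypes: pd.DataFrame,
    genotype_class: Mapping[str, int] | pd.Series,
    trait_sd: Mapping[str, float] | float,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
) -> pd.DataFrame:
    """Per-trait genotype-class effects in GSD units.

    ``phenotypes`` has columns animal/year/trait/value (yield
    deviations); ``genotype_class`` maps animal to 0/1/2 copies of the
    tag haplotype; ``trait_sd`` gives each trait's genetic standard
    deviation (or one scalar for all traits).

    Per trait: least-squares fit of value on genotype class + year of
    birth (both categorical); the het-ref and hom-ref class coefficients
    divided by the genetic SD are the GSD contrasts.  Raw p-values come
    from Welch t-tests between the raw class groups and are BH-adjusted
    across all trait x contrast pairs.  Contrasts whose class falls below
    ``min_class_size`` are reported missing.
    """
    import statsmodels.formula.api as smf

    gclass = pd.Series(genotype_class, name="gclass")
    rows = []
    for trait, sub in phenotypes.groupby("trait", sort=True):
        sub = sub.copy()
        sub["gclass"] = sub["animal"].map(gclass)
        sub = sub.dropna(subset=["gclass", "value"])
        sub["gclass"] = sub["gclass"].astype(int)
        sd = trait_sd[trait] if isinstance(trait_sd, Mapping) else float(trait_sd)
        counts = sub["gclass"].value_counts()
        n0, n1, n2 = (int(counts.get(c, 0)) for c in (0, 1, 2))
        means = sub.groupby("gclass")["value"].mean()
        present = sorted(sub["gclass"].unique())
        coefs = {}
        if len(present) >= 2 and n0 > 0:
            model = smf.ols("value ~ C(gclass) + C(year)", data=sub).fit()
            for c in (1, 2):
                name = f"C(gclass)[T.{c}]"
                if name in model.params.index:
                    coefs[c] = float(model.params[name])
        row = {
            "trait": trait,
            "n0": n0,
            "n1": n1,
            "n2": n2,
            "mean0": float(means.get(0, np.nan)),
            "mean1": float(means.get(1, np.nan)),
            "mean2": float(means.get(2, np.nan)),
        }
        for c, label in ((1, "het"), (2, "hom")):
            nc = {1: n1, 2: n2}[c]
            if n0 >= min_class_size and nc >= min_class_size and c in coefs:
                row[f"contrast_{label}_gsd"] = coefs[c] / sd
                g0 = sub.loc[sub["gclass"] == 0, "value"]
                gc = sub.loc[sub["gclass"] == c, "value"]
                row[f"p_{label}"] = float(
                    stats.ttest_ind(gc, g0, equal_var=False).pvalue
                )
            else:
                row[f"contrast_{label}_gsd"] = np.nan
                row[f"p_{label}"] = np.nan
        rows.append(row)
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    # BH across all tested trait x contrast pairs
    stacked = []
    for label in ("het", "hom"):
        for i in result.index:
            p = result.loc[i, f"p_{label}"]
            if np.isfinite(p):
                stacked.append((i, label, p))
    if stacked:
        adj = bh_adjust([p for _, _, p in stacked])
        result["p_adj_het"] = np.nan
        result["p_adj_hom"] = np.nan
        for (i, label, _), a in zip(stacked, adj):
            result.loc[i, f"p_adj_{label}"] = a
    else:
        result["p_adj_het"] = np.nan
        result["p_adj_hom"] = np.nan
    return result
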