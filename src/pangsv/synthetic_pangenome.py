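"""Synthetic pangenome generator with ground truth.

Emulates, at desk scale, the data a graph-based cattle pangenome study
works with: a small multi-chromosome reference genome; breed haplotypes
carrying implanted insertions, deletions and substitutions whose lengths
follow a transposable-element-like mixture (SINE-scale ~150-300 bp,
LINE-scale ~1.5 kb and ~8.5 kb modes); a reference-anchored sequence
graph with per-assembly walks and occasional untraversed ("nested")
segments; a gene annotation with exon/CDS/UTR/intron structure; QTL
intervals with an elevated insertion density; a phased SNP-marker panel
in which one marker haplotype tags a designated non-reference insertion;
and phenotypes with additive genotype effects expressed in genetic
standard deviations (GSD).

Every generated artifact is paired with a :class:`TruthTable` so that the
downstream calling, genotyping and association stages can be tested for
exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .graph_core import AssemblyPath, PangenomeGraph, Segment, Walk

BASES = np.frombuffer(b"ACGT", dtype="S1")

EVENT_CLASSES = (
    "strict_insertion",
    "relaxed_insertion",
    "strict_deletion",
    "relaxed_deletion",
    "substitution",
    "multiallelic",
)

MIN_EVENT_SPACING = 500  # bp between implanted events on the reference


class ConfigurationError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


class InternalConsistencyError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """All tunables of the generator.

    Defaults encode the study conditions the pipeline is meant to
    exercise: insertion-length modes at 225 bp / 1.5 kb / 8.5 kb,
    additive effects of +0.25 GSD (heterozygote) and +0.50 GSD
    (homozygote) on the simulated trait, a marker haplotype in complete
    LD (r^2 = 1) with the tagged insertion, and a five-fold insertion
    density inside QTL intervals.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 200_000
    breeds: tuple[tuple[str, int], ...] = (("HOL", 4), ("NMD", 4), ("ABO", 4), ("CHA", 4))
    # events per megabase, by class
    sv_rates: dict[str, float] = field(
        default_factory=lambda: {
            "strict_insertion": 68.0,
            "relaxed_insertion": 18.0,
            "strict_deletion": 53.0,
            "relaxed_deletion": 14.0,
            "substitution": 37.0,
            "multiallelic": 12.0,
        }
    )
    # (mode bp, weight) pairs; lengths drawn N(mode, spread*mode), floor 51
    insertion_length_modes: tuple[float, ...] = (225.0, 1500.0, 8500.0)
    insertion_length_weights: tuple[float, ...] = (0.55, 0.30, 0.15)
    insertion_length_spread: float = 0.15
    nested_node_rate: float = 0.05
    breed_private_rate: float = 0.3
    # marker/phenotype simulation
    n_markers: int = 30
    n_animals: int = 20_000
    nrui_allele_freq: float = 0.25
    tag_window_size: int = 5
    tag_r2: float = 1.0
    effect_gsd: tuple[float, float] = (0.25, 0.50)
    trait_sd: float = 1.0
    residual_sd: float = 0.5
    year_sd: float = 0.25
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020, 2021)
    trait_name: str = "stature"
    min_class_size_target: int = 30
    # annotation simulation
    n_genes: int = 12
    qtl_enrichment_factor: float = 5.0
    qtl_window: int = 2000
    qtl_genome_fraction: float = 0.1
    n_null_terms: int = 3

    def __post_init__(self) -> None:
        if self.chrom_length < 10_000:
            raise ConfigurationError("chrom_length must be at least 10 kb")
        if self.n_chromosomes < 1:
            raise ConfigurationError("need at least one chromosome")
        if any(r < 0 for r in self.sv_rates.values()):
            raise ConfigurationError("sv_rates must be non-negative")
        unknown = set(self.sv_rates) - set(EVENT_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown sv_rates classes: {sorted(unknown)}")
        if abs(sum(self.insertion_length_weights) - 1.0) > 1e-9:
            raise ConfigurationError("insertion_length_weights must sum to 1")
        if len(self.insertion_length_modes) != len(self.insertion_length_weights):
            raise ConfigurationError("modes and weights must have equal length")
        if not self.breeds or any(n < 1 for _, n in self.breeds):
            raise ConfigurationError("each breed needs >= 1 haplotype")
        if not 0.0 <= self.nested_node_rate <= 1.0:
            raise ConfigurationError("nested_node_rate must lie in [0, 1]")
        if not 0.0 < self.nrui_allele_freq < 1.0:
            raise ConfigurationError("nrui_allele_freq must lie in (0, 1)")

    def haplotype_names(self) -> list[str]:
        return [f"{breed}_h{i + 1}" for breed, n in self.breeds for i in range(n)]

    def breed_of(self) -> dict[str, str]:
        return {h: h.rsplit("_h", 1)[0] for h in self.haplotype_names()}


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class TruthEvent:
    chrom: str
    pos: int  # 1-based; insertions: base immediately left of the insertion
    start0: int  # 0-based half-open interval of replaced reference bases
    end0: int
    class_label: str  # one of EVENT_CLASSES
    ref: str
    alts: tuple[str, ...]
    carriers: dict[str, int]  # haplotype -> alt allele index (1-based)
    breed_private: bool

    @property
    def carrier_set(self) -> frozenset[str]:
        return frozenset(self.carriers)

    @property
    def is_nrui(self) -> bool:
        return len(self.ref) == 0 and len(self.alts) == 1 and len(self.alts[0]) > 50

    @property
    def nrui_id(self) -> str:
        return f"{self.chrom}_{self.pos}_{len(self.alts[0])}"


@dataclass
class TagHaplotypeTruth:
    window_start: int  # marker index, inclusive
    window_end: int  # marker index, inclusive
    allele_string: str
    nrui_id: str


@dataclass
class TruthTable:
    events: list[TruthEvent] = field(default_factory=list)
    tag_haplotype: TagHaplotypeTruth | None = None
    tagged_event: TruthEvent | None = None

    def nrui_events(self) -> list[TruthEvent]:
        return [e for e in self.events if e.is_nrui]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            rows.append(
                {
                    "chrom": e.chrom,
                    "pos": e.pos,
                    "class": e.class_label,
                    "ref": e.ref,
                    "alts": ",".join(e.alts),
                    "carriers": ";".join(f"{h}:{i}" for h, i in sorted(e.carriers.items())),
                    "breed_private": e.breed_private,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "class", "ref", "alts", "carriers", "breed_private"],
        )


# ---------------------------------------------------------------------------
# reference and haplotypes
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def simulate_reference(config: SimConfig) -> dict[str, str]:
    """Random reference chromosomes ``chr1..chrN`` over {A,C,G,T}."""
    rng = np.random.default_rng(config.seed)
    return {
        f"chr{i + 1}": _random_seq(rng, config.chrom_length)
        for i in range(config.n_chromosomes)
    }


def _mixture_length(rng: np.random.Generator, config: SimConfig) -> int:
    mode = float(rng.choice(config.insertion_length_modes, p=config.insertion_length_weights))
    length = rng.normal(mode, config.insertion_length_spread * mode)
    return max(51, int(round(length)))


def _pick_carriers(
    rng: np.random.Generator, config: SimConfig, private: bool, min_carriers: int = 1
) -> tuple[dict[str, int], str | None]:
    """Random non-empty carrier set; private sets stay within one breed."""
    if private:
        breed, n = config.breeds[rng.integers(len(config.breeds))]
        pool = [f"{breed}_h{i + 1}" for i in range(n)]
    else:
        breed = None
        pool = config.haplotype_names()
    k = int(rng.integers(min_carriers, len(pool) + 1)) if len(pool) >= min_carriers else len(pool)
    chosen = sorted(rng.choice(pool, size=k, replace=False).tolist())
    return {h: 1 for h in chosen}, breed


def _event_alleles(
    rng: np.random.Generator, config: SimConfig, cls: str, reference: str, start: int
) -> tuple[str, tuple[str, ...], int]:
    """Build (ref allele, alt alleles, end0) for an event starting at
    0-based ``start`` on ``reference``."""
    if cls == "strict_insertion":
        return "", (_random_seq(rng, _mixture_length(rng, config)),), start
    if cls == "relaxed_insertion":
        k = int(rng.integers(1, 6))
        return reference[start : start + k], (_random_seq(rng, _mixture_length(rng, config)),), start + k
    if cls == "strict_deletion":
        L = _mixture_length(rng, config)
        return reference[start : start + L], ("",), start + L
    if cls == "relaxed_deletion":
        L = _mixture_length(rng, config)
        return reference[start : start + L], (_random_seq(rng, int(rng.integers(1, 6))),), start + L
    if cls == "substitution":
        L = _mixture_length(rng, config)
        ref = reference[start : start + L]
        alt = _random_seq(rng, _mixture_length(rng, config))
        while alt == ref:
            alt = _random_seq(rng, len(alt))
        return ref, (alt,), start + L
    if cls == "multiallelic":
        a1 = _random_seq(rng, _mixture_length(rng, config))
        a2 = _random_seq(rng, _mixture_length(rng, config))
        while a2 == a1:
            a2 = _random_seq(rng, len(a2))
        return "", (a1, a2), start
    raise ConfigurationError(f"unknown event class {cls!r}")


def simulate_haplotypes(
    reference: dict[str, str], config: SimConfig
) -> tuple[dict[str, dict[str, str]], TruthTable]:
    """Implant non-overlapping events (>= 500 bp apart) into breed
    haplotypes and return the haplotype sequences plus the truth table.

    Event counts per class are Poisson with the configured per-Mb rates.
    Placement allocates inter-event gaps by a multinomial split of the
    free bases, which cannot collide; if the drawn events do not fit on
    the genome a :class:`SimulationError` is raised.
    """
    rng = np.random.default_rng(config.seed + 1)
    hap_names = config.haplotype_names()
    genome_mb = config.n_chromosomes * config.chrom_length / 1e6

    # draw per-class event counts, then assign events to chromosomes
    class_counts = {
        cls: int(rng.poisson(rate * genome_mb)) for cls, rate in sorted(config.sv_rates.items())
    }
    event_classes: list[str] = []
    for cls in EVENT_CLASSES:
        event_classes.extend([cls] * class_counts.get(cls, 0))
    rng.shuffle(event_classes)

    chroms = sorted(reference)
    chrom_of_event = [chroms[i] for i in rng.integers(0, len(chroms), size=len(event_classes))]

    truth = TruthTable()
    privacy_by_breed = {b: 0 for b, _ in config.breeds}
    for chrom in chroms:
        classes_here = [c for c, ch in zip(event_classes, chrom_of_event) if ch == chrom]
        if not classes_here:
            continue
        events = _place_events_on_chrom(rng, config, reference[chrom], chrom, classes_here)
        truth.events.extend(events)

    # guarantee one private event per breed when any events exist
    shared = [e for e in truth.events if not e.breed_private and len(e.alts) == 1]
    for e in truth.events:
        if e.breed_private and e.carriers:
            breed = next(iter(e.carriers)).rsplit("_h", 1)[0]
            privacy_by_breed[breed] += 1
    for breed, n in config.breeds:
        if privacy_by_breed[breed] == 0 and shared:
            e = shared.pop()
            pool = [f"{breed}_h{i + 1}" for i in range(n)]
            k = int(rng.integers(1, len(pool) + 1))
            chosen = sorted(rng.choice(pool, size=k, replace=False).tolist())
            e.carriers = {h: 1 for h in chosen}
            e.breed_private = True
            privacy_by_breed[breed] += 1

    # breed_private is re-derived from the final carrier sets
    breed_of = config.breed_of()
    for e in truth.events:
        breeds_seen = {breed_of[h] for h in e.carriers}
        e.breed_private = len(breeds_seen) == 1

    truth.events.sort(key=lambda e: (e.chrom, e.start0))
    haplotypes = {
        hap: {
            chrom: _apply_events(reference[chrom], truth.events, chrom, hap)
            for chrom in chroms
        }
        for hap in hap_names
    }
    # conservation check
    for hap in hap_names:
        for chrom in chroms:
            delta = sum(
                len(e.alts[e.carriers[hap] - 1]) - len(e.ref)
                for e in truth.events
                if e.chrom == chrom and hap in e.carriers
            )
            if len(haplotypes[hap][chrom]) != len(reference[chrom]) + delta:
                raise InternalConsistencyError(
                    f"length conservation violated for {hap}/{chrom}"
                )

    if truth.events:
        nruis = truth.nrui_events()
        if nruis:
            truth.tagged_event = nruis[0]
    return haplotypes, truth


def _place_events_on_chrom(
    rng: np.random.Generator,
    config: SimConfig,
    reference: str,
    chrom: str,
    classes: list[str],
) -> list[TruthEvent]:
    n = len(classes)
    # draw alleles first at provisional start 0 to learn reference spans;
    # re-slice the true ref allele once positions are fixed
    ref_spans = []
    drafts = []
    for cls in classes:
        ref, alts, end0 = _event_alleles(rng, config, cls, reference, 0)
        ref_spans.append(end0)  # == len(ref)
        drafts.append((cls, alts, len(ref)))
    L = len(reference)
    margin = MIN_EVENT_SPACING
    free = L - 2 * margin - sum(ref_spans) - (n - 1) * MIN_EVENT_SPACING
    if free < 0:
        raise SimulationError(
            f"{chrom}: {n} events (reference span {sum(ref_spans)} bp) do not fit in "
            f"{L} bp with {MIN_EVENT_SPACING} bp spacing"
        )
    # split the free bases into n+1 gaps
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    events = []
    cursor = margin + int(gaps[0])
    for i, (cls, alts, ref_len) in enumerate(drafts):
        start0 = cursor
        end0 = start0 + ref_len
        ref = reference[start0:end0]
        if cls == "substitution" and alts[0] == ref:  # vanishing chance, keep alleles distinct
            alts = (_random_seq(rng, len(alts[0])),)
        private = bool(rng.random() < config.breed_private_rate)
        min_carriers = 2 if cls == "multiallelic" else 1
        if cls == "multiallelic" and min(n for _, n in config.breeds) < 2:
            private = False
        carriers, _ = _pick_carriers(rng, config, private, min_carriers=min_carriers)
        if cls == "multiallelic":
            names = sorted(carriers)
            split = max(1, len(names) // 2)
            carriers = {h: (1 if i < split else 2) for i, h in enumerate(names)}
            if len(set(carriers.values())) == 1:  # need both alleles observed
                carriers[names[-1]] = 2
        pos = start0 if ref_len == 0 else start0 + 1
        events.append(
            TruthEvent(
                chrom=chrom,
                pos=pos,
                start0=start0,
                end0=end0,
                class_label=cls,
                ref=ref,
                alts=alts,
                carriers=carriers,
                breed_private=private,
            )
        )
        cursor = end0 + MIN_EVENT_SPACING + int(gaps[i + 1])
    return events


def _apply_events(
    reference: str, events: list[TruthEvent], chrom: str, hap: str
) -> str:
    parts = []
    cursor = 0
    for e in events:
        if e.chrom != chrom or hap not in e.carriers:
            continue
        parts.append(reference[cursor : e.start0])
        parts.append(e.alts[e.carriers[hap] - 1])
        cursor = e.end0
    parts.append(reference[cursor:])
    return "".join(parts)


# ---------------------------------------------------------------------------
# truth graph
# ---------------------------------------------------------------------------

def build_truth_graph(
    reference: dict[str, str],
    haplotypes: dict[str, dict[str, str]],
    truth: TruthTable,
    config: SimConfig,
) -> tuple[PangenomeGraph, list[AssemblyPath]]:
    """Build the reference-anchored graph implied by the truth events.

    Reference chromosomes are split at event boundaries into reference
    segments; each event contributes its alternate allele(s) as extra
    segments (or a deletion edge) between the two flanking anchors.
    With probability ``nested_node_rate`` a bubble additionally receives
    a parallel segment traversed by no walk, mimicking unresolvable
    nested nodes.  Every walk is verified to re-spell its haplotype.
    """
    rng = np.random.default_rng(config.seed + 2)
    graph = PangenomeGraph()
    breed_of = config.breed_of()
    walks: dict[str, dict[str, Walk]] = {hap: {} for hap in haplotypes}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"s{counter}"

    for chrom in sorted(reference):
        seq = reference[chrom]
        events = [e for e in truth.events if e.chrom == chrom]
        boundaries = sorted({0, len(seq)} | {e.start0 for e in events} | {e.end0 for e in events})
        ref_steps: Walk = []
        seg_at: dict[tuple[int, int], str] = {}
        for a, b in zip(boundaries, boundaries[1:]):
            sid = new_id()
            graph.add_segment(Segment(sid, seq[a:b], {"SN": chrom, "SO": str(a), "SR": "0"}))
            seg_at[(a, b)] = sid
            ref_steps.append((sid, "+"))
        for u, v in zip(ref_steps, ref_steps[1:]):
            graph.add_link(u[0], "+", v[0], "+")
        graph.reference_path[chrom] = ref_steps

        alt_steps_of: dict[int, dict[int, Walk]] = {}
        for ei, e in enumerate(events):
            left = seg_at[(boundaries[boundaries.index(e.start0) - 1], e.start0)]
            right_interval_start = e.end0
            right = seg_at[
                (right_interval_start, boundaries[boundaries.index(right_interval_start) + 1])
            ]
            alt_steps_of[ei] = {}
            for ai, alt in enumerate(e.alts, start=1):
                if alt:
                    sid = new_id()
                    graph.add_segment(Segment(sid, alt, {"SR": "1"}))
                    graph.add_link(left, "+", sid, "+")
                    graph.add_link(sid, "+", right, "+")
                    alt_steps_of[ei][ai] = [(sid, "+")]
                else:
                    graph.add_link(left, "+", right, "+")
                    alt_steps_of[ei][ai] = []
            if rng.random() < config.nested_node_rate:
                sid = new_id()
                graph.add_segment(Segment(sid, _random_seq(rng, int(rng.integers(20, 101))), {"SR": "2"}))
                graph.add_link(left, "+", sid, "+")
                graph.add_link(sid, "+", right, "+")

        for hap in haplotypes:
            walk: Walk = []
            for i, (a, b) in enumerate(zip(boundaries, boundaries[1:])):
                covering = next(
                    (
                        (ei, e)
                        for ei, e in enumerate(events)
                        if e.start0 <= a and b <= e.end0 and hap in e.carriers
                    ),
                    None,
                )
                if covering is not None:
                    ei, e = covering
                    if a == e.start0:  # emit the alt once, at the interval start
                        walk.extend(alt_steps_of[ei][e.carriers[hap]])
                    continue
                walk.append((seg_at[(a, b)], "+"))
                # zero-length events: insertion after this segment?
                for ei, e in enumerate(events):
                    if e.start0 == e.end0 == b and hap in e.carriers:
                        walk.extend(alt_steps_of[ei][e.carriers[hap]])
            walks[hap][chrom] = walk

        if graph.spell(ref_steps) != seq:
            raise InternalConsistencyError(f"reference path does not re-spell {chrom}")

    paths = []
    for hap in sorted(haplotypes):
        ap = AssemblyPath(sample=hap, breed=breed_of[hap], walks=walks[hap])
        for chrom in sorted(reference):
            if graph.spell(ap.walks[chrom]) != haplotypes[hap][chrom]:
                raise InternalConsistencyError(f"walk of {hap} does not re-spell {chrom}")
        paths.append(ap)
    return graph, paths


# ---------------------------------------------------------------------------
# marker panel and phenotypes
# ---------------------------------------------------------------------------

def _solve_false_positive_rate(p: float, target_r2: float) -> float:
    """Rate q at which non-carrier haplotypes receive the tag string so
    that corr(tag, carrier)^2 == target_r2 in expectation."""
    if not 0.0 < target_r2 <= 1.0:
        raise SimulationError(f"target r^2 {target_r2} is not attainable")
    if target_r2 == 1.0:
        return 0.0

    def f(q: float) -> float:
        t = p + q * (1 - p)
        return p * (1 - p) * (1 - q) ** 2 / (t * (1 - t)) - target_r2

    return float(brentq(f, 0.0, 1.0 - 1e-9))


def simulate_array_and_phenotypes(
    truth: TruthTable, config: SimConfig
) -> tuple["PhasedPanel", pd.DataFrame, pd.DataFrame]:
    """Diploid animal population with phased markers, NRUI genotypes and
    phenotypes.

    A window of ``tag_window_size`` markers in the panel centre carries a
    fixed allele string on every NRUI-carrying haplotype; non-carrier
    haplotypes receive it at the rate that realises the configured
    ``tag_r2``.  Phenotype = class shift (0 / het / hom, in
    ``effect_gsd`` x ``trait_sd``) + year-of-birth effect + Gaussian
    residual.
    """
    from .haplotag_assoc import PhasedPanel

    if truth.tagged_event is None:
        raise SimulationError("no tagged NRUI designated in the truth table")
    event = truth.tagged_event
    rng = np.random.default_rng(config.seed + 3)
    n, m = config.n_animals, config.n_markers
    if m < config.tag_window_size + 2:
        raise ConfigurationError("n_markers too small for the tag window")
    p = config.nrui_allele_freq

    carrier = rng.random((n, 2)) < p  # haplotype-level NRUI status
    freqs = rng.uniform(0.1, 0.9, size=m)
    haps = (rng.random((n, 2, m)) < freqs).astype(np.int8)

    # marker coordinates first: the tag window is the run of markers
    # physically closest to the insertion point
    marker_pos = np.sort(
        rng.choice(np.arange(1, config.chrom_length, 2), size=m, replace=False)
    )
    w = config.tag_window_size
    center = int(np.abs(marker_pos - event.pos).argmin())
    w_start = min(max(center - w // 2, 0), m - w)
    w_end = w_start + w - 1
    tag_string = (rng.random(w) < 0.5).astype(np.int8)
    q = _solve_false_positive_rate(p, config.tag_r2)
    expected_fp = q * (1 - p) * 2 * n
    if 0 < q and expected_fp < 1:
        raise SimulationError(
            f"target r^2 {config.tag_r2} infeasible for n_animals={n}"
        )

    window = slice(w_start, w_end + 1)
    give_tag = carrier | (rng.random((n, 2)) < q)
    haps[:, :, window][give_tag] = tag_string
    # break accidental copies of the tag string on untagged haplotypes
    accidental = (~give_tag) & (haps[:, :, window] == tag_string).all(axis=2)
    for i, j in zip(*np.nonzero(accidental)):
        flip = w_start + int(rng.integers(w))
        haps[i, j, flip] = 1 - haps[i, j, flip]

    chrom = event.chrom
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": marker_pos,
            "id": [f"SNP{i + 1}" for i in range(m)],
        }
    )
    animals = [f"A{i + 1}" for i in range(n)]
    panel = PhasedPanel(animals=animals, markers=markers, haplotypes=haps)

    gclass = carrier.sum(axis=1).astype(int)
    genotypes = pd.DataFrame(
        {"animal": animals, "genotype": gclass, "case": gclass > 0}
    )

    years = rng.choice(config.years, size=n)
    year_effect = {y: rng.normal(0.0, config.year_sd * config.trait_sd) for y in config.years}
    shift = np.array([0.0, config.effect_gsd[0], config.effect_gsd[1]]) * config.trait_sd
    value = (
        shift[gclass]
        + np.array([year_effect[y] for y in years])
        + rng.normal(0.0, config.residual_sd * config.trait_sd, size=n)
    )
    phenotypes = pd.DataFrame(
        {
            "animal": animals,
            "year": years,
            "trait": config.trait_name,
            "value": value,
        }
    )

    truth.tag_haplotype = TagHaplotypeTruth(
        window_start=w_start,
        window_end=w_end,
        allele_string="".join(map(str, tag_string.tolist())),
        nrui_id=event.nrui_id,
    )
    return panel, genotypes, phenotypes


# ---------------------------------------------------------------------------
# annotation (genes + QTL intervals)
# ---------------------------------------------------------------------------

PLANTED_CONTEXT_CYCLE = ("intron", "CDS", "UTR", "exon")


def simulate_annotation(
    reference: dict[str, str], truth: TruthTable, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Gene models planted around NRUI insertion points plus QTL
    intervals with elevated NRUI density.

    Returns ``(features, qtl_intervals, planted_contexts)``.  Features
    use GTF conventions (1-based, inclusive) with kinds gene / exon /
    CDS / five_prime_utr / three_prime_utr.  QTL intervals are 1-based
    inclusive with a ``term`` column; the term ``planted_QTL`` covers
    NRUI positions at ~``qtl_enrichment_factor`` times the background
    density, alongside ``n_null_terms`` random null terms.
    """
    rng = np.random.default_rng(config.seed + 4)
    nruis = truth.nrui_events()
    features: list[dict] = []
    contexts: dict[str, str] = {}

    n_anchored = min(config.n_genes, len(nruis))
    for gi in range(n_anchored):
        e = nruis[gi]
        context = PLANTED_CONTEXT_CYCLE[gi % len(PLANTED_CONTEXT_CYCLE)]
        gene_id = f"GENE{gi + 1}"
        contexts[e.nrui_id] = context
        p = e.pos  # 1-based point tested downstream
        L = len(reference[e.chrom])
        g_start, g_end = max(1, p - 200), min(L, p + 200)
        features.append(_feat(e.chrom, g_start, g_end, "gene", gene_id))
        if context == "intron":
            features.append(_feat(e.chrom, g_start, p - 150, "exon", gene_id))
            features.append(_feat(e.chrom, g_start, p - 150, "CDS", gene_id))
            features.append(_feat(e.chrom, p + 150, g_end, "exon", gene_id))
        elif context == "CDS":
            features.append(_feat(e.chrom, p - 50, p + 50, "exon", gene_id))
            features.append(_feat(e.chrom, p - 50, p + 50, "CDS", gene_id))
        elif context == "UTR":
            features.append(_feat(e.chrom, p - 50, p + 50, "exon", gene_id))
            features.append(_feat(e.chrom, p - 50, p + 50, "five_prime_utr", gene_id))
            features.append(_feat(e.chrom, g_end - 20, g_end, "CDS", gene_id))
        else:  # exon that is neither CDS nor UTR (non-coding exon)
            features.append(_feat(e.chrom, p - 50, p + 50, "exon", gene_id))
            features.append(_feat(e.chrom, g_end - 20, g_end, "exon", gene_id))
            features.append(_feat(e.chrom, g_end - 20, g_end, "CDS", gene_id))
    for e in nruis[n_anchored:]:
        contexts[e.nrui_id] = "intergenic"

    features_df = pd.DataFrame(
        features, columns=["chrom", "start", "end", "kind", "gene_id"]
    )

    qtl = _plant_qtl_intervals(rng, reference, nruis, config)
    return features_df, qtl, contexts


def _feat(chrom: str, start: int, end: int, kind: str, gene_id: str) -> dict:
    return {"chrom": chrom, "start": int(start), "end": int(end), "kind": kind, "gene_id": gene_id}


def _plant_qtl_intervals(
    rng: np.random.Generator,
    reference: dict[str, str],
    nruis: list[TruthEvent],
    config: SimConfig,
) -> pd.DataFrame:
    G = sum(len(s) for s in reference.values())
    w = config.qtl_window
    rows: list[dict] = []
    K = len(nruis)
    chroms = sorted(reference)
    if K:
        # the planted term covers a fixed genome fraction; the number of
        # NRUI-covering windows is chosen so that the NRUI density inside
        # the term is qtl_enrichment_factor times the outside density
        f = config.qtl_enrichment_factor
        L = config.qtl_genome_fraction * G
        m = int(round(K * f * L / (G - L + f * L)))
        m = min(max(m, 1), K)
        chosen = set(rng.choice(K, size=m, replace=False).tolist())
        nrui_pos = {(e.chrom, e.pos) for e in nruis}
        for idx in sorted(chosen):
            e = nruis[idx]
            start = max(1, e.pos - w // 2)
            rows.append(
                {"term": "planted_QTL", "chrom": e.chrom, "start": start, "end": start + w - 1}
            )
        # NRUI-free filler windows up to the target covered length
        n_filler = max(0, int(round(L / w)) - m)
        placed = 0
        attempts = 0
        while placed < n_filler and attempts < 50 * n_filler + 100:
            attempts += 1
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1, len(reference[chrom]) - w))
            if any(
                c == chrom and start <= p <= start + w - 1 for c, p in nrui_pos
            ):
                continue
            rows.append(
                {"term": "planted_QTL", "chrom": chrom, "start": start, "end": start + w - 1}
            )
            placed += 1
    for t in range(config.n_null_terms):
        for _ in range(3):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1, len(reference[chrom]) - w))
            rows.append(
                {
                    "term": f"null_term_{t + 1}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + w - 1,
                }
            )
    return pd.DataFrame(rows, columns=["term", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# file writers
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(features: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for row in features.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}";'
            fh.write(
                f"{row.chrom}\tpangsv_sim\t{row.kind}\t{row.start}\t{row.end}"
                f"\t.\t+\t.\t{attrs}\n"
            )


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """1-based inclusive intervals written as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.term}\n")


def read_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            rows.append(
                {
                    "term": fields[3] if len(fields) > 3 else "interval",
                    "chrom": fields[0],
                    "start": int(fields[1]) + 1,
                    "end": int(fields[2]),
                }
            )
    return pd.DataFrame(rows, columns=["term", "chrom", "start", "end"])


@dataclass
class SimBundle:
    """Everything one simulation produces, in memory."""

    config: SimConfig
    reference: dict[str, str]
    haplotypes: dict[str, dict[str, str]]
    truth: TruthTable
    graph: PangenomeGraph
    paths: list[AssemblyPath]
    features: pd.DataFrame
    qtl: pd.DataFrame
    planted_contexts: dict[str, str]
    marker_panel: object | None = None
    nrui_genotypes: pd.DataFrame | None = None
    phenotypes: pd.DataFrame | None = None


def simulate_all(config: SimConfig, with_population: bool = True) -> SimBundle:
    """Run every generator stage with a single configuration."""
    reference = simulate_reference(config)
    haplotypes, truth = simulate_haplotypes(reference, config)
    graph, paths = build_truth_graph(reference, haplotypes, truth, config)
    features, qtl, contexts = simulate_annotation(reference, truth, config)
    bundle = SimBundle(
        config=config,
        reference=reference,
        haplotypes=haplotypes,
        truth=truth,
        graph=graph,
        paths=paths,
        features=features,
        qtl=qtl,
        planted_contexts=contexts,
    )
    if with_population and truth.tagged_event is not None:
        panel, genotypes, phenotypes = simulate_array_and_phenotypes(truth, config)
        bundle.marker_panel = panel
        bundle.nrui_genotypes = genotypes
        bundle.phenotypes = phenotypes
    return bundle
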