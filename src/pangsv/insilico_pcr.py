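"""In-silico PCR across an insertion breakpoint.

Given a reference-allele template and an insertion-allele template plus a
primer pair spanning the breakpoint, predicts the per-allele amplicon
sizes and the band pattern expected for each diploid genotype: the
reference homozygote shows the short band, the insertion homozygote the
long band, and the heterozygote both.  Matching is exact (no mismatches,
no degenerate bases) and each primer must bind its template exactly once;
the amplicon length is measured inclusively between the two primer
5' ends, so when both primers bind outside the inserted sequence the two
amplicons differ by exactly the insertion length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_core import reverse_complement

MIN_PRIMER_LEN = 15
_VALID = set("ACGT")


class AmbiguousPrimingError(ValueError):
    pass


class OrientationError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerPair:
    forward: str  # 5'->3' on the + strand
    reverse: str  # 5'->3' on the - strand
    name: str = ""

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if len(seq) < MIN_PRIMER_LEN:
                raise ValueError(f"{label} primer shorter than {MIN_PRIMER_LEN} nt")
            if not set(seq) <= _VALID:
                raise ValueError(f"{label} primer contains non-ACGT characters")


@dataclass
class AmpliconPrediction:
    reference_length: int
    insertion_length: int  # amplicon on the insertion allele
    band_pattern: dict[str, tuple[int, ...]]


def _find_unique(template: str, site: str, label: str) -> int:
    first = template.find(site)
    if first == -1:
        raise AmbiguousPrimingError(f"{label} primer does not bind the template")
    if template.find(site, first + 1) != -1:
        raise AmbiguousPrimingError(f"{label} primer binds the template more than once")
    return first


def amplicon_length(template: str, primers: PrimerPair) -> int:
    """Inclusive distance between the forward primer's 5' end and the
    reverse primer's 5' end (the end of its reverse-complement site)."""
    f = _find_unique(template, primers.forward, "forward")
    rc = reverse_complement(primers.reverse)
    r = _find_unique(template, rc, "reverse")
    end = r + len(rc)
    if r < f + len(primers.forward):
        raise OrientationError("reverse primer site lies upstream of the forward primer")
    return end - f


def predict_amplicons(
    reference_template: str, insertion_template: str, primers: PrimerPair
) -> AmpliconPrediction:
    """Per-allele amplicon sizes and diploid band patterns.

    Allele 0 is the reference template, allele 1 the insertion-carrying
    template; the band pattern maps genotype (``0/0``, ``0/1``, ``1/1``)
    to the sorted distinct amplicon lengths on a gel.
    """
    ref_len = amplicon_length(reference_template, primers)
    ins_len = amplicon_length(insertion_template, primers)
    het = tuple(sorted({ref_len, ins_len}))
    return AmpliconPrediction(
        reference_length=ref_len,
        insertion_length=ins_len,
        band_pattern={"0/0": (ref_len,), "0/1": het, "1/1": (ins_len,)},
    )


def synthetic_templates_for_primers(
    primers: PrimerPair,
    ref_amplicon: int,
    insert_len: int,
    seed: int = 0,
    flank: int = 25,
) -> tuple[str, str]:
    """Synthetic template pair for a primer pair: random filler sequence
    such that the reference allele yields an amplicon of exactly
    ``ref_amplicon`` bp and the insertion allele carries ``insert_len``
    extra bases between the primer sites."""
    import numpy as np

    filler_len = ref_amplicon - len(primers.forward) - len(primers.reverse)
    if filler_len < 0:
        raise ValueError("amplicon shorter than the two primers")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    filler = "".join(rng.choice(bases, size=filler_len))
    insert = "".join(rng.choice(bases, size=insert_len))
    left = "".join(rng.choice(bases, size=flank))
    right = "".join(rng.choice(bases, size=flank))
    amp = primers.forward + filler + reverse_complement(primers.reverse)
    cut = len(primers.forward) + filler_len // 2
    ref_template = left + amp + right
    ins_template = left + amp[:cut] + insert + amp[cut:] + right
    return ref_template, ins_template


def breakpoint_templates(
    reference: str, pos: int, insert: str, flank: int = 400
) -> tuple[str, str]:
    """Build the two allele templates around an insertion: ``pos`` is the
    1-based base immediately left of the breakpoint on ``reference``."""
    lo = max(0, pos - flank)
    hi = min(len(reference), pos + flank)
    ref_t = reference[lo:hi]
    ins_t = reference[lo:pos] + insert + reference[pos:hi]
    return ref_t, ins_t
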