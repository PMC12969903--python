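# Methods

This note documents the models and procedures implemented in `pangsv`,
the defaults of the synthetic-data generator, the numerical choices made
where the design was genuinely open, and what the tests do and do not
demonstrate about real data.

## Graph model and partition

A pangenome graph is a set of sequence segments (nodes) and oriented
links, with one designated reference walk per chromosome; each haplotype
assembly contributes one ordered, oriented walk per chromosome. This is
the minigraph-style representation in which bubbles between shared
anchor segments encode alternative alleles.

Segments are partitioned by traversal count, with the reference walk
counted as one traversal alongside every assembly walk: **core** =
traversed by all traversals, **flexible** = traversed by at least one
but not all, **untraversed** = traversed by none. Orientation is ignored
for membership. Whether the reference should count as a traversal is not
forced by the data model; counting it reproduces the trichotomy in which
reference-only segments are flexible rather than core-by-default, and it
guarantees that reference segments are never untraversed. Untraversed
segments — in practice nested nodes inside structurally complex bubbles
that no walk resolves — are flagged and excluded from variant analyses.

## Bubble detection and SV classification

Bubbles are found by walk comparison rather than realignment: for each
assembly walk, maximal intervals between consecutive shared
reference-walk segments where the two walks disagree are collected, and
overlapping intervals across assemblies are unioned. Each assembly's
sub-walk between the anchors spells one allele; allele 0 is the
reference spelling. Samples whose walk does not span both anchors are
called missing rather than reference (absence of evidence).

Classification uses allele lengths only, on records whose longest allele
is ≥ 50 nt:

| class | reference allele | alternate allele |
|---|---|---|
| strict insertion | length 0 | any |
| relaxed insertion | 1–5 nt | ≥ 50 nt |
| strict deletion | any | length 0 |
| relaxed deletion | ≥ 50 nt | 1–5 nt |
| other (substitution-like) | non-zero | non-zero |

Multi-allelic records receive an insertion/deletion class only when
every alternate satisfies the same rule, otherwise `other`. This is the
strictest consistent reading; no published rule exists for the
multi-allelic margin, so the choice is recorded here rather than
inferred. Ties at identical start positions sort by (chromosome,
position, reference length, first alternate lexicographically).

Coordinates are 0-based half-open internally. The reported position of a
pure insertion is the 1-based base immediately left of the breakpoint;
other events report their first reference base. VCF output is 4.2 with
standard left-anchor padding for empty alleles (an explicit `PAD` INFO
flag records that padding was applied, so parsing is unambiguous even
for 1-nt residual alleles), explicit sequences (no symbolic alleles),
and haploid genotypes because each genotyped unit is a haplotype
assembly.

## NRUI extraction, merging, genotyping

The three filters retain exactly the biallelic bubbles with an empty
reference allele and an inserted sequence strictly exceeding 50 nt whose
insertion segments are traversed by at least one assembly and absent
from the reference walk. "Exceeding 50" is applied strictly (> 50) even
though the SV floor is ≥ 50, following the definitional wording for
NRUIs.

Panel merging collapses records with identical (chromosome, position)
and equal length first (`common-identical`); remaining candidates
anchored within 50 bp whose lengths reciprocally overlap by ≥ 90%
collapse to the first panel's representative (`common-overlap`). The
reciprocal-overlap fallback re-uses the conventional 90% SV-equivalence
threshold because no insertion-specific rule is published; matching is
greedy in panel order, which is deterministic and one-to-one.

PAV genotyping sets a cell to 1 when the assembly's walk traverses every
insertion segment of the NRUI, 0 otherwise, and missing when the
assembly lacks the chromosome. Frequencies are carriers over non-missing
*haplotypes* (the genotyped units are haplotype assemblies, not diploid
animals); missing cells leave both numerator and denominator. A column
is private when all of its ≥ 1 carriers belong to one breed. Clustering
uses Jaccard distance on the binary columns with average (UPGMA)
linkage — the standard combination for presence/absence data; the flat
cut at k = number of breeds is compared to the breed partition with the
adjusted Rand index.

## Context assignment and enrichment

An NRUI occupies zero reference bases, so functional context is assigned
at the insertion point (a single base), with precedence CDS > UTR >
exon > intron > intergenic; intron means inside a gene span without
touching any exon, and 5′/3′ UTRs are reported as one category. A point
spanning several genes is assigned by precedence, then the leftmost gene
for determinism.

Enrichment of a panel in an interval set is a hypergeometric upper tail
over fixed-width genomic bins (default 200 bp, well below the minimum
spacing of distinct insertions, so distinct NRUIs occupy distinct bins):
with N bins of which K overlap the term, observing k of n NRUIs inside
the term scores P(X ≥ k). K = 0 yields p = 1 by convention. P-values are
Benjamini–Hochberg adjusted across terms, significant at adjusted
p < 0.001. The bin universe is an explicit choice: the published
analyses delegate to a QTL-enrichment package whose universe is not
restated, and a bin universe makes the null (uniform placement)
well-defined and testable. Under that null the raw p-value is slightly
conservative because the statistic is discrete.

## Tag haplotypes and effect estimation

The search enumerates contiguous marker windows with sizes in a
configurable range (default 2–10), optionally required to cover the
marker nearest the insertion. Per window, every distinct haplotype
allele string carried by all cases survives filter 1; filter 2 keeps the
survivor with the fewest control carriers, tie-broken by shorter window,
leftmost start, then lexicographic allele string. Windows are encoded as
integers (numeric order equals lexicographic order at fixed width), so
the exhaustive search is vectorised; on panels of ≤ 12 markers it is
verified against an independent string-based enumeration. "Possessing"
the haplotype means carrying ≥ 1 copy. When no candidate passes filter 1
the result is an explicit not-found value, not an exception.

Effects are estimated on yield deviations — phenotypes already adjusted
for non-genetic effects — by ordinary least squares with genotype class
(0/1/2 copies) and year of birth as categorical fixed effects. The
polygenic random effect of a full mixed-model evaluation is deliberately
out of scope (no pedigree), which leaves class contrasts unbiased under
the generator's model but without shrinkage. Contrasts (het−ref,
hom−ref) are divided by the trait's genetic standard deviation to give
GSD units; p-values are Welch t-tests between raw class groups,
BH-adjusted across trait × contrast pairs; classes below 30 animals
(default) report missing contrasts.

## In-silico PCR

Exact matching only: each primer must bind its template exactly once,
the reverse primer via its reverse complement downstream of the forward
site; mismatches, degenerate bases and thermodynamics are out of scope
for a validation-scale tool. Amplicon length is inclusive of both primer
5′ ends, the convention under which the insertion-allele amplicon minus
the reference amplicon equals the insertion length whenever both primers
bind outside the insertion.

## The synthetic generator

The generator emulates the structure of a multi-breed bovine pangenome
at desk scale. Defaults (all overridable in `SimConfig`):

- **Genome**: 2 chromosomes × 200 kb (tests and the acceptance script
  scale up to a few Mb where a criterion needs ≥ 500 events).
- **Haplotypes**: 4 breeds × 4 haplotypes = 16, mirroring a 16-assembly
  graph.
- **Event rates** (per Mb): strict insertion 68, relaxed insertion 18,
  strict deletion 53, relaxed deletion 14, substitution 37, multiallelic
  12 — proportioned like the published SV-type distribution.
- **Length mixture**: modes at 225 bp, 1.5 kb and 8.5 kb with weights
  0.55/0.30/0.15 and a Gaussian spread of 15% of the mode (floor 51 nt).
  The modes reproduce the characteristic SINE/LINE peaks of the
  insertion–deletion size spectrum; the spreads and weights are free
  parameters (the real spectrum's shape between the peaks is not
  published) chosen so most variants are small, as observed.
- **Placement**: events are non-overlapping with ≥ 500 bp spacing —
  bubbles assume locally separable variation and insertion coordinates
  are points — implemented by a multinomial split of the free bases, so
  placement cannot collide; configurations that cannot fit raise a
  simulation error.
- **Breed structure**: each event is breed-private with probability 0.3
  (carriers drawn within one breed); each breed is guaranteed ≥ 1
  private event when rates permit. The private flag is re-derived from
  final carrier sets.
- **Nested nodes**: with probability 0.05 per bubble a parallel segment
  traversed by no walk is attached between the anchors.
- **Marker panel**: 30 biallelic phased markers; a 5-marker window at
  the markers physically nearest the insertion carries a fixed allele
  string on every NRUI haplotype; non-carrier haplotypes receive the
  string at the rate that realises the target r² (default 1.0, complete
  LD), solved in closed form from the carrier frequency; accidental
  copies elsewhere are broken by a one-allele flip.
- **Population**: 20,000 diploid animals, insertion allele frequency
  0.25 (high enough that the homozygote class supports the default
  30-animal minimum and ±0.05-GSD recovery at this n).
- **Phenotype**: value = class shift (0 / 0.25 / 0.50 GSD × genetic SD)
  + year-of-birth effect (i.i.d. Gaussian, SD 0.25 genetic SD) + residual
  (SD 0.5 genetic SD). Yield deviations are pre-adjusted phenotypes, so
  the residual is set below the genetic SD; year effects stand in for the
  remaining environmental structure.
- **Annotation**: gene models with exon/CDS/UTR/intron structure are
  planted around insertion points cycling through the four genic
  contexts (remaining NRUIs intergenic); QTL intervals cover 10% of the
  genome with the number of NRUI-covering windows chosen so the inside
  density is `qtl_enrichment_factor` (default 5) times the outside
  density, plus three random null terms.

Everything is driven by `numpy.random.default_rng` seeded from
`SimConfig.seed` (sub-stages use fixed offsets), so identical
configurations produce byte-identical FASTA/GFA/path/TSV outputs.

### What the generator does not emulate

No sequencing or assembly errors, no alignment ambiguity, no inversions
or translocations, no overlapping/nested variation beyond the planted
untraversed segments, no linkage disequilibrium among background
markers, no pedigree or polygenic covariance among animals, and no
recombination. Passing tests therefore demonstrate correctness of the
graph algorithms, filters, statistics and bookkeeping under locally
separable variation — not robustness to graph-construction artifacts in
real pangenomes.

## Problem sizes in the test suite and acceptance script

The default test genome (2 × 200 kb, ~80 events) exercises every stage
in seconds. Criteria that are statements about statistical behaviour use
the sizes they name: effect recovery runs 100 replicates of 20,000
animals; enrichment detection uses ~540 insertions on an 8 Mb genome;
clustering uses ~360 insertions across 16 haplotypes. The acceptance
script completes in well under a minute on one CPU.

## Known limitations

- Bubble detection assumes each reference segment appears once per
  reference walk and that assembly walks are colinear with the reference
  (no rearrangements); assemblies sharing no anchors are skipped with a
  warning.
- The panel-merge greedy matching is order-dependent in the rare case of
  several b-panel records within 50 bp of one a-panel record.
- `enrich` treats multiple NRUIs in one bin as distinct draws; with the
  default 200 bp bins and ≥ 500 bp event spacing this cannot occur in
  generated data, but dense real panels should use a smaller bin width.
- The effect model has no polygenic term; on real data with family
  structure the t-tests are anti-conservative relative to a mixed model.
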