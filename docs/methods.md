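# Methods

## Coordinate system and variant model

All positions are 1-based on a single named gene reference (position 1 =
first base), mirroring RefSeqGene-style pharmacogene references; no
genome-build liftover is performed. A variant is an SNV, a pure insertion
(anchored at the position *after which* bases are inserted) or a pure
deletion. Indels are not left-aligned: with one fixed reference and no
repeat assumption, the anchored representation is unambiguous.

## Allele definitions

A star allele is a named haplotype defined by a core-variant set; `*1` is
the reference allele (empty core) and `*5` the whole-gene deletion
(structural, no variants). Suballeles add variants on top of the core set.
Function classes are `normal`, `decreased`, `none`, `uncertain`,
`unknown`; an activity value (0, 0.25, 0.5 or 1 per allele here) exists
exactly when the function is characterised (`normal`/`decreased`/`none`).

Two tables ship with the package:

- `current` — the 13 star alleles observed in the study cohort, their
  activity values and function classes, and the newly assigned suballeles;
- `prior` — the pre-study state: the nine previously known alleles plus
  three alleles not observed in the cohort whose core sets contain variants
  that the cohort rediscovered on different backgrounds.

The published record does not include core-variant sets for the previously
known alleles (those live in the PharmVar database and are not
redistributed), so the shipped core sets are **synthetic stand-ins**:
realistic in size and location but not faithful to PharmVar content.
Everything that depends only on table structure — matching, specificity,
suballele resolution, novel-variant logic — is unaffected by this choice;
anyone with a PharmVar export can supply it as a TSV in the same format.

## Synthetic cohort generator

The generator's defaults are the study conditions: 202 samples / 404
haplotypes with the published star-allele composition (189 `*1`, 57 `*2`,
7 `*4`, 5 `*5`, 74 `*10`, 3 `*35`, 27 `*41`, 1 `*43`, 36 `*71`, and
1/1/2/1 of the four new alleles), and the published novel variants placed
on their reported background alleles with their reported carrier counts
(e.g. the intron-2 G>A at 6528 on 19 distinct `*41` carriers).

Design points:

- Haplotypes pair into diplotypes uniformly at random (the study does not
  publish per-sample diplotypes), with one constraint: two whole-gene
  deletion haplotypes never pair, since a sample with no amplifiable gene
  copy cannot appear in an observed cohort. Consequently phenotype *class
  counts* (the NM/IM split in particular) vary with the pairing seed; only
  pairing-independent statements (the uncertainty rule, allele
  frequencies, carrier counts) are asserted against published values.
- Each novel variant is placed in the stated number of *distinct samples*,
  one haplotype each, so carrier-sample and carrier-haplotype counts agree
  with how observation counts are reported.
- The reference sequence is random (GC ≈ 0.5, length 9,700 with a 6,600 bp
  amplicon window) with the bases at all tabulated variant positions
  pinned to their tabulated reference alleles.

## Read simulator

Reads emulate single-molecule amplicon sequencing at the level the calling
stack consumes:

- **Coordinates, not alignment.** Reads are emitted in reference
  coordinates; the haplotype's own indels travel as explicit events next to
  the sequence. This replaces the external aligner of a production
  pipeline and is the principal simplification: alignment error and
  indel-type sequencing error are out of model. The seam is explicit — any
  aligner producing per-read coordinates and indel events could slot in.
- **Substitution-only errors**, i.i.d. per reference-aligned base at rate
  ε (default 0.05), substituting to a uniformly chosen different base.
  Real nanopore error includes indels; keeping the error model
  substitution-only makes consensus logic testable without gap handling.
  Passing tests therefore demonstrate correctness of the phasing/calling
  logic, not robustness to homopolymer indel noise.
- **Lengths** are truncated-normal around the amplicon product length
  (s.d. 300 bp, default depth 100× — the study states only a ≥50-read
  floor). Reads start at the window start and are truncated at the 3' end;
  reads drawn longer than the product get a random unaligned tail
  (adapter-like), so both QC length bounds are exercisable.
- **Quality** is constant per read at a per-read mean drawn from
  N(12, 1.5), since the QC rule filters on mean Q only.
- A `*5` haplotype contributes no reads (allelic dropout); the
  deletion/duplication assay is simulated as a per-sample boolean flag —
  the secondary 3.5 kb amplicon's *outcome*, not its sequence.

## QC and phasing

Reads are retained when 6,000 ≤ length ≤ 8,000 (inclusive bounds) and
mean Q strictly > 9; samples with fewer than 50 retained reads are
excluded. Candidate sites require a non-reference allele fraction ≥ 0.2 at
depth ≥ 20; at those thresholds, substitution noise at ε = 0.05 (≈ 1.7%
per specific alternate base) is invisible, while true heterozygous sites
(~0.5) and homozygous sites (~0.95) are far inside the bands. Sites with
alternate fraction ≥ 0.8 are homozygous (assigned to both haplotypes);
sites in [0.2, 0.8) are heterozygous and phased.

Phasing is 2-means over per-read observations at heterozygous sites
(values alt/ref/missing; bases that are neither ref nor alt count as
missing), with Hamming distance ignoring missing, at most 50 iterations,
and reassignment ties keeping the current cluster — deterministic given
read order. Initialisation is the farthest pair of *read patterns*; ties
between equally distant pairs break to the pair supported by the most
reads, because complementary single-error reads can also sit at maximal
distance and must not seed the clusters. Cluster collapse (all reads on
one side despite heterozygous sites) is flagged low-confidence, not
dropped. `phasing_confidence` is the fraction of reads matching their
cluster's consensus at every heterozygous site they observe — a
deliberately conservative definition, so that on simulated data the
fraction of reads whose truth tag agrees with their assigned cluster is at
least the reported confidence.

## Star-allele matching and structural integration

Among alleles whose full core set is present on a haplotype, the largest
core set wins (most specific); a size tie breaks to the lowest star number
and is flagged ambiguous. With no complete core set the haplotype is `*1`.
Full core-set presence is required — partial matches under dropout are not
attempted. The suballele with the largest fully present extra-variant set
is then selected; leftover variants are potentially novel.

A positive deletion assay with a single observed haplotype re-calls the
apparent homozygote as `<hap>/*5`; with two clearly distinct haplotypes it
raises a conflict flag instead of overwriting calls. Duplications are
flagged but not assigned to an allele (none occur in the emulated cohort).

## Novel-variant classification

Consequence and deleteriousness annotations (missense/synonymous/
noncoding, SIFT/PolyPhen labels) are **inputs**, mirroring the study's use
of external predictors; nothing is predicted here. The rule set:

- missense, or annotated deleterious → candidate new star allele;
- otherwise → new suballele of the background (matched) allele.

Prior existence as a core variant of a *different* allele is recorded as
supporting evidence but does not alone promote: in the emulated cohort the
two known-but-relocated variants with benign annotations became suballeles
of their observed background, while the known deleterious one became a new
star allele, and the rule reproduces exactly that behaviour. Promoted
variants take the externally assigned star name when the annotation table
provides one (as a naming authority does in practice); carrier haplotypes
adopt the promoted label, while suballele-class novelties leave the
background allele label (and hence the frequency census) unchanged.

Gene regions (promoter/exon/intron labels) come from a BED gene model
(0-based half-open on disk, converted to 1-based closed intervals);
positions outside the model are labelled `unannotated` but still reported.

## Phenotyping

The diplotype activity score is the sum of the two allele activities;
undefined if either allele's function is uncertain/unknown — the
uncertainty dominates (an uncertain/no-function pair is Uncertain, not
PM). Class edges are taken literally: 0 → PM, [0.25, 1] → IM,
[1.25, 2] → NM, > 2 → UM. Allele activities are quarter-steps, so scores
inside (0, 0.25) or (1, 1.25), or off the quarter grid, are unreachable
and rejected with an error rather than rounded.

## Fisher's exact test

Two-sided p-value defined as the total hypergeometric probability of all
tables with the observed margins whose probability does not exceed the
observed table's — the conventional exact definition (mid-p and doubling
variants exist; this is the one implemented), with a relative tolerance of
1e-7 for floating-point ties and a zero-margin convention of p = 1 with a
warning. Implemented by enumeration over the hypergeometric support
(scipy pmf); validated in the tests against an independent
rational-arithmetic enumeration (exact `Fraction` tie comparison) on every
table with margins ≤ 30, and against `scipy.stats.fisher_exact`.

Comparator cohorts are supplied as (allele, haplotype count, total) rows.
Published comparators often report frequencies without counts; counts
reconstructed by rounding frequency × total are flagged `reconstructed`,
and the resulting p-values are approximations of the published
comparisons, not re-derivations.

## Problem sizes and determinism

The desk-scale ("truth-mode") runs use the full 202-sample cohort. The
read-level validation runs use 100-sample subsets at 100× depth and a
100-replicate seeded phasing experiment — sizes chosen to give exact or
tight-binomial checks while keeping a full run in minutes on one CPU. All
randomness flows from a single integer seed (per-sample seeds derived via
`SeedSequence`); a fixed seed reproduces byte-identical report files,
FASTQ output included.

## Known limitations

- Substitution-only error model; no indel sequencing errors, chimeras,
  barcode hopping or alignment artefacts.
- Synthetic core-variant sets for previously known alleles (see above).
- No hybrid gene detection and no copy-number quantification beyond the
  deletion/duplication presence flag.
- Duplication-positive samples are flagged, never allele-assigned.
- Calling assumes phased single-amplicon data; unphased short-read input
  is out of scope.
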