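"""Star-allele matching, structural-assay integration and novel-variant
classification.

Matching rule: among alleles whose entire core-variant set is present on the
haplotype, the most specific (largest core set) wins; a haplotype carrying
no complete core set is the reference allele *1 by default. A matched
suballele additionally requires all of its extra variants. Variants left
over after matching are flagged as potentially novel.

Novel classification follows the study's designations: an unmatched variant
that is missense or annotated deleterious nominates a candidate new star
allele; otherwise it extends its background allele as a new suballele.
Prior existence as a core variant of another allele is recorded as
supporting evidence but does not alone promote (non-deleterious variants
known from other alleles became suballeles of their observed background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .definitions import DefinitionTable, star_number, star_sort_key
from .reads import PhasedCallSet
from .variants import VariantKey


# ---------------------------------------------------------------------------
# haplotype matching


@dataclass(frozen=True)
class HaplotypeCall:
    matched_allele: str
    matched_suballele: str | None
    unmatched_variants: frozenset[VariantKey]
    match_basis: frozenset[VariantKey]  # core (+suballele) variants observed
    ambiguous: bool = False


def match_haplotype(
    hap_variants: frozenset[VariantKey] | set[VariantKey], table: DefinitionTable
) -> HaplotypeCall:
    """Assign the most specific star allele whose core set is fully present.

    Ties on core-set size break to the lowest star number and are flagged
    ambiguous. After the allele, the suballele with the largest fully
    present extra-variant set is selected; everything left is unmatched.
    """
    hap_variants = frozenset(hap_variants)
    candidates = [
        d
        for d in table.alleles.values()
        if d.core_variants and d.core_variants <= hap_variants
    ]
    ambiguous = False
    if not candidates:
        allele = table.alleles["*1"]
    else:
        best_size = max(len(d.core_variants) for d in candidates)
        tied = sorted(
            (d for d in candidates if len(d.core_variants) == best_size),
            key=lambda d: star_number(d.name),
        )
        allele = tied[0]
        ambiguous = len(tied) > 1

    remaining = hap_variants - allele.core_variants
    suballele = None
    sub_variants: frozenset[VariantKey] = frozenset()
    matching_subs = [
        (name, extra)
        for name, extra in allele.suballeles.items()
        if extra <= remaining
    ]
    if matching_subs:
        matching_subs.sort(key=lambda it: (-len(it[1]), star_number(it[0])))
        suballele, sub_variants = matching_subs[0]
    return HaplotypeCall(
        matched_allele=allele.name,
        matched_suballele=suballele,
        unmatched_variants=remaining - sub_variants,
        match_basis=allele.core_variants | sub_variants,
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# structural integration


@dataclass(frozen=True)
class StructuralAssay:
    """Outcome of the secondary 3.5 kb long-PCR fragment assay."""

    deletion_positive: bool = False
    duplication_positive: bool = False


@dataclass(frozen=True)
class ReadEvidence:
    """What the read data says about haplotype multiplicity in a sample."""

    distinct_haplotypes: int  # 1 or 2
    hap_fractions: tuple[float, float] = (1.0, 0.0)

    @classmethod
    def from_callset(cls, callset: PhasedCallSet) -> "ReadEvidence":
        total = callset.n_reads_hap1 + callset.n_reads_hap2
        if total == 0:
            return cls(distinct_haplotypes=1)
        return cls(
            distinct_haplotypes=callset.distinct_haplotypes,
            hap_fractions=(callset.n_reads_hap1 / total, callset.n_reads_hap2 / total),
        )


@dataclass
class DiplotypeResult:
    sample_id: str
    call_a: HaplotypeCall
    call_b: HaplotypeCall
    allele_a: str  # final label (after any novel-star promotion)
    allele_b: str
    deletion_integrated: bool = False
    duplication_flagged: bool = False
    conflict: bool = False
    novel_a: bool = False  # final label is a promoted (not-in-table) star
    novel_b: bool = False
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def diplotype_string(self) -> str:
        a, b = sorted((self.allele_a, self.allele_b), key=star_sort_key)
        return f"{a}/{b}"

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)


_DELETION_CALL = HaplotypeCall(
    matched_allele="*5",
    matched_suballele=None,
    unmatched_variants=frozenset(),
    match_basis=frozenset(),
)


def integrate_structural(
    sample_id: str,
    call_a: HaplotypeCall,
    call_b: HaplotypeCall,
    assay: StructuralAssay,
    evidence: ReadEvidence,
) -> DiplotypeResult:
    """Fold the deletion/duplication assay into the read-based calls.

    A positive deletion assay with a single observed haplotype means the
    second haplotype is the whole-gene deletion: the apparent homozygote is
    re-called as <hap>/*5 (allelic dropout). A positive deletion assay with
    two clearly distinct observed haplotypes is a conflict. Duplications are
    flagged only (allele-level assignment out of scope; none observed in the
    study)."""
    result = DiplotypeResult(
        sample_id=sample_id,
        call_a=call_a,
        call_b=call_b,
        allele_a=call_a.matched_allele,
        allele_b=call_b.matched_allele,
        duplication_flagged=assay.duplication_positive,
    )
    if assay.deletion_positive:
        if evidence.distinct_haplotypes == 1:
            result.call_b = _DELETION_CALL
            result.allele_b = "*5"
            result.deletion_integrated = True
        else:
            result.conflict = True
    return result


# ---------------------------------------------------------------------------
# gene model and annotations


@dataclass
class GeneModel:
    """Ordered labelled intervals (1-based, closed) over the reference."""

    intervals: list[tuple[int, int, str]]

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneModel":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "label"]
        )
        ivals = [
            (int(r["start"]) + 1, int(r["end"]), str(r["label"]))
            for _, r in df.iterrows()
        ]
        return cls(intervals=sorted(ivals))

    @classmethod
    def bundled(cls) -> "GeneModel":
        with resources.as_file(
            resources.files("starcall.data").joinpath("gene_model.bed")
        ) as p:
            return cls.from_bed(p)

    def region_of(self, position: int) -> str:
        for start, end, label in self.intervals:
            if start <= position <= end:
                return label
        return "unannotated"


@dataclass(frozen=True)
class VariantAnnotation:
    consequence: str  # missense | synonymous | noncoding | unannotated
    rsid: str = ""
    deleterious: bool = False
    designation: str = ""  # externally assigned label, e.g. "*167.001"


class AnnotationTable:
    """Externally supplied consequence/deleteriousness annotations (mirrors
    the study's use of SIFT/PolyPhen predictions as inputs, never computed
    here)."""

    def __init__(self, entries: dict[VariantKey, VariantAnnotation]):
        self.entries = entries

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        entries = {}
        for _, r in df.iterrows():
            v = VariantKey(int(r["position"]), r["ref"], r["alt"])
            deleterious = r.get("sift_label", "") == "deleterious" or r.get(
                "polyphen_label", ""
            ) in ("possibly_damaging", "probably_damaging")
            entries[v] = VariantAnnotation(
                consequence=r["consequence"] or "unannotated",
                rsid=r.get("rsid", ""),
                deleterious=deleterious,
                designation=r.get("designation", ""),
            )
        return cls(entries)

    @classmethod
    def bundled(cls) -> "AnnotationTable":
        with resources.as_file(
            resources.files("starcall.data").joinpath("novel_variant_annotations.tsv")
        ) as p:
            return cls.from_tsv(p)

    def get(self, v: VariantKey) -> VariantAnnotation:
        return self.entries.get(v, VariantAnnotation(consequence="unannotated"))


# ---------------------------------------------------------------------------
# novel variants


@dataclass
class NovelVariantEntry:
    variant: VariantKey
    region: str
    consequence: str
    rsid: str
    carriers: list[tuple[str, str]]  # (sample_id, hap label "a"/"b"/"1"/"2")
    background_allele: str
    proposal: str  # "candidate_new_star" | "new_suballele_of:<star>"
    designation: str = ""
    previously_known: bool = False  # in the definition table's variant universe
    core_of: list[str] = field(default_factory=list)

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass
class NovelVariantReport:
    entries: list[NovelVariantEntry]

    @property
    def novel_entries(self) -> list[NovelVariantEntry]:
        """Variants absent from the definition table (not previously
        reported anywhere)."""
        return [e for e in self.entries if not e.previously_known]

    def by_variant(self, v: VariantKey) -> NovelVariantEntry:
        for e in self.entries:
            if e.variant == v:
                return e
        raise KeyError(str(v))


def classify_novel(
    variant: VariantKey,
    background: HaplotypeCall,
    gene_model: GeneModel,
    annotation: AnnotationTable,
    table: DefinitionTable,
) -> NovelVariantEntry:
    """Rule-derived designation proposal for one unmatched variant."""
    ann = annotation.get(variant)
    region = gene_model.region_of(variant.position)
    core_of = [
        n for n in table.core_membership(variant) if n != background.matched_allele
    ]
    if ann.consequence == "missense" or ann.deleterious:
        proposal = "candidate_new_star"
    else:
        proposal = f"new_suballele_of:{background.matched_allele}"
    return NovelVariantEntry(
        variant=variant,
        region=region,
        consequence=ann.consequence,
        rsid=ann.rsid,
        carriers=[],
        background_allele=background.matched_allele,
        proposal=proposal,
        designation=ann.designation,
        previously_known=variant in table.all_known_variants,
        core_of=core_of,
    )


def _promoted_label(entry: NovelVariantEntry) -> str:
    """Star label for a promoted candidate new star: the star part of the
    external designation when given (e.g. *167.001 -> *167), otherwise a
    synthetic placeholder."""
    if entry.designation:
        return entry.designation.split(".")[0]
    return f"*novel{entry.variant.position}"


# ---------------------------------------------------------------------------
# cohort calling


def cohort_call(
    callsets: list[tuple[PhasedCallSet, StructuralAssay]],
    table: DefinitionTable,
    gene_model: GeneModel | None = None,
    annotation: AnnotationTable | None = None,
) -> tuple[list[DiplotypeResult], NovelVariantReport]:
    """Call every sample's diplotype, collect and classify unmatched
    variants, and promote candidate new star alleles across the cohort.

    Haplotypes whose unmatched variant is promoted to a new star take that
    star's label; suballele-class novels leave the matched allele label
    unchanged (the carrier haplotype still counts as its background allele).
    """
    gene_model = gene_model or GeneModel.bundled()
    annotation = annotation or AnnotationTable.bundled()

    results: list[DiplotypeResult] = []
    novel_index: dict[VariantKey, NovelVariantEntry] = {}
    for callset, assay in callsets:
        if callset.excluded:
            results.append(
                DiplotypeResult(
                    sample_id=callset.sample_id,
                    call_a=_DELETION_CALL,
                    call_b=_DELETION_CALL,
                    allele_a="",
                    allele_b="",
                    excluded=True,
                    exclusion_reason=callset.exclusion_reason,
                )
            )
            continue
        call_a = match_haplotype(callset.hap1_variants, table)
        call_b = match_haplotype(callset.hap2_variants, table)
        result = integrate_structural(
            callset.sample_id,
            call_a,
            call_b,
            assay,
            ReadEvidence.from_callset(callset),
        )
        results.append(result)
        for hap_label, call in (("1", result.call_a), ("2", result.call_b)):
            for v in sorted(call.unmatched_variants):
                entry = novel_index.get(v)
                if entry is None:
                    entry = classify_novel(v, call, gene_model, annotation, table)
                    novel_index[v] = entry
                entry.carriers.append((result.sample_id, hap_label))

    # promote candidate new stars and rewrite carrier labels
    promotions: dict[VariantKey, str] = {
        v: _promoted_label(e)
        for v, e in novel_index.items()
        if e.proposal == "candidate_new_star"
    }
    if promotions:
        by_sample = {r.sample_id: r for r in results}
        for v, label in promotions.items():
            for sample_id, hap_label in novel_index[v].carriers:
                r = by_sample[sample_id]
                if hap_label == "1":
                    r.allele_a, r.novel_a = label, True
                else:
                    r.allele_b, r.novel_b = label, True

    report = NovelVariantReport(
        entries=sorted(novel_index.values(), key=lambda e: e.variant)
    )
    return results, report


def distinct_alleles(results: list[DiplotypeResult]) -> list[str]:
    """The distinct-allele census over all called haplotypes."""
    seen = {a for r in results if not r.excluded for a in r.alleles}
    return sorted(seen, key=star_sort_key)
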