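"""Read QC, candidate-site detection, haplotype phasing and phased VCF I/O.

A single long read spans the whole amplicon, so phasing is read-backed:
reads are partitioned into two clusters over the heterozygous candidate
sites (2-means on Hamming distance, farthest-pair initialisation), and each
cluster's majority vote yields one haplotype's variant set.

Reads arrive in reference coordinates (see :mod:`starcall.cohort`); site
extraction is positional lookup rather than alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .cohort import SimulatedRead, SyntheticReference
from .variants import VariantKey

MISSING = 0  # sentinel byte in the aligned matrix


# ---------------------------------------------------------------------------
# QC


@dataclass(frozen=True)
class QCParams:
    """Read and sample retention thresholds.

    Defaults follow the study: reads between 6 and 8 kb (inclusive) with a
    mean Qscore strictly greater than 9; samples with fewer than 50 retained
    reads are excluded.
    """

    min_len: int = 6_000
    max_len: int = 8_000
    min_mean_q: float = 9.0
    min_reads_per_sample: int = 50

    def __post_init__(self) -> None:
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")
        if self.min_len < 0 or self.min_mean_q < 0 or self.min_reads_per_sample < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class QCReport:
    n_input: int = 0
    n_retained: int = 0
    n_too_short: int = 0
    n_too_long: int = 0
    n_low_quality: int = 0


def filter_reads(
    reads: list[SimulatedRead], params: QCParams | None = None
) -> tuple[list[SimulatedRead], QCReport]:
    """Retain reads with min_len <= length <= max_len and mean Q strictly
    greater than min_mean_q. Idempotent."""
    params = params or QCParams()
    report = QCReport(n_input=len(reads))
    retained = []
    for r in reads:
        if r.length < params.min_len:
            report.n_too_short += 1
        elif r.length > params.max_len:
            report.n_too_long += 1
        elif not (r.mean_q > params.min_mean_q):
            report.n_low_quality += 1
        else:
            retained.append(r)
    report.n_retained = len(retained)
    return retained, report


def check_sample_depth(reads: list[SimulatedRead], params: QCParams | None = None) -> bool:
    """True iff the sample passes the minimum retained-read-count threshold."""
    params = params or QCParams()
    return len(reads) >= params.min_reads_per_sample


# ---------------------------------------------------------------------------
# aligned view and candidate sites


def _aligned_matrix(
    reads: list[SimulatedRead], ref: SyntheticReference
) -> np.ndarray:
    """n_reads x window matrix of observed bases (ASCII), MISSING where a
    read does not cover a position (truncation, deletion, inserted bases are
    spliced out)."""
    start, _ = ref.amplicon_window
    n_window = ref.window_length
    m = np.full((len(reads), n_window), MISSING, dtype=np.uint8)
    for i, r in enumerate(reads):
        off0 = r.ref_start - start
        aligned_len = r.n_ref + sum(len(s) for _, s in r.insertions) - sum(
            len(s) for _, s in r.deletions
        )
        seg = np.frombuffer(r.sequence[:aligned_len].encode(), dtype=np.uint8)
        if not r.insertions and not r.deletions:
            m[i, off0 : off0 + r.n_ref] = seg
        else:
            row = np.full(r.n_ref, MISSING, dtype=np.uint8)
            cursor = 0  # within seg
            ref_cursor = 0  # within row
            events = sorted(
                [(p, "ins", s) for p, s in r.insertions]
                + [(p, "del", s) for p, s in r.deletions]
            )
            for p, kind, s in events:
                off = p - r.ref_start
                if kind == "ins":
                    n = off + 1 - ref_cursor
                    row[ref_cursor : off + 1] = seg[cursor : cursor + n]
                    cursor += n + len(s)
                    ref_cursor = off + 1
                else:
                    n = off - ref_cursor
                    row[ref_cursor:off] = seg[cursor : cursor + n]
                    cursor += n
                    ref_cursor = off + len(s)  # deleted positions stay MISSING
            row[ref_cursor:] = seg[cursor : cursor + (r.n_ref - ref_cursor)]
            m[i, off0 : off0 + r.n_ref] = row
    return m


@dataclass(frozen=True)
class CandidateSite:
    variant: VariantKey
    depth: int
    alt_fraction: float


def detect_candidate_sites(
    reads: list[SimulatedRead],
    ref: SyntheticReference,
    min_alt_fraction: float = 0.2,
    min_depth: int = 20,
) -> list[CandidateSite]:
    """Report sites whose non-reference allele fraction is >= min_alt_fraction
    at depth >= min_depth. SNVs come from the aligned base matrix; indel
    events are counted against reads spanning their anchor."""
    if not reads:
        return []
    start, _ = ref.amplicon_window
    m = _aligned_matrix(reads, ref)
    refarr = ref.window_array()
    covered = m != MISSING
    depth = covered.sum(axis=0)
    mismatch = (covered & (m != refarr[None, :])).sum(axis=0)
    sites: list[CandidateSite] = []
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, mismatch / np.maximum(depth, 1), 0.0)
    for col in np.nonzero((depth >= min_depth) & (frac >= min_alt_fraction))[0]:
        col_bases = m[covered[:, col], col]
        alts, counts = np.unique(col_bases[col_bases != refarr[col]], return_counts=True)
        best = alts[np.argmax(counts)]
        alt_frac = counts.max() / depth[col]
        if alt_frac >= min_alt_fraction:
            v = VariantKey(start + int(col), chr(refarr[col]), chr(best))
            sites.append(CandidateSite(v, int(depth[col]), float(alt_frac)))

    # indel events (error-free by construction of the substitution-only model)
    ins_counts: dict[tuple[int, str], int] = {}
    del_counts: dict[tuple[int, str], int] = {}
    for r in reads:
        for p, s in r.insertions:
            ins_counts[(p, s)] = ins_counts.get((p, s), 0) + 1
        for p, s in r.deletions:
            del_counts[(p, s)] = del_counts.get((p, s), 0) + 1
    for (p, s), n in ins_counts.items():
        d = int(covered[:, p - start].sum())
        if d >= min_depth and n / d >= min_alt_fraction:
            sites.append(CandidateSite(VariantKey(p, "", s), d, n / d))
    for (p, s), n in del_counts.items():
        span = covered[:, p - start : p - start + len(s)]
        d = int((span.any(axis=1)).sum()) + n  # carriers show MISSING across the span
        if d >= min_depth and n / d >= min_alt_fraction:
            sites.append(CandidateSite(VariantKey(p, s, ""), d, n / d))
    return sorted(sites, key=lambda c: (c.variant.position, c.variant.alt))


@dataclass
class SiteObservationMatrix:
    """Per-read allele observations at candidate sites: 1 alt, 0 ref, -1
    missing/other."""

    sample_id: str
    sites: list[CandidateSite]
    obs: np.ndarray  # int8, n_reads x n_sites
    read_ids: list[str]
    truth_haps: list[str] = field(default_factory=list)  # simulator tags, if known


def build_observation_matrix(
    reads: list[SimulatedRead],
    ref: SyntheticReference,
    sites: list[CandidateSite],
    sample_id: str = "",
) -> SiteObservationMatrix:
    start, _ = ref.amplicon_window
    m = _aligned_matrix(reads, ref)
    obs = np.full((len(reads), len(sites)), -1, dtype=np.int8)
    for j, site in enumerate(sites):
        v = site.variant
        col = v.position - start
        if v.kind == "SNV":
            bases = m[:, col]
            obs[bases == ord(v.ref), j] = 0
            obs[bases == ord(v.alt), j] = 1
        elif v.kind == "insertion":
            covered = m[:, col] != MISSING
            has = np.array([(v.position, v.alt) in r.insertions for r in reads])
            obs[covered, j] = 0
            obs[has, j] = 1
        else:  # deletion
            span_covered = (m[:, col : col + len(v.ref)] != MISSING).any(axis=1)
            has = np.array([(v.position, v.ref) in r.deletions for r in reads])
            obs[span_covered, j] = 0
            obs[has, j] = 1
    return SiteObservationMatrix(
        sample_id=sample_id or (reads[0].sample_id if reads else ""),
        sites=sites,
        obs=obs,
        read_ids=[r.read_id for r in reads],
        truth_haps=[r.hap for r in reads],
    )


# ---------------------------------------------------------------------------
# phasing


@dataclass
class PhasedCallSet:
    """Two phased haplotype variant sets for one sample.

    Homozygous-alt sites appear in both sets; hap1 ∪ hap2 covers every site
    called non-reference.
    """

    sample_id: str
    hap1_variants: frozenset[VariantKey]
    hap2_variants: frozenset[VariantKey]
    site_stats: list[CandidateSite]
    phasing_confidence: float
    n_reads_hap1: int
    n_reads_hap2: int
    low_confidence: bool = False
    excluded: bool = False
    exclusion_reason: str = ""
    read_assignment: np.ndarray | None = None  # cluster index per read (0/1)

    @property
    def distinct_haplotypes(self) -> int:
        return 1 if self.hap1_variants == self.hap2_variants else 2


def excluded_callset(sample_id: str, reason: str) -> PhasedCallSet:
    return PhasedCallSet(
        sample_id=sample_id,
        hap1_variants=frozenset(),
        hap2_variants=frozenset(),
        site_stats=[],
        phasing_confidence=0.0,
        n_reads_hap1=0,
        n_reads_hap2=0,
        excluded=True,
        exclusion_reason=reason,
    )


def _consensus(obs: np.ndarray) -> np.ndarray:
    """Majority vote per column ignoring missing; ties go to ref (0)."""
    alt = (obs == 1).sum(axis=0)
    refc = (obs == 0).sum(axis=0)
    return (alt > refc).astype(np.int8)


def _distances(obs: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Mean mismatch over observed sites between each read and a centroid."""
    observed = obs >= 0
    mism = (obs != centroid[None, :]) & observed
    n_obs = observed.sum(axis=1)
    return np.where(n_obs > 0, mism.sum(axis=1) / np.maximum(n_obs, 1), 0.0)


def phase_sample(
    matrix: SiteObservationMatrix,
    *,
    hom_fraction: float = 0.8,
    het_fraction: float = 0.2,
    max_iter: int = 50,
) -> PhasedCallSet:
    """Partition reads into two haplotype clusters and call each cluster's
    variants by majority vote.

    Sites with alt fraction >= ``hom_fraction`` (among ref/alt observations)
    are homozygous and assigned to both haplotypes; sites in
    [``het_fraction``, ``hom_fraction``) are heterozygous and phased by
    2-means over Hamming distance with farthest-pair initialisation.
    Reassignment ties keep the current cluster, so the procedure is
    deterministic given read order.
    """
    obs = matrix.obs
    n_reads, n_sites = obs.shape
    alt = (obs == 1).sum(axis=0)
    refc = (obs == 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(alt + refc > 0, alt / np.maximum(alt + refc, 1), 0.0)
    hom_idx = [j for j in range(n_sites) if frac[j] >= hom_fraction]
    het_idx = [j for j in range(n_sites) if het_fraction <= frac[j] < hom_fraction]
    hom_calls = frozenset(matrix.sites[j].variant for j in hom_idx)

    if not het_idx:
        return PhasedCallSet(
            sample_id=matrix.sample_id,
            hap1_variants=hom_calls,
            hap2_variants=hom_calls,
            site_stats=matrix.sites,
            phasing_confidence=1.0,
            n_reads_hap1=n_reads,
            n_reads_hap2=0,
            read_assignment=np.zeros(n_reads, dtype=np.int8),
        )

    het = obs[:, het_idx]
    observed = het >= 0
    # farthest-pair initialisation on normalised Hamming distance, computed
    # over unique read patterns; ties between equally distant pairs break to
    # the pair supported by the most reads (lone error reads can sit at
    # maximal distance too, and must not seed the clusters)
    patterns, counts = np.unique(het, axis=0, return_counts=True)
    obs_p = patterns >= 0
    diff = (patterns[:, None, :] != patterns[None, :, :]) & obs_p[:, None, :] & obs_p[None, :, :]
    joint = (obs_p[:, None, :] & obs_p[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(joint > 0, diff.sum(axis=2) / np.maximum(joint, 1), 0.0)
    best_key, best_pair = (-1.0, -1), (0, 0)
    for i in range(len(patterns)):
        for j in range(i + 1, len(patterns)):
            key = (dist[i, j], int(counts[i] + counts[j]))
            if key > best_key:
                best_key, best_pair = key, (i, j)
    i0, i1 = best_pair
    c0, c1 = patterns[i0].clip(0), patterns[i1].clip(0)

    assign = np.zeros(n_reads, dtype=np.int8)
    d0, d1 = _distances(het, c0), _distances(het, c1)
    assign = np.where(d1 < d0, 1, 0).astype(np.int8)
    for _ in range(max_iter):
        in1 = assign == 1
        if (~in1).sum() == 0 or in1.sum() == 0:
            break
        c0 = _consensus(het[~in1])
        c1 = _consensus(het[in1])
        d0, d1 = _distances(het, c0), _distances(het, c1)
        new = np.where(d1 < d0, 1, np.where(d0 < d1, 0, assign)).astype(np.int8)
        if np.array_equal(new, assign):
            assign = new
            break
        assign = new

    n1 = int((assign == 1).sum())
    n0 = n_reads - n1
    collapsed = n0 == 0 or n1 == 0
    if collapsed:
        consensus_all = _consensus(het)
        hap1_het = hap2_het = frozenset(
            matrix.sites[het_idx[j]].variant for j in np.nonzero(consensus_all == 1)[0]
        )
        confidence = 0.0
    else:
        c0 = _consensus(het[assign == 0])
        c1 = _consensus(het[assign == 1])
        hap1_het = frozenset(
            matrix.sites[het_idx[j]].variant for j in np.nonzero(c0 == 1)[0]
        )
        hap2_het = frozenset(
            matrix.sites[het_idx[j]].variant for j in np.nonzero(c1 == 1)[0]
        )
        # a read is consistent if it matches its cluster's consensus at every
        # het site it observes (conservative: any mismatch disqualifies)
        own = np.where(assign[:, None] == 1, c1[None, :], c0[None, :])
        mismatch = (het != own) & observed
        confidence = float((~mismatch.any(axis=1)).mean())

    return PhasedCallSet(
        sample_id=matrix.sample_id,
        hap1_variants=hom_calls | hap1_het,
        hap2_variants=hom_calls | hap2_het,
        site_stats=matrix.sites,
        phasing_confidence=confidence,
        n_reads_hap1=n0,
        n_reads_hap2=n1,
        low_confidence=collapsed,
        read_assignment=assign,
    )


# ---------------------------------------------------------------------------
# phased VCF I/O


def _vcf_record_fields(
    v: VariantKey, ref: SyntheticReference
) -> tuple[int, str, str]:
    """VCF POS/REF/ALT encoding: SNVs direct; indels left-anchored on the
    preceding reference base per VCF convention."""
    if v.kind == "SNV":
        return v.position, v.ref, v.alt
    if v.kind == "insertion":
        anchor = ref.base(v.position)
        return v.position, anchor, anchor + v.alt
    anchor = ref.base(v.position - 1)
    return v.position - 1, anchor + v.ref, anchor


def _variant_from_vcf(pos: int, ref_allele: str, alt_allele: str) -> VariantKey:
    if len(ref_allele) == 1 and len(alt_allele) == 1:
        return VariantKey(pos, ref_allele, alt_allele)
    if len(alt_allele) > len(ref_allele) and alt_allele.startswith(ref_allele):
        return VariantKey(pos + len(ref_allele) - 1, "", alt_allele[len(ref_allele):])
    if len(ref_allele) > len(alt_allele) and ref_allele.startswith(alt_allele):
        return VariantKey(pos + len(alt_allele), ref_allele[len(alt_allele):], "")
    raise ValueError(f"unsupported VCF allele pair {ref_allele}>{alt_allele} at {pos}")


def write_phased_vcf(
    callset: PhasedCallSet, ref: SyntheticReference, path: str | Path
) -> None:
    """One record per called variant with a phased genotype (hap1 first):
    ``1|0``, ``0|1`` or ``1|1``."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={ref.name},length={len(ref.sequence)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(callset.sample_id or "sample")
    all_variants = sorted(callset.hap1_variants | callset.hap2_variants)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in all_variants:
            pos, ra, aa = _vcf_record_fields(v, ref)
            rec = vcf.new_record(
                contig=ref.name, start=pos - 1, alleles=(ra, aa), filter="PASS"
            )
            gt = (
                1 if v in callset.hap1_variants else 0,
                1 if v in callset.hap2_variants else 0,
            )
            rec.samples[0]["GT"] = gt
            rec.samples[0].phased = True
            vcf.write(rec)


def read_phased_vcf(path: str | Path) -> PhasedCallSet:
    """Recover the phased variant content written by :func:`write_phased_vcf`."""
    hap1: set[VariantKey] = set()
    hap2: set[VariantKey] = set()
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            v = _variant_from_vcf(rec.pos, rec.ref, rec.alts[0])
            gt = rec.samples[sample]["GT"]
            if gt[0]:
                hap1.add(v)
            if gt[1]:
                hap2.add(v)
    return PhasedCallSet(
        sample_id=sample,
        hap1_variants=frozenset(hap1),
        hap2_variants=frozenset(hap2),
        site_stats=[],
        phasing_confidence=1.0,
        n_reads_hap1=0,
        n_reads_hap2=0,
    )
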