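"""Ground-truthed synthetic cohorts and nanopore-like amplicon reads.

The study design being emulated: a ~6.6 kb long-PCR amplicon spanning the
whole CYP2D6 gene is sequenced per sample on a nanopore device; a separate
PCR assay (a secondary 3.5 kb junction fragment) reports presence of a
whole-gene deletion (*5) or duplication. A *5 haplotype contributes no
amplicon template, so its reads are absent (allelic dropout).

Everything here is deterministic for a fixed seed. Reads are emitted in
reference coordinates: substitution errors only, with any haplotype indels
carried as explicit events alongside the sequence — the seam where an
external aligner would otherwise sit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .definitions import DefinitionTable, load_bundled_definitions
from .variants import VariantKey, format_variant_set, parse_variant_set

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# reference


@dataclass(frozen=True)
class SyntheticReference:
    """A synthetic gene reference with the amplified window marked.

    ``amplicon_window`` is a 1-based closed interval [start, end] of the
    long-PCR product within the reference.
    """

    name: str
    sequence: str
    amplicon_window: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.amplicon_window
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(f"amplicon window {self.amplicon_window} outside reference")

    @property
    def window_length(self) -> int:
        return self.amplicon_window[1] - self.amplicon_window[0] + 1

    def base(self, position: int) -> str:
        return self.sequence[position - 1]

    def window_array(self) -> np.ndarray:
        start, end = self.amplicon_window
        return np.frombuffer(self.sequence[start - 1 : end].encode(), dtype=np.uint8).copy()


DEFAULT_REFERENCE_LENGTH = 9_700
DEFAULT_WINDOW = (3_050, 9_649)  # 6,600 bp product covering all fixture positions


def default_anchor_bases() -> dict[int, str]:
    """Reference bases implied by the bundled definition tables and
    annotations (insertions impose no anchor)."""
    anchors: dict[int, str] = {}
    for which in ("current", "prior"):
        for v in load_bundled_definitions(which).all_known_variants:
            if v.ref:
                anchors[v.position] = v.ref
    ann = load_annotation_refs()
    for pos, ref in ann.items():
        if ref and anchors.setdefault(pos, ref) != ref:
            raise ValueError(f"conflicting reference base at {pos}")
    return anchors


def load_annotation_refs() -> dict[int, str]:
    with resources.as_file(
        resources.files("starcall.data").joinpath("novel_variant_annotations.tsv")
    ) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    return {int(r["position"]): r["ref"] for _, r in df.iterrows() if r["ref"]}


def build_reference(
    seed: int,
    length: int = DEFAULT_REFERENCE_LENGTH,
    *,
    name: str = "CYP2D6_synthetic",
    window: tuple[int, int] = DEFAULT_WINDOW,
    anchor_bases: dict[int, str] | None = None,
) -> SyntheticReference:
    """Generate a random reference sequence (GC ~ 0.5), deterministically
    for a fixed seed, with known variant positions pinned to their
    tabulated reference bases."""
    if anchor_bases is None:
        anchor_bases = default_anchor_bases()
    max_pos = max(anchor_bases, default=1)
    if length < max_pos or length < window[1]:
        raise ValueError(
            f"reference length {length} too small (needs >= {max(max_pos, window[1])})"
        )
    rng = np.random.default_rng(seed)
    seq = _BASE_ARR[rng.integers(0, 4, size=length)]
    for pos, base in anchor_bases.items():
        seq[pos - 1] = ord(base)
    return SyntheticReference(name=name, sequence=seq.tobytes().decode(), amplicon_window=window)


# ---------------------------------------------------------------------------
# diplotypes


@dataclass(frozen=True)
class HaplotypeSpec:
    """Truth description of one haplotype: a star allele, optionally a
    suballele, plus any extra (novel) variants placed on that background."""

    allele: str
    suballele: str | None = None
    extra_variants: frozenset[VariantKey] = frozenset()

    def variant_set(self, table: DefinitionTable) -> frozenset[VariantKey]:
        d = table.alleles[self.allele]
        out = set(d.core_variants)
        if self.suballele is not None:
            out |= d.suballeles[self.suballele]
        out |= self.extra_variants
        return frozenset(out)

    def is_deletion(self, table: DefinitionTable) -> bool:
        return table.alleles[self.allele].structural == "whole_gene_deletion"

    @property
    def label(self) -> str:
        extras = f"+{format_variant_set(self.extra_variants)}" if self.extra_variants else ""
        return (self.suballele or self.allele) + extras


@dataclass(frozen=True)
class TrueDiplotype:
    sample_id: str
    hap_a: HaplotypeSpec
    hap_b: HaplotypeSpec
    deletion_assay_positive: bool
    duplication_assay_positive: bool = False

    def haplotypes(self) -> tuple[HaplotypeSpec, HaplotypeSpec]:
        return (self.hap_a, self.hap_b)


def study_composition() -> dict[str, int]:
    """The study cohort's haplotype composition (404 haplotypes over 202
    samples) as shipped with the package."""
    with resources.as_file(
        resources.files("starcall.data").joinpath("cohort_composition.tsv")
    ) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["allele"], df["haplotypes"].astype(int)))


def novel_variant_placements() -> list[tuple[VariantKey, str, int]]:
    """Novel-variant placements (variant, background allele, carrier count)
    for variants not generated through a star-allele core set."""
    with resources.as_file(
        resources.files("starcall.data").joinpath("novel_variant_spec.tsv")
    ) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        v = VariantKey(int(r["position"]), r["ref"], r["alt"])
        out.append((v, r["background_allele"], int(r["carriers"])))
    return out


def make_cohort(
    table: DefinitionTable,
    composition: dict[str, int],
    novel_spec: list[tuple[VariantKey, str, int]] | None = None,
    seed: int = 0,
    *,
    sample_prefix: str = "S",
) -> list[TrueDiplotype]:
    """Build a cohort whose haplotype multiset exactly matches
    ``composition``, with pairing into diplotypes randomised by ``seed``.

    Each novel-spec variant is placed on the stated background allele in the
    requested number of *distinct samples* (one haplotype each), so carrier
    sample counts equal carrier haplotype counts, matching how the study
    reports observation counts.

    Pairing is uniform random except that two whole-gene-deletion
    haplotypes are never paired together: a sample with both gene copies
    deleted yields no amplicon and could not appear in an observed cohort,
    so every deletion haplotype in the composition sits in its own sample.
    """
    novel_spec = novel_spec or []
    for allele, n in composition.items():
        if allele not in table.alleles:
            raise ValueError(f"composition allele {allele} not in definition table")
        if n < 0:
            raise ValueError("haplotype counts must be non-negative")
    total = sum(composition.values())
    if total == 0 or total % 2:
        raise ValueError(f"haplotype counts must sum to a positive even number, got {total}")
    for v, bg, n in novel_spec:
        if bg not in composition or composition[bg] < n:
            raise ValueError(f"novel variant {v}: background {bg} has fewer than {n} haplotypes")

    rng = np.random.default_rng(seed)
    haps = [HaplotypeSpec(a) for a in sorted(composition, key=lambda a: composition[a]) for _ in range(composition[a])]
    order = rng.permutation(len(haps))
    paired = [haps[i] for i in order]
    n_samples = total // 2
    width = max(3, len(str(n_samples)))
    samples: list[list[HaplotypeSpec]] = [
        [paired[2 * i], paired[2 * i + 1]] for i in range(n_samples)
    ]

    # break up any deletion/deletion pair by swapping with the first sample
    # holding two non-deletion haplotypes (deterministic fix-up)
    def _both_deleted(pair: list[HaplotypeSpec]) -> bool:
        return pair[0].is_deletion(table) and pair[1].is_deletion(table)

    for si, pair in enumerate(samples):
        if _both_deleted(pair):
            for sj, other in enumerate(samples):
                if sj != si and not other[0].is_deletion(table) and not other[1].is_deletion(table):
                    pair[1], other[0] = other[0], pair[1]
                    break
            else:
                raise ValueError("composition leaves no valid deletion pairing")

    # place novel variants in distinct samples on un-carried background haplotypes
    carried: set[tuple[int, int]] = set()
    for v, bg, n in novel_spec:
        candidates = []
        for si, pair in enumerate(samples):
            for hi, hap in enumerate(pair):
                if hap.allele == bg and (si, hi) not in carried:
                    candidates.append((si, hi))
                    break  # at most one haplotype per sample per variant
        if len(candidates) < n:
            raise ValueError(
                f"novel variant {v}: only {len(candidates)} eligible samples for background {bg}"
            )
        chosen = rng.choice(len(candidates), size=n, replace=False)
        for ci in sorted(chosen):
            si, hi = candidates[ci]
            hap = samples[si][hi]
            samples[si][hi] = replace(hap, extra_variants=hap.extra_variants | {v})
            carried.add((si, hi))

    out = []
    for i, (a, b) in enumerate(samples, start=1):
        deletion = a.is_deletion(table) or b.is_deletion(table)
        out.append(
            TrueDiplotype(
                sample_id=f"{sample_prefix}{i:0{width}d}",
                hap_a=a,
                hap_b=b,
                deletion_assay_positive=deletion,
            )
        )
    return out


# ---------------------------------------------------------------------------
# haplotype products


def _split_variants(
    variants: frozenset[VariantKey],
) -> tuple[list[VariantKey], list[tuple[int, str]], list[tuple[int, str]]]:
    snvs = sorted(v for v in variants if v.kind == "SNV")
    ins = sorted((v.position, v.alt) for v in variants if v.kind == "insertion")
    dels = sorted((v.position, v.ref) for v in variants if v.kind == "deletion")
    positions = [v.position for v in snvs] + [p for p, _ in ins]
    for p, r in dels:
        positions.extend(range(p, p + len(r)))
    if len(positions) != len(set(positions)):
        raise ValueError(f"overlapping variants in haplotype: {format_variant_set(variants)}")
    return snvs, ins, dels


def haplotype_sequence(
    ref: SyntheticReference, hap: HaplotypeSpec, table: DefinitionTable
) -> str:
    """The amplicon product of one haplotype: window sequence with the
    haplotype's variants applied (right-to-left so coordinates stay valid).
    A whole-gene deletion yields a zero-length product."""
    if hap.is_deletion(table):
        return ""
    start, end = ref.amplicon_window
    variants = hap.variant_set(table)
    for v in variants:
        if not (start <= v.position <= end):
            raise ValueError(f"variant {v} outside amplicon window {ref.amplicon_window}")
    snvs, ins, dels = _split_variants(variants)
    seq = list(ref.sequence[start - 1 : end])
    for v in snvs:
        off = v.position - start
        if seq[off] != v.ref:
            raise ValueError(f"reference mismatch at {v.position}: {seq[off]} != {v.ref}")
        seq[off] = v.alt
    edits = [(p, "ins", s) for p, s in ins] + [(p, "del", s) for p, s in dels]
    for p, kind, s in sorted(edits, reverse=True):
        off = p - start
        if kind == "ins":
            seq[off + 1 : off + 1] = list(s)
        else:
            if "".join(seq[off : off + len(s)]) != s:
                raise ValueError(f"reference mismatch for deletion at {p}")
            del seq[off : off + len(s)]
    return "".join(seq)


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated amplicon read in reference coordinates.

    The read's aligned segment starts at window position ``ref_start`` and
    covers ``n_ref`` reference positions; the haplotype's indels within that
    span are listed as events. ``pad`` unaligned bases (adapter-like tail)
    follow the aligned segment in ``sequence``.
    """

    read_id: str
    sequence: str
    qualities: str  # Phred+33, one char per base
    sample_id: str
    hap: str  # truth tag: "a" or "b"
    ref_start: int
    n_ref: int
    insertions: tuple[tuple[int, str], ...] = ()
    deletions: tuple[tuple[int, str], ...] = ()
    pad: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("zero-length read")
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")
        if self.hap not in ("a", "b"):
            raise ValueError("truth tag must be 'a' or 'b'")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mean_q(self) -> float:
        return float(np.mean([ord(c) - 33 for c in self.qualities]))


@dataclass(frozen=True)
class SimParams:
    depth: int = 100
    error_rate: float = 0.05
    length_sd: float = 300.0
    q_mean: float = 12.0
    q_sd: float = 1.5


def simulate_reads(
    dip: TrueDiplotype,
    ref: SyntheticReference,
    table: DefinitionTable,
    *,
    depth: int = 100,
    error_rate: float = 0.05,
    length_sd: float = 300.0,
    q_mean: float = 12.0,
    q_sd: float = 1.5,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Draw ``depth`` reads from the sample's two haplotype products with
    equal probability. Substitution errors are i.i.d. at ``error_rate`` on
    reference-aligned bases; a *5 haplotype contributes no reads (allelic
    dropout). Deterministic for a fixed seed."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    start, end = ref.amplicon_window
    n_window = ref.window_length
    window = ref.window_array()

    layers: dict[str, tuple[np.ndarray, list, list] | None] = {}
    for tag, hap in (("a", dip.hap_a), ("b", dip.hap_b)):
        if hap.is_deletion(table):
            layers[tag] = None
            continue
        variants = hap.variant_set(table)
        snvs, ins, dels = _split_variants(variants)
        arr = window.copy()
        for v in snvs:
            off = v.position - start
            if arr[off] != ord(v.ref):
                raise ValueError(f"reference mismatch at {v.position}")
            arr[off] = ord(v.alt)
        layers[tag] = (arr, ins, dels)

    available = [t for t in ("a", "b") if layers[t] is not None]
    if not available:
        warnings.warn(f"{dip.sample_id}: both haplotypes deleted, no reads simulated")
        return []

    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for i in range(depth):
        tag = available[rng.integers(len(available))]
        arr, ins, dels = layers[tag]  # type: ignore[misc]
        product_len = n_window + sum(len(s) for _, s in ins) - sum(len(s) for _, s in dels)
        length = int(rng.normal(product_len, length_sd))
        length = max(200, length)

        base = arr.copy()
        if error_rate > 0:
            mask = rng.random(n_window) < error_rate
            n_err = int(mask.sum())
            if n_err:
                # substitute with a uniformly chosen different base
                shift = rng.integers(1, 4, size=n_err)
                idx = np.searchsorted(_BASE_ARR, base[mask])
                base[mask] = _BASE_ARR[(idx + shift) % 4]

        if not ins and not dels:
            n_ref = min(length, n_window)
            aligned = base[:n_ref]
            r_ins: tuple = ()
            r_dels: tuple = ()
            spliced = aligned.tobytes().decode()
        else:
            # splice indels (tracking each spliced base's ref offset, -1 for
            # inserted bases), then truncate at the 3' end
            events = sorted(
                [(p, "ins", s) for p, s in ins] + [(p, "del", s) for p, s in dels]
            )
            parts_seq: list[np.ndarray] = []
            parts_off: list[np.ndarray] = []
            ins_spans: list[tuple[int, int, str]] = []  # (spliced start, length, seq) per insertion
            cursor = 0
            spliced_len = 0
            for p, kind, s in events:
                off = p - start
                if kind == "ins":
                    parts_seq.append(base[cursor : off + 1])
                    parts_off.append(np.arange(cursor, off + 1))
                    spliced_len += off + 1 - cursor
                    ins_spans.append((spliced_len, len(s), s))
                    parts_seq.append(np.frombuffer(s.encode(), dtype=np.uint8))
                    parts_off.append(np.full(len(s), -1))
                    spliced_len += len(s)
                    cursor = off + 1
                else:
                    parts_seq.append(base[cursor:off])
                    parts_off.append(np.arange(cursor, off))
                    spliced_len += off - cursor
                    cursor = off + len(s)
            parts_seq.append(base[cursor:])
            parts_off.append(np.arange(cursor, n_window))
            full_seq = np.concatenate(parts_seq)
            full_off = np.concatenate(parts_off)
            trunc_off = full_off[:length]
            covered = trunc_off[trunc_off >= 0]
            n_ref = int(covered.max()) + 1 if covered.size else 0
            spliced = full_seq[:length].tobytes().decode()
            covered_end = start + n_ref - 1
            r_ins = tuple(
                (p, s)
                for (sp_start, sp_len, s), (p, _) in zip(ins_spans, ins)
                if sp_start + sp_len <= length
            )
            r_dels = tuple((p, s) for p, s in dels if p + len(s) <= covered_end)

        pad = max(0, length - len(spliced))
        if pad:
            tail = _BASE_ARR[rng.integers(0, 4, size=pad)].tobytes().decode()
            spliced = spliced + tail

        q = int(round(rng.normal(q_mean, q_sd)))
        q = min(40, max(2, q))
        reads.append(
            SimulatedRead(
                read_id=f"{dip.sample_id}_r{i:04d}",
                sequence=spliced,
                qualities=chr(q + 33) * len(spliced),
                sample_id=dip.sample_id,
                hap=tag,
                ref_start=start,
                n_ref=n_ref,
                insertions=r_ins,
                deletions=r_dels,
                pad=pad,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# FASTQ and truth-table I/O


def _events_str(events: tuple[tuple[int, str], ...]) -> str:
    return ";".join(f"{p}:{s}" for p, s in events) or "."


def _parse_events(text: str) -> tuple[tuple[int, str], ...]:
    if text == ".":
        return ()
    out = []
    for part in text.split(";"):
        p, s = part.split(":")
        out.append((int(p), s))
    return tuple(out)


def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    """Write reads as Sanger (Phred+33) FASTQ; truth and coordinate metadata
    travel in the description field."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description=(
            f"sample={r.sample_id} hap={r.hap} start={r.ref_start} nref={r.n_ref} "
            f"ins={_events_str(r.insertions)} del={_events_str(r.deletions)} pad={r.pad}"
        ))
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.qualities]
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path: str | Path) -> list[SimulatedRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        meta = dict(kv.split("=", 1) for kv in rec.description.split()[1:])
        reads.append(
            SimulatedRead(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities="".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
                sample_id=meta["sample"],
                hap=meta["hap"],
                ref_start=int(meta["start"]),
                n_ref=int(meta["nref"]),
                insertions=_parse_events(meta["ins"]),
                deletions=_parse_events(meta["del"]),
                pad=int(meta["pad"]),
            )
        )
    return reads


def write_truth_table(cohort: list[TrueDiplotype], path: str | Path) -> None:
    rows = []
    for d in cohort:
        rows.append(
            {
                "sample_id": d.sample_id,
                "hap_a_allele": d.hap_a.allele,
                "hap_a_extras": format_variant_set(d.hap_a.extra_variants) or ".",
                "hap_b_allele": d.hap_b.allele,
                "hap_b_extras": format_variant_set(d.hap_b.extra_variants) or ".",
                "deletion_assay_positive": int(d.deletion_assay_positive),
                "duplication_assay_positive": int(d.duplication_assay_positive),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[TrueDiplotype]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            TrueDiplotype(
                sample_id=r["sample_id"],
                hap_a=HaplotypeSpec(
                    r["hap_a_allele"],
                    extra_variants=parse_variant_set(r["hap_a_extras"].replace(".", "")),
                ),
                hap_b=HaplotypeSpec(
                    r["hap_b_allele"],
                    extra_variants=parse_variant_set(r["hap_b_extras"].replace(".", "")),
                ),
                deletion_assay_positive=bool(int(r["deletion_assay_positive"])),
                duplication_assay_positive=bool(int(r["duplication_assay_positive"])),
            )
        )
    return out
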