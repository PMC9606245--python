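"""End-to-end pipeline: simulate -> QC -> phase -> call -> phenotype -> report.

Two execution modes share every calling stage:

``reads``
    full read-level run — simulate nanopore-like reads per sample, apply
    read/sample QC, detect candidate sites, phase by read clustering, then
    call. This is the fidelity path used to validate the calling stack
    against simulator truth.

``truth``
    desk-scale run — phased call sets are taken directly from the cohort's
    true haplotype variant sets (allelic dropout for *5 preserved). This is
    the path for whole-cohort table reproduction, where read-level noise is
    not the question.

Outputs are deterministic for a fixed seed: re-running a config reproduces
byte-identical report files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .caller import (
    AnnotationTable,
    DiplotypeResult,
    GeneModel,
    NovelVariantReport,
    StructuralAssay,
    cohort_call,
    distinct_alleles,
)
from .cohort import (
    SimParams,
    SyntheticReference,
    TrueDiplotype,
    build_reference,
    make_cohort,
    simulate_reads,
    study_composition,
    novel_variant_placements,
)
from .definitions import DefinitionTable, load_bundled_definitions, parse_definition_table
from .phenotype import cohort_phenotypes, phenotype_sample
from .popgen import CohortFrequencyTable, allele_frequencies, round_half_up
from .reads import (
    PhasedCallSet,
    QCParams,
    build_observation_matrix,
    check_sample_depth,
    detect_candidate_sites,
    excluded_callset,
    filter_reads,
    phase_sample,
)

_IMPACT = {
    "normal": "Normal function",
    "decreased": "Decreased function",
    "none": "No function",
    "uncertain": "Uncertain function",
    "unknown": "Unknown function",
}


@dataclass
class PipelineConfig:
    """Everything a run needs; every threshold is surfaced here."""

    seed: int = 1
    mode: str = "truth"  # "truth" | "reads"
    truth_definitions: str = "current"  # bundled name or TSV path
    matching_definitions: str = "prior"
    composition: str | None = None  # TSV path; None -> bundled study composition
    novel_spec: str | None = None
    gene_model: str | None = None
    annotation: str | None = None
    n_samples: int | None = None  # subset for scaled-down runs
    qc: QCParams = field(default_factory=QCParams)
    sim: SimParams = field(default_factory=SimParams)
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("truth", "reads"):
            raise ValueError(f"mode must be 'truth' or 'reads', got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "qc" in raw:
            raw["qc"] = QCParams(**raw["qc"])
        if "sim" in raw:
            raw["sim"] = SimParams(**raw["sim"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _load_definitions(spec: str) -> DefinitionTable:
    if spec in ("current", "prior"):
        return load_bundled_definitions(spec)
    return parse_definition_table(spec)


@dataclass
class RunResult:
    cohort: list[TrueDiplotype]
    reference: SyntheticReference
    callsets: list[PhasedCallSet]
    results: list[DiplotypeResult]
    novel_report: NovelVariantReport
    frequencies: CohortFrequencyTable
    phenotypes: pd.DataFrame
    qc_rows: list[dict]

    @property
    def n_called(self) -> int:
        return sum(not r.excluded for r in self.results)

    @property
    def n_excluded(self) -> int:
        return sum(r.excluded for r in self.results)

    @property
    def allele_census(self) -> list[str]:
        return distinct_alleles(self.results)


def truth_callset(
    dip: TrueDiplotype, table: DefinitionTable, depth: int = 100
) -> PhasedCallSet:
    """A perfect phased call set straight from the truth haplotypes, with
    *5 allelic dropout reproduced (a deleted haplotype is invisible to the
    sequencer, so the sample presents as a single haplotype)."""
    sets = [
        None if hap.is_deletion(table) else hap.variant_set(table)
        for hap in dip.haplotypes()
    ]
    present = [s for s in sets if s is not None]
    if not present:
        return excluded_callset(dip.sample_id, "no_reads")
    if len(present) == 1:
        return PhasedCallSet(
            sample_id=dip.sample_id,
            hap1_variants=present[0],
            hap2_variants=present[0],
            site_stats=[],
            phasing_confidence=1.0,
            n_reads_hap1=depth,
            n_reads_hap2=0,
        )
    return PhasedCallSet(
        sample_id=dip.sample_id,
        hap1_variants=present[0],
        hap2_variants=present[1],
        site_stats=[],
        phasing_confidence=1.0,
        n_reads_hap1=depth // 2,
        n_reads_hap2=depth - depth // 2,
    )


def call_sample_from_reads(
    dip: TrueDiplotype,
    ref: SyntheticReference,
    table: DefinitionTable,
    qc: QCParams,
    sim: SimParams,
    seed: int,
) -> tuple[PhasedCallSet, dict]:
    """Simulate, QC and phase one sample; returns the call set and a QC row."""
    reads = simulate_reads(
        dip,
        ref,
        table,
        depth=sim.depth,
        error_rate=sim.error_rate,
        length_sd=sim.length_sd,
        q_mean=sim.q_mean,
        q_sd=sim.q_sd,
        seed=seed,
    )
    retained, report = filter_reads(reads, qc)
    qc_row = {
        "sample_id": dip.sample_id,
        "n_reads": report.n_input,
        "n_retained": report.n_retained,
        "n_too_short": report.n_too_short,
        "n_too_long": report.n_too_long,
        "n_low_quality": report.n_low_quality,
    }
    if not check_sample_depth(retained, qc):
        qc_row["excluded"] = "low_read_depth"
        return excluded_callset(dip.sample_id, "low_read_depth"), qc_row
    qc_row["excluded"] = ""
    sites = detect_candidate_sites(retained, ref)
    matrix = build_observation_matrix(retained, ref, sites, sample_id=dip.sample_id)
    return phase_sample(matrix), qc_row


def run_pipeline(config: PipelineConfig) -> RunResult:
    truth_table = _load_definitions(config.truth_definitions)
    matching_table = _load_definitions(config.matching_definitions)
    gene_model = (
        GeneModel.from_bed(config.gene_model) if config.gene_model else GeneModel.bundled()
    )
    annotation = (
        AnnotationTable.from_tsv(config.annotation)
        if config.annotation
        else AnnotationTable.bundled()
    )
    if config.composition:
        df = pd.read_csv(config.composition, sep="\t")
        composition = dict(zip(df["allele"], df["haplotypes"].astype(int)))
    else:
        composition = study_composition()
    if config.novel_spec:
        from .variants import VariantKey

        df = pd.read_csv(config.novel_spec, sep="\t", dtype=str, keep_default_na=False)
        novel_spec = [
            (VariantKey(int(r["position"]), r["ref"], r["alt"]), r["background_allele"], int(r["carriers"]))
            for _, r in df.iterrows()
        ]
    else:
        novel_spec = novel_variant_placements()

    reference = build_reference(config.seed)
    cohort = make_cohort(truth_table, composition, novel_spec, seed=config.seed)
    if config.n_samples is not None:
        cohort = cohort[: config.n_samples]

    qc_rows: list[dict] = []
    callsets: list[tuple[PhasedCallSet, StructuralAssay]] = []
    seeds = np.random.SeedSequence(config.seed).generate_state(len(cohort)) % (2**31)
    for dip, sample_seed in zip(cohort, seeds):
        if config.mode == "truth":
            cs = truth_callset(dip, truth_table, depth=config.sim.depth)
            qc_rows.append(
                {
                    "sample_id": dip.sample_id,
                    "n_reads": config.sim.depth,
                    "n_retained": config.sim.depth,
                    "n_too_short": 0,
                    "n_too_long": 0,
                    "n_low_quality": 0,
                    "excluded": cs.exclusion_reason,
                }
            )
        else:
            cs, qc_row = call_sample_from_reads(
                dip, reference, truth_table, config.qc, config.sim, int(sample_seed)
            )
            qc_rows.append(qc_row)
        callsets.append(
            (cs, StructuralAssay(dip.deletion_assay_positive, dip.duplication_assay_positive))
        )

    results, novel_report = cohort_call(callsets, matching_table, gene_model, annotation)
    if any(not r.excluded for r in results):
        frequencies = allele_frequencies(results, cohort_name="cohort")
    else:  # nothing callable: empty report rather than a crash
        frequencies = CohortFrequencyTable(
            cohort_name="cohort",
            n_samples=0,
            table=pd.DataFrame(columns=["allele", "count", "frequency"]),
        )
    phenos = cohort_phenotypes(results, matching_table)

    run = RunResult(
        cohort=cohort,
        reference=reference,
        callsets=[cs for cs, _ in callsets],
        results=results,
        novel_report=novel_report,
        frequencies=frequencies,
        phenotypes=phenos,
        qc_rows=qc_rows,
    )
    if config.outdir:
        render_reports(run, matching_table, config, Path(config.outdir))
    return run


def render_reports(
    run: RunResult,
    table: DefinitionTable,
    config: PipelineConfig,
    outdir: Path,
) -> None:
    """Write the report TSV set (allele frequencies, phenotypes, novel
    variants, per-sample diplotypes, QC) plus a machine-readable manifest."""
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for _, r in run.frequencies.table.iterrows():
        allele = r["allele"]
        if allele in table.alleles:
            d = table.alleles[allele]
            act = "?" if d.activity is None else f"{d.activity:g}"
            impact = _IMPACT[d.function]
        else:
            act, impact = "?", "Unknown function"
        rows.append(
            {
                "allele": allele,
                "frequency": f"{r['frequency']:.3f}",
                "haplotypes": int(r["count"]),
                "activity_score": act,
                "impact": impact,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "allele_frequencies.tsv", sep="\t", index=False)

    ph = run.phenotypes.copy()
    ph["frequency"] = [f"{round_half_up(x, 3):.3f}" for x in ph["frequency"]]
    ph.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)

    novel_rows = []
    for e in run.novel_report.entries:
        novel_rows.append(
            {
                "position": e.variant.position,
                "region": e.region,
                "variant": str(e.variant),
                "rsid": e.rsid or "rs/na",
                "consequence": e.consequence,
                "n_observed": e.n_carriers,
                "background": e.background_allele,
                "proposal": e.proposal,
                "designation": e.designation,
                "previously_known": int(e.previously_known),
            }
        )
    pd.DataFrame(
        novel_rows,
        columns=[
            "position",
            "region",
            "variant",
            "rsid",
            "consequence",
            "n_observed",
            "background",
            "proposal",
            "designation",
            "previously_known",
        ],
    ).to_csv(outdir / "novel_variants.tsv", sep="\t", index=False)

    dip_rows = []
    for r in run.results:
        if r.excluded:
            dip_rows.append(
                {
                    "sample_id": r.sample_id,
                    "diplotype": "",
                    "activity_score": "",
                    "phenotype": "",
                    "excluded": r.exclusion_reason,
                }
            )
            continue
        p = phenotype_sample(r, table)
        dip_rows.append(
            {
                "sample_id": r.sample_id,
                "diplotype": r.diplotype_string,
                "activity_score": "" if p.activity_score is None else f"{p.activity_score:g}",
                "phenotype": p.phenotype,
                "excluded": "",
            }
        )
    pd.DataFrame(dip_rows).to_csv(outdir / "diplotypes.tsv", sep="\t", index=False)

    pd.DataFrame(run.qc_rows).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)

    cfg = config.to_dict()
    cfg.pop("outdir", None)  # output location is not part of the run identity
    manifest = {
        "tool": "starcall",
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "n_samples": len(run.cohort),
        "n_called": run.n_called,
        "n_excluded": run.n_excluded,
        "allele_census": run.allele_census,
        "n_novel_variants": len(run.novel_report.novel_entries),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
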