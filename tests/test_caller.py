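import random

import pytest

import starcall as sc
from starcall.caller import (
    HaplotypeCall,
    ReadEvidence,
    StructuralAssay,
    classify_novel,
    cohort_call,
    distinct_alleles,
    integrate_structural,
    match_haplotype,
)
from starcall.definitions import DefinitionTable, StarAlleleDefinition
from starcall.pipeline import PipelineConfig, run_pipeline, truth_callset
from starcall.variants import VariantKey, parse_variant


def V(text):
    return parse_variant(text)


class TestMatchHaplotype:
    def test_no_core_variants_defaults_to_reference_allele(self, prior_table):
        call = match_haplotype({V("7061G>C")}, prior_table)
        assert call.matched_allele == "*1"
        assert call.unmatched_variants == {V("7061G>C")}

    def test_empty_set_is_clean_reference(self, prior_table):
        call = match_haplotype(frozenset(), prior_table)
        assert call.matched_allele == "*1"
        assert call.matched_suballele is None
        assert not call.unmatched_variants

    def test_known_suballele_is_selected(self, current_table):
        hap = current_table.alleles["*41"].core_variants | {V("6528G>A")}
        call = match_haplotype(hap, current_table)
        assert (call.matched_allele, call.matched_suballele) == ("*41", "*41.006")
        assert not call.unmatched_variants

    def test_unknown_variant_on_known_background_left_unmatched(self, prior_table):
        hap = prior_table.alleles["*10"].core_variants | {V("9414C>T")}
        call = match_haplotype(hap, prior_table)
        assert call.matched_allele == "*10"
        assert call.unmatched_variants == {V("9414C>T")}

    def test_largest_core_set_wins(self, current_table):
        # *35's core is a superset of *2's; a *35 haplotype satisfies both
        call = match_haplotype(current_table.alleles["*35"].core_variants, current_table)
        assert call.matched_allele == "*35"
        assert not call.ambiguous

    def test_core_size_tie_breaks_to_lowest_star_and_flags(self, current_table):
        defs = {
            "*1": current_table.alleles["*1"],
            "*5": current_table.alleles["*5"],
            "*7": StarAlleleDefinition("*7", frozenset({V("5065C>T")}), {}, "normal", 1.0),
            "*9": StarAlleleDefinition("*9", frozenset({V("5065C>T")}), {}, "normal", 1.0),
        }
        table = DefinitionTable("test", defs)
        call = match_haplotype({V("5065C>T")}, table)
        assert call.matched_allele == "*7"
        assert call.ambiguous

    def test_monotone_in_added_variants(self, current_table):
        # adding variants never shrinks the matched core set
        rng = random.Random(0)
        universe = sorted(current_table.all_known_variants)
        for _ in range(50):
            hap = set(rng.sample(universe, rng.randint(0, 8)))
            size0 = len(current_table.alleles[match_haplotype(hap, current_table).matched_allele].core_variants)
            extra = rng.choice(universe)
            size1 = len(current_table.alleles[match_haplotype(hap | {extra}, current_table).matched_allele].core_variants)
            assert size1 >= size0


class TestIntegrateStructural:
    def _call(self, table, allele):
        return match_haplotype(table.alleles[allele].core_variants, table)

    def test_single_haplotype_plus_deletion_assay_gives_star5(self, prior_table):
        c = self._call(prior_table, "*1")
        res = integrate_structural(
            "S", c, c, StructuralAssay(deletion_positive=True), ReadEvidence(1)
        )
        assert res.diplotype_string == "*1/*5"
        assert res.deletion_integrated

    def test_negative_assays_pass_through(self, prior_table):
        a, b = self._call(prior_table, "*1"), self._call(prior_table, "*41")
        res = integrate_structural("S", a, b, StructuralAssay(), ReadEvidence(2, (0.5, 0.5)))
        assert res.diplotype_string == "*1/*41"
        assert not res.deletion_integrated and not res.conflict

    def test_homozygous_looking_deletion_carrier_recalled(self, prior_table):
        # truth *10/*5 presents as an apparent *10 homozygote
        c = self._call(prior_table, "*10")
        res = integrate_structural(
            "S", c, c, StructuralAssay(deletion_positive=True), ReadEvidence(1)
        )
        assert res.diplotype_string == "*5/*10"  # numeric star order

    def test_two_haplotypes_with_positive_assay_is_conflict(self, prior_table):
        a, b = self._call(prior_table, "*1"), self._call(prior_table, "*2")
        res = integrate_structural(
            "S", a, b, StructuralAssay(deletion_positive=True), ReadEvidence(2, (0.5, 0.5))
        )
        assert res.conflict
        assert res.diplotype_string == "*1/*2"  # calls not silently overwritten

    def test_diplotype_string_sorted_numerically(self, prior_table):
        a, b = self._call(prior_table, "*10"), self._call(prior_table, "*2")
        res = integrate_structural("S", a, b, StructuralAssay(), ReadEvidence(2))
        assert res.diplotype_string == "*2/*10"
        swapped = integrate_structural("S", b, a, StructuralAssay(), ReadEvidence(2))
        assert swapped.diplotype_string == res.diplotype_string


class TestClassifyNovel:
    def _background(self, table, allele="*1"):
        return match_haplotype(table.alleles[allele].core_variants, table)

    @pytest.mark.parametrize(
        "variant, background, expected",
        [
            ("6071A>G", "*1", "candidate_new_star"),  # missense
            ("6947G>A", "*1", "candidate_new_star"),  # missense
            ("7061G>C", "*1", "new_suballele_of:*1"),  # intronic
            ("8887C>T", "*2", "new_suballele_of:*2"),  # synonymous
            ("4818G>A", "*4", "new_suballele_of:*4"),  # promoter
        ],
    )
    def test_proposals_follow_consequence_rules(
        self, prior_table, gene_model, annotation, variant, background, expected
    ):
        entry = classify_novel(
            V(variant), self._background(prior_table, background), gene_model, annotation, prior_table
        )
        assert entry.proposal == expected

    def test_deleterious_known_core_variant_nominates_new_star(
        self, prior_table, gene_model, annotation
    ):
        entry = classify_novel(
            V("8934C>T"), self._background(prior_table), gene_model, annotation, prior_table
        )
        assert entry.proposal == "candidate_new_star"
        assert entry.core_of == ["*136"]
        assert entry.previously_known

    def test_benign_known_core_variant_stays_suballele(
        self, prior_table, gene_model, annotation
    ):
        entry = classify_novel(
            V("9414C>T"), self._background(prior_table, "*10"), gene_model, annotation, prior_table
        )
        assert entry.proposal == "new_suballele_of:*10"
        assert entry.core_of == ["*56"]

    def test_position_outside_gene_model_still_reported(
        self, prior_table, gene_model, annotation
    ):
        entry = classify_novel(
            V("100A>G"), self._background(prior_table), gene_model, annotation, prior_table
        )
        assert entry.region == "unannotated"

    @pytest.mark.parametrize(
        "variant, region",
        [("4818G>A", "promoter"), ("6528G>A", "intron2"), ("8887C>T", "exon8")],
    )
    def test_region_labels(self, prior_table, gene_model, annotation, variant, region):
        entry = classify_novel(
            V(variant), self._background(prior_table), gene_model, annotation, prior_table
        )
        assert entry.region == region


@pytest.fixture(scope="module")
def study_run():
    return run_pipeline(PipelineConfig(seed=1, mode="truth"))


class TestCohortCall:
    def test_study_cohort_census(self, study_run):
        assert len(study_run.allele_census) == 13
        assert len(study_run.novel_report.novel_entries) == 12

    def test_novel_carrier_counts(self, study_run):
        assert study_run.novel_report.by_variant(V("6528G>A")).n_carriers == 19

    def test_single_reference_homozygote(self, current_table, prior_table):
        cohort = sc.make_cohort(current_table, {"*1": 2}, seed=0)
        callsets = [
            (truth_callset(d, current_table), StructuralAssay()) for d in cohort
        ]
        results, report = cohort_call(callsets, prior_table)
        assert distinct_alleles(results) == ["*1"]
        assert report.entries == []

    def test_permutation_invariance_over_samples(self, current_table, prior_table):
        comp = {"*1": 6, "*41": 4, "*71": 2}
        cohort = sc.make_cohort(current_table, comp, seed=4)
        callsets = [
            (truth_callset(d, current_table), StructuralAssay(d.deletion_assay_positive))
            for d in cohort
        ]
        fwd, _ = cohort_call(callsets, prior_table)
        rev, _ = cohort_call(callsets[::-1], prior_table)
        assert {r.sample_id: r.diplotype_string for r in fwd} == {
            r.sample_id: r.diplotype_string for r in rev
        }

    def test_no_variant_silently_dropped(self, study_run, prior_table):
        # every observed non-reference variant is either matched or reported
        reported = {e.variant for e in study_run.novel_report.entries}
        for cs, r in zip(study_run.callsets, study_run.results):
            matched = r.call_a.match_basis | r.call_b.match_basis
            for v in cs.hap1_variants | cs.hap2_variants:
                assert v in matched or v in reported

    def test_excluded_samples_propagate_reason(self, current_table, prior_table):
        from starcall.reads import excluded_callset

        callsets = [
            (excluded_callset("S1", "low_read_depth"), StructuralAssay()),
            (truth_callset(sc.make_cohort(current_table, {"*1": 2}, seed=0)[0], current_table),
             StructuralAssay()),
        ]
        results, _ = cohort_call(callsets, prior_table)
        assert results[0].excluded and results[0].exclusion_reason == "low_read_depth"
        assert not results[1].excluded
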