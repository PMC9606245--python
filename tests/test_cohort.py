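import io
from collections import Counter

import numpy as np
import pytest

import starcall as sc
from starcall.cohort import (
    HaplotypeSpec,
    TrueDiplotype,
    build_reference,
    haplotype_sequence,
    make_cohort,
    read_fastq,
    simulate_reads,
    write_fastq,
)
from starcall.variants import VariantKey


class TestBuildReference:
    def test_deterministic_for_fixed_seed(self):
        assert build_reference(1).sequence == build_reference(1).sequence

    def test_different_seeds_differ(self):
        assert build_reference(1).sequence != build_reference(2).sequence

    def test_gc_content_near_half(self, reference):
        s = reference.sequence
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.5) < 0.05

    def test_known_variant_positions_are_anchored(self, reference, current_table):
        for v in current_table.all_known_variants:
            if v.ref:
                assert reference.base(v.position) == v.ref

    def test_too_short_reference_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build_reference(1, length=4_000)


class TestMakeCohort:
    def test_study_composition_reproduced_exactly(self, study_cohort):
        census = Counter(h.allele for d in study_cohort for h in d.haplotypes())
        assert dict(census) == sc.study_composition()
        assert len(study_cohort) == 202
        assert sum(census.values()) == 404

    def test_single_homozygote(self, current_table):
        cohort = make_cohort(current_table, {"*1": 2}, seed=0)
        (dip,) = cohort
        assert dip.hap_a.allele == dip.hap_b.allele == "*1"
        assert not dip.deletion_assay_positive

    def test_odd_total_rejected(self, current_table):
        with pytest.raises(ValueError, match="even"):
            make_cohort(current_table, {"*1": 3}, seed=0)

    def test_novel_background_must_exist(self, current_table):
        spec = [(VariantKey(6528, "G", "A"), "*41", 1)]
        with pytest.raises(ValueError, match="background"):
            make_cohort(current_table, {"*1": 4}, spec, seed=0)

    def test_novel_carriers_in_distinct_samples(self, study_cohort):
        for v, expected in [
            (VariantKey(6528, "G", "A"), 19),
            (VariantKey(8406, "", "AGCACC"), 2),
            (VariantKey(9021, "A", "G"), 1),
        ]:
            carriers = [
                d.sample_id
                for d in study_cohort
                for h in d.haplotypes()
                if v in h.extra_variants
            ]
            assert len(carriers) == expected
            assert len(set(carriers)) == expected

    def test_novel_variants_sit_on_stated_backgrounds(self, study_cohort):
        for d in study_cohort:
            for h in d.haplotypes():
                if VariantKey(6528, "G", "A") in h.extra_variants:
                    assert h.allele == "*41"

    def test_deletion_haplotypes_flag_assay_and_never_pair(self, study_cohort, current_table):
        n_del_haps = 0
        for d in study_cohort:
            deleted = [h.is_deletion(current_table) for h in d.haplotypes()]
            n_del_haps += sum(deleted)
            assert sum(deleted) <= 1
            assert d.deletion_assay_positive == any(deleted)
            assert not d.duplication_assay_positive  # none observed in the study
        assert n_del_haps == 5

    def test_pairing_depends_on_seed(self, current_table):
        comp = {"*1": 20, "*2": 10, "*10": 10}
        a = make_cohort(current_table, comp, seed=1)
        b = make_cohort(current_table, comp, seed=2)
        assert [d.hap_a.allele for d in a] != [d.hap_a.allele for d in b]


class TestHaplotypeSequence:
    def test_reference_haplotype_is_window_identity(self, reference, current_table):
        s = haplotype_sequence(reference, HaplotypeSpec("*1"), current_table)
        start, end = reference.amplicon_window
        assert s == reference.sequence[start - 1 : end]

    def test_snv_changes_exactly_one_offset(self, reference, current_table):
        hap = HaplotypeSpec("*71")  # single core SNV at 5168
        s = haplotype_sequence(reference, hap, current_table)
        ref_s = haplotype_sequence(reference, HaplotypeSpec("*1"), current_table)
        diffs = [i for i, (x, y) in enumerate(zip(ref_s, s)) if x != y]
        assert diffs == [5168 - reference.amplicon_window[0]]

    def test_whole_gene_deletion_yields_empty_product(self, reference, current_table):
        assert haplotype_sequence(reference, HaplotypeSpec("*5"), current_table) == ""

    def test_insertion_extends_product(self, reference, current_table):
        hap = HaplotypeSpec("*1", suballele="*1.053")  # 8406insAGCACC
        s = haplotype_sequence(reference, hap, current_table)
        assert len(s) == reference.window_length + 6

    def test_overlapping_variants_rejected(self, reference, current_table):
        hap = HaplotypeSpec(
            "*71", extra_variants=frozenset({VariantKey(5168, "G", "C")})
        )
        with pytest.raises(ValueError, match="overlap"):
            haplotype_sequence(reference, hap, current_table)


class TestSimulateReads:
    def test_error_free_reads_match_their_haplotype(self, reference, current_table):
        dip = TrueDiplotype("S1", HaplotypeSpec("*1"), HaplotypeSpec("*2"), False)
        products = {
            "a": haplotype_sequence(reference, dip.hap_a, current_table),
            "b": haplotype_sequence(reference, dip.hap_b, current_table),
        }
        for r in simulate_reads(dip, reference, current_table, depth=20, error_rate=0.0, seed=5):
            aligned = r.sequence[: len(r.sequence) - r.pad]
            assert products[r.hap].startswith(aligned)

    def test_fixed_seed_gives_identical_fastq(self, tmp_path, reference, current_table):
        dip = TrueDiplotype("S1", HaplotypeSpec("*1"), HaplotypeSpec("*41"), False)
        out = []
        for name in ("a.fastq", "b.fastq"):
            reads = simulate_reads(dip, reference, current_table, depth=10, error_rate=0.05, seed=9)
            write_fastq(reads, tmp_path / name)
            out.append((tmp_path / name).read_bytes())
        assert out[0] == out[1]

    def test_deletion_haplotype_contributes_no_reads(self, reference, current_table):
        dip = TrueDiplotype("S1", HaplotypeSpec("*1"), HaplotypeSpec("*5"), True)
        reads = simulate_reads(dip, reference, current_table, depth=100, error_rate=0.0, seed=2)
        assert len(reads) == 100
        assert all(r.hap == "a" for r in reads)

    def test_double_deletion_warns_and_returns_nothing(self, reference, current_table):
        dip = TrueDiplotype("S1", HaplotypeSpec("*5"), HaplotypeSpec("*5"), True)
        with pytest.warns(UserWarning, match="both haplotypes deleted"):
            reads = simulate_reads(dip, reference, current_table, depth=10, seed=0)
        assert reads == []

    def test_substitution_count_matches_binomial_expectation(self, reference, current_table):
        # independent counting oracle: compare each full-length read to the
        # clean product; mean errors per read ~ Binomial(L, eps)
        eps, depth = 0.05, 60
        dip = TrueDiplotype("S1", HaplotypeSpec("*1"), HaplotypeSpec("*1"), False)
        product = haplotype_sequence(reference, dip.hap_a, current_table)
        L = len(product)
        reads = simulate_reads(
            dip, reference, current_table, depth=depth, error_rate=eps, length_sd=0.0, seed=11
        )
        counts = [
            sum(x != y for x, y in zip(r.sequence[:L], product)) for r in reads
        ]
        mean = np.mean(counts)
        se = np.sqrt(L * eps * (1 - eps) / depth)
        assert abs(mean - L * eps) < 2.58 * se  # central 99% interval

    def test_hap_fractions_balanced_over_seeds(self, reference, current_table):
        dip = TrueDiplotype("S1", HaplotypeSpec("*1"), HaplotypeSpec("*2"), False)
        fracs = []
        for seed in range(30):
            reads = simulate_reads(dip, reference, current_table, depth=50, error_rate=0.0, seed=seed)
            fracs.append(sum(r.hap == "a" for r in reads) / len(reads))
        se = 0.5 / np.sqrt(50 * 30)
        assert abs(np.mean(fracs) - 0.5) < 3 * se

    def test_fastq_round_trip_preserves_reads(self, tmp_path, reference, current_table):
        dip = TrueDiplotype(
            "S1", HaplotypeSpec("*1", suballele="*1.053"), HaplotypeSpec("*2"), False
        )
        reads = simulate_reads(dip, reference, current_table, depth=8, error_rate=0.02, seed=3)
        write_fastq(reads, tmp_path / "r.fastq")
        assert read_fastq(tmp_path / "r.fastq") == reads


def test_truth_table_round_trip(tmp_path, study_cohort):
    p = tmp_path / "truth.tsv"
    sc.cohort.write_truth_table(study_cohort, p)
    back = sc.cohort.read_truth_table(p)
    assert [d.sample_id for d in back] == [d.sample_id for d in study_cohort]
    assert all(
        a.hap_a.allele == b.hap_a.allele and a.hap_b.extra_variants == b.hap_b.extra_variants
        for a, b in zip(study_cohort, back)
    )
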