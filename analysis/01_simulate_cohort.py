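"""Build the study-shaped synthetic cohort and record its ground truth.

Generates the 202-sample / 404-haplotype cohort whose star-allele
composition matches the study census, places the novel variants on their
background alleles (one distinct sample per carrier), and writes the truth
table plus a small example FASTQ so the read format is inspectable.
"""

from collections import Counter
from pathlib import Path

import starcall as sc

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = sc.load_bundled_definitions("current")
    ref = sc.build_reference(SEED)
    cohort = sc.make_cohort(table, sc.study_composition(), sc.novel_variant_placements(), seed=SEED)
    sc.cohort.write_truth_table(cohort, OUT / "truth.tsv")

    census = Counter(h.allele for d in cohort for h in d.haplotypes())
    print(f"cohort: {len(cohort)} samples, {sum(census.values())} haplotypes")
    print("haplotype census:", dict(sorted(census.items(), key=lambda kv: sc.definitions.star_number(kv[0]))))
    n_del = sum(d.deletion_assay_positive for d in cohort)
    print(f"deletion-assay-positive samples: {n_del} (one per *5 haplotype)")

    carriers = Counter(str(v) for d in cohort for h in d.haplotypes() for v in h.extra_variants)
    print("novel-variant carriers:", dict(sorted(carriers.items())))

    # one example sample's reads, error-free and noisy, for format inspection
    example = cohort[0]
    for eps, name in ((0.0, "example_clean.fastq"), (0.05, "example_noisy.fastq")):
        reads = sc.simulate_reads(example, ref, table, depth=3, error_rate=eps, seed=SEED)
        sc.cohort.write_fastq(reads, OUT / name)
    print(f"wrote truth table and example FASTQs to {OUT}")


if __name__ == "__main__":
    main()
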