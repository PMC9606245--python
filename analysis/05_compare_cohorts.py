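"""Cross-cohort allele-frequency comparisons (two-sided Fisher's exact).

Comparator haplotype counts are reconstructed from published frequencies
and assumed totals (the source studies print frequencies, not counts), so
the p-values here are approximations of the published comparisons, not
re-derivations — the flag column says so. The direction and order of
magnitude are the interpretable part.
"""

from pathlib import Path

import starcall as sc
from starcall.pipeline import PipelineConfig, run_pipeline
from starcall.popgen import compare_cohorts, load_comparator_table

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    run = run_pipeline(PipelineConfig(seed=SEED, mode="truth"))
    res = compare_cohorts(run.frequencies, load_comparator_table())
    with Path(OUT / "cohort_comparisons.tsv").open("w") as fh:
        res.to_csv(fh, sep="\t", index=False)
    for _, r in res.iterrows():
        print(f"{r['cohort']:16s} {r['allele']:4s} ours {r['our_frequency']:.3f} "
              f"vs {r['their_frequency']:.3f}  p={r['p_value']:.3g} "
              f"{'significant' if r['significant'] else 'n.s.'}"
              f"{'  (reconstructed counts)' if r['reconstructed'] else ''}")
    print(f"wrote {OUT / 'cohort_comparisons.tsv'}")


if __name__ == "__main__":
    main()
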