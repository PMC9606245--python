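# starcall

Star-allele diplotype calling for the pharmacogene *CYP2D6* from long-read
amplicon sequencing, with novel-variant discovery, metaboliser-phenotype
inference and population allele-frequency comparison.

## The problem

*CYP2D6* encodes an enzyme that metabolises roughly a quarter of commonly
prescribed drugs. The gene is highly polymorphic; haplotypes are named with
star-allele nomenclature (`*1` reference, `*2`, `*4`, …), each defined by a
set of *core variants*, with minor variations tracked as *suballeles*
(`*2.031`). Each allele carries a function class and an activity value; the
diplotype activity score — the sum over the two alleles — translates to a
metaboliser phenotype:

| activity score | phenotype |
|---|---|
| 0 | poor metaboliser (PM) |
| 0.25 – 1 | intermediate (IM) |
| 1.25 – 2 | normal (NM) |
| > 2 | ultrarapid (UM) |

A diplotype containing any allele of uncertain or unknown function (e.g.
`*43`, `*71`, newly discovered alleles) has an undefined score and an
Uncertain phenotype.

Single long reads spanning a ~6.6 kb *CYP2D6* long-PCR amplicon make
phasing read-backed: each read reports one haplotype end-to-end. A
secondary 3.5 kb PCR fragment reports whole-gene deletions (`*5`) and
duplications; a `*5` haplotype contributes no amplicon template, so a
deletion carrier presents as an apparent homozygote (allelic dropout) and
the assay flag resolves it.

`starcall` implements the full analysis: read QC (length 6–8 kb, mean
Q > 9, ≥ 50 reads/sample), candidate-site detection, haplotype phasing by
2-means read clustering over heterozygous sites, star-allele and suballele
matching (most specific complete core set wins), structural-assay
integration, rule-based classification of unmatched variants (missense or
predicted-deleterious → candidate new star allele; otherwise → new
suballele of the background allele), activity-score phenotyping, and
per-allele cohort comparison by two-sided Fisher's exact test (full
hypergeometric enumeration).

Because per-sample raw data for the motivating cohort cannot be shared, the
package ships a ground-truthed synthetic-cohort generator
(`starcall.cohort`) that reproduces the cohort's published structure — 202
samples / 404 haplotypes with a fixed star-allele composition and placed
novel variants — plus a nanopore-like read simulator (substitution errors,
truncated-normal read lengths, per-read quality, `*5` dropout), so every
stage is testable against exact truth.

## Worked example

```python
from starcall.pipeline import PipelineConfig, run_pipeline

run = run_pipeline(PipelineConfig(seed=1, mode="truth", outdir="results/tables"))
print(len(run.allele_census), "alleles;",
      len(run.novel_report.novel_entries), "novel variants")
print(run.frequencies.table.head(5).to_string(index=False))
```

prints

```
13 alleles; 12 novel variants
allele  count  frequency
    *1    189      0.468
    *2     57      0.141
    *4      7      0.017
    *5      5      0.012
   *10     74      0.183
```

i.e. thirteen distinct star alleles over 404 haplotypes, with `*1` at
frequency 0.468 (189/404) and the `*5` gene deletion at 0.012, and twelve
variants absent from the allele-definition table, classified into four
candidate new star alleles and new suballeles. `mode="truth"` takes phased
call sets straight from the generator (desk-scale reproduction);
`mode="reads"` runs the same calling stack from simulated reads.

The numbered scripts under `analysis/` walk the full study: cohort
simulation (`01`), diplotype calling and read-level validation (`02`),
phenotyping (`03`), novel-variant classification (`04`) and cross-cohort
Fisher comparisons (`05`). Each writes its tables under `results/`. A CLI
is included: `starcall run-all --mode truth --seed 1 --out results/tables`,
plus `simulate`, `defs-validate` and `compare` subcommands.

## Layout

```
src/starcall/        library (definitions, cohort, reads, caller,
                     phenotype, popgen, pipeline, cli) + bundled data
analysis/            numbered narrative drivers
scripts/acceptance.py
tests/               pytest suite (unit, property, acceptance)
docs/methods.md      model, parameters, design choices, limitations
```

Note: the bundled allele-definition tables use synthetic core-variant sets
for the previously known alleles (the real definition sets are maintained
by PharmVar and are not redistributed here); coordinates, functions and
activity values follow the study reference. See `docs/methods.md`.
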