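"""Allele-frequency tabulation and cross-cohort Fisher's exact comparisons.

Frequencies are haplotype counts over 2N chromosomes, reported at three
decimals (half-up, matching how such cohort tables are printed). Cohorts
are compared per allele with the conventional two-sided Fisher's exact
test: the p-value is the total hypergeometric probability of all tables
with the same margins whose probability does not exceed the observed
table's (relative tolerance 1e-7 for floating-point ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .caller import DiplotypeResult
from .definitions import star_sort_key

_TIE_REL_TOL = 1e-7


def round_half_up(x: float, ndigits: int = 3) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"), rounding=ROUND_HALF_UP))


@dataclass
class CohortFrequencyTable:
    """Per-allele haplotype counts and frequencies over 2N chromosomes."""

    cohort_name: str
    n_samples: int
    table: pd.DataFrame  # columns: allele, count, frequency

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_samples

    def count(self, allele: str) -> int:
        rows = self.table.loc[self.table["allele"] == allele, "count"]
        return int(rows.iloc[0]) if len(rows) else 0

    def frequency(self, allele: str) -> float:
        rows = self.table.loc[self.table["allele"] == allele, "frequency"]
        return float(rows.iloc[0]) if len(rows) else 0.0


def allele_frequencies(
    results: list[DiplotypeResult], cohort_name: str = "cohort"
) -> CohortFrequencyTable:
    """Tabulate allele counts over all called samples' haplotypes.

    Excluded samples are omitted (their count is recoverable from the
    results list); each called sample contributes two haplotypes.
    """
    called = [r for r in results if not r.excluded]
    if not called:
        raise ValueError("no called samples to tabulate")
    counts: dict[str, int] = {}
    for r in called:
        for a in r.alleles:
            counts[a] = counts.get(a, 0) + 1
    two_n = 2 * len(called)
    alleles = sorted(counts, key=star_sort_key)
    df = pd.DataFrame(
        {
            "allele": alleles,
            "count": [counts[a] for a in alleles],
            "frequency": [round_half_up(counts[a] / two_n, 3) for a in alleles],
        }
    )
    return CohortFrequencyTable(cohort_name=cohort_name, n_samples=len(called), table=df)


@dataclass(frozen=True)
class TwoByTwo:
    """Carrier/non-carrier x cohort1/cohort2 contingency counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def fisher_two_sided(t: TwoByTwo) -> float:
    """Exact two-sided Fisher p-value by hypergeometric enumeration."""
    r1, r2, c1, _ = t.margins
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1 by convention")
        return 1.0
    dist = hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(t.a)
    mask = pmf <= p_obs * (1 + _TIE_REL_TOL)
    if mask.all():
        return 1.0  # every table is at least as extreme
    return min(float(pmf[mask].sum()), 1.0)


def load_comparator_table(path: str | Path | None = None) -> pd.DataFrame:
    """Comparator cohorts as (cohort, allele, count, total) rows. Counts
    reconstructed from published frequencies are flagged ``reconstructed``."""
    if path is None:
        with resources.as_file(
            resources.files("starcall.data").joinpath("comparator_cohorts.tsv")
        ) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def compare_cohorts(
    ours: CohortFrequencyTable,
    other: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Fisher comparison of per-allele haplotype counts between
    our cohort and each comparator cohort.

    ``other`` columns: cohort, allele, count, total (haplotypes), and
    optionally ``reconstructed``. Alleles absent from one side are treated
    as count 0 with a note.
    """
    rows = []
    for _, r in other.iterrows():
        allele = r["allele"]
        total2 = int(r["total"])
        if total2 <= 0:
            raise ValueError(f"{r['cohort']}: comparator total must be positive")
        count2 = int(r["count"])
        count1 = ours.count(allele)
        note = "" if (ours.table["allele"] == allele).any() else "absent from our cohort"
        t = TwoByTwo(count1, ours.n_haplotypes - count1, count2, total2 - count2)
        p = fisher_two_sided(t)
        rows.append(
            {
                "cohort": r["cohort"],
                "allele": allele,
                "our_count": count1,
                "our_total": ours.n_haplotypes,
                "our_frequency": round_half_up(count1 / ours.n_haplotypes, 3),
                "their_count": count2,
                "their_total": total2,
                "their_frequency": round_half_up(count2 / total2, 3),
                "p_value": p,
                "significant": p < alpha,
                "reconstructed": str(r.get("reconstructed", "")) == "yes",
                "note": note,
            }
        )
    return pd.DataFrame(rows)
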