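"""Diplotype activity scores and metaboliser phenotype classes.

The diplotype activity score is the sum of the two alleles' activity
values. Scores translate to metaboliser classes as: 0 -> poor (PM),
0.25-1 -> intermediate (IM), 1.25-2 -> normal (NM), above 2 -> ultrarapid
(UM). A diplotype containing any allele of uncertain or unknown function
(here *43, *71 and the novel stars) has an undefined score and an
Uncertain phenotype — the uncertainty dominates regardless of the partner
allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .caller import DiplotypeResult
from .definitions import DefinitionTable

PHENOTYPE_CLASSES = ("UM", "NM", "IM", "PM", "Uncertain")

_DISPLAY = {
    "UM": "Ultrarapid",
    "NM": "Normal",
    "IM": "Intermediate",
    "PM": "Poor",
    "Uncertain": "Uncertain/unknown",
}


@dataclass(frozen=True)
class PhenotypeResult:
    sample_id: str
    activity_score: float | None
    phenotype: str
    driving_alleles: tuple[str, str]


def _allele_activity(
    label: str, table: DefinitionTable, *, novel: bool = False
) -> float | None:
    if label in table.alleles:
        return table.alleles[label].activity
    if novel:
        return None  # promoted novel star: unknown function by definition
    raise KeyError(f"allele {label} not in definition table")


def activity_score(dip: DiplotypeResult, table: DefinitionTable) -> float | None:
    """Sum of the two alleles' activity values; undefined (None) if either
    allele's function is uncertain or unknown."""
    a = _allele_activity(dip.allele_a, table, novel=dip.novel_a)
    b = _allele_activity(dip.allele_b, table, novel=dip.novel_b)
    if a is None or b is None:
        return None
    return a + b


def classify_phenotype(score: float | None) -> str:
    """Map a diplotype activity score to a metaboliser class.

    Allele activities are multiples of 0.25, so sums in the open gaps
    (0, 0.25) and (1, 1.25) are unreachable and rejected loudly rather than
    rounded.
    """
    if score is None:
        return "Uncertain"
    if score < 0 or round(score * 4) != score * 4:
        raise ValueError(f"activity score {score} is not a reachable quarter-step value")
    if score == 0:
        return "PM"
    if 0.25 <= score <= 1:
        return "IM"
    if 1.25 <= score <= 2:
        return "NM"
    if score > 2:
        return "UM"
    raise ValueError(f"activity score {score} falls in an unreachable gap")


def phenotype_sample(dip: DiplotypeResult, table: DefinitionTable) -> PhenotypeResult:
    score = activity_score(dip, table)
    return PhenotypeResult(
        sample_id=dip.sample_id,
        activity_score=score,
        phenotype=classify_phenotype(score),
        driving_alleles=(dip.allele_a, dip.allele_b),
    )


def cohort_phenotypes(
    results: list[DiplotypeResult], table: DefinitionTable
) -> pd.DataFrame:
    """Counts and frequencies per phenotype class over called samples;
    classes with zero count are included."""
    called = [r for r in results if not r.excluded]
    counts = {c: 0 for c in PHENOTYPE_CLASSES}
    for r in called:
        counts[phenotype_sample(r, table).phenotype] += 1
    n = len(called)
    return pd.DataFrame(
        {
            "phenotype": list(PHENOTYPE_CLASSES),
            "label": [_DISPLAY[c] for c in PHENOTYPE_CLASSES],
            "count": [counts[c] for c in PHENOTYPE_CLASSES],
            "frequency": [counts[c] / n if n else 0.0 for c in PHENOTYPE_CLASSES],
        }
    )
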