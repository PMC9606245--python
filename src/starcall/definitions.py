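"""Star-allele definition tables (PharmVar-style).

A star allele (e.g. ``*2``) is defined by a set of *core variants* relative
to the reference allele ``*1``; a *suballele* (e.g. ``*2.031``) shares the
core variants and carries additional, usually non-functional, variants.
Each allele carries a function class and, where the function is
characterised, an activity value used for diplotype activity scoring.

The on-disk format is a tab-delimited table with columns
``allele, suballele, position, ref, alt, function, activity, structural``:
one row per defining variant (blank ``suballele`` rows define core
variants), plus a single metadata row for variant-less alleles such as the
reference ``*1`` or the whole-gene deletion ``*5``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .variants import VariantKey

FUNCTION_CLASSES = ("normal", "decreased", "none", "uncertain", "unknown")
#: function classes for which an activity value must be defined
DEFINED_ACTIVITY = frozenset({"normal", "decreased", "none"})

_COLUMNS = ["allele", "suballele", "position", "ref", "alt", "function", "activity", "structural"]


class DefinitionError(ValueError):
    """Raised for malformed or inconsistent allele-definition tables."""


def star_number(name: str) -> tuple[int, int]:
    """Numeric sort key for star labels: ``*41`` -> (41, 0), ``*41.006`` -> (41, 6)."""
    m = re.match(r"^\*(\d+)(?:\.(\d+))?$", name)
    if not m:
        raise DefinitionError(f"not a star-allele label: {name!r}")
    return int(m.group(1)), int(m.group(2) or 0)


def star_sort_key(name: str) -> tuple[int, int, int, str]:
    """Like :func:`star_number` but total: non-standard labels sort last,
    alphabetically."""
    try:
        n, s = star_number(name)
        return (0, n, s, name)
    except DefinitionError:
        return (1, 0, 0, name)


@dataclass(frozen=True)
class StarAlleleDefinition:
    """One named star allele with its core variants, suballeles and function."""

    name: str
    core_variants: frozenset[VariantKey]
    suballeles: dict[str, frozenset[VariantKey]]
    function: str
    activity: float | None
    structural: str = "none"  # "none" | "whole_gene_deletion" | "duplication_of:<name>"

    def __post_init__(self) -> None:
        star_number(self.name)
        if self.function not in FUNCTION_CLASSES:
            raise DefinitionError(f"{self.name}: unknown function class {self.function!r}")
        if (self.activity is not None) != (self.function in DEFINED_ACTIVITY):
            raise DefinitionError(
                f"{self.name}: activity must be defined iff function is one of "
                f"{sorted(DEFINED_ACTIVITY)} (function={self.function}, activity={self.activity})"
            )
        if self.activity is not None and self.activity < 0:
            raise DefinitionError(f"{self.name}: activity must be non-negative")
        if self.structural == "whole_gene_deletion" and (self.core_variants or self.suballeles):
            raise DefinitionError(f"{self.name}: a whole-gene deletion allele carries no variants")
        for sub, extra in self.suballeles.items():
            if star_number(sub)[0] != star_number(self.name)[0]:
                raise DefinitionError(f"suballele {sub} does not belong to {self.name}")
            if extra & self.core_variants:
                raise DefinitionError(f"{sub}: suballele variants overlap the core set")
            if not extra:
                raise DefinitionError(f"{sub}: suballele must add at least one variant")

    @property
    def all_variants(self) -> frozenset[VariantKey]:
        out = set(self.core_variants)
        for extra in self.suballeles.values():
            out |= extra
        return frozenset(out)


@dataclass
class DefinitionTable:
    """A validated collection of star-allele definitions on one reference."""

    reference_name: str
    alleles: dict[str, StarAlleleDefinition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for required in ("*1", "*5"):
            if required not in self.alleles:
                raise DefinitionError(f"definition table must contain {required}")
        if self.alleles["*1"].core_variants:
            raise DefinitionError("*1 is the reference allele and must have an empty core set")
        for name, d in self.alleles.items():
            if name != d.name:
                raise DefinitionError(f"allele keyed {name} but named {d.name}")

    @property
    def all_known_variants(self) -> frozenset[VariantKey]:
        out: set[VariantKey] = set()
        for d in self.alleles.values():
            out |= d.all_variants
        return frozenset(out)

    def core_membership(self, variant: VariantKey) -> list[str]:
        """Alleles that carry ``variant`` in their *core* set."""
        return [n for n, d in self.alleles.items() if variant in d.core_variants]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DefinitionTable):
            return NotImplemented
        return self.reference_name == other.reference_name and self.alleles == other.alleles


def _variant_from_row(row: pd.Series) -> VariantKey | None:
    if pd.isna(row["position"]) or str(row["position"]).strip() == "":
        return None
    ref = "" if pd.isna(row["ref"]) else str(row["ref"]).strip()
    alt = "" if pd.isna(row["alt"]) else str(row["alt"]).strip()
    return VariantKey(int(row["position"]), ref, alt)


def parse_definition_table(path: str | Path) -> DefinitionTable:
    """Parse a tab-delimited star-allele definition table.

    Rows sharing an ``allele`` label aggregate into one definition; rows with
    a blank ``suballele`` define core variants, others extend the named
    suballele.  A leading ``#reference=<name>`` comment line names the
    coordinate reference.
    """
    path = Path(path)
    reference_name = "reference"
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#reference="):
        reference_name = first.removeprefix("#reference=").strip()
        skip = 1
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str, keep_default_na=False)
    if list(df.columns) != _COLUMNS:
        raise DefinitionError(f"{path}: expected columns {_COLUMNS}, got {list(df.columns)}")
    df = df.replace("", pd.NA)

    alleles: dict[str, StarAlleleDefinition] = {}
    for name, grp in df.groupby("allele", sort=False):
        functions = grp["function"].dropna().unique()
        if len(functions) != 1:
            raise DefinitionError(f"{name}: function class missing or inconsistent")
        function = functions[0]
        activities = grp["activity"].dropna().unique()
        if len(activities) > 1:
            raise DefinitionError(f"{name}: conflicting activity values")
        activity = float(activities[0]) if len(activities) else None
        if activity is not None and function not in DEFINED_ACTIVITY:
            raise DefinitionError(
                f"{name}: activity given for {function}-function allele"
            )
        structurals = grp["structural"].dropna().unique()
        structural = structurals[0] if len(structurals) else "none"

        core: set[VariantKey] = set()
        subs: dict[str, set[VariantKey]] = {}
        seen: dict[tuple[str | None, int], VariantKey] = {}
        for _, row in grp.iterrows():
            v = _variant_from_row(row)
            if v is None:
                continue
            sub = None if pd.isna(row["suballele"]) else str(row["suballele"]).strip()
            key = (sub, v.position)
            if key in seen and seen[key] != v:
                raise DefinitionError(
                    f"{name}: conflicting variants at position {v.position} "
                    f"({seen[key]} vs {v})"
                )
            seen[key] = v
            if sub is None:
                core.add(v)
            else:
                subs.setdefault(sub, set()).add(v)
        alleles[str(name)] = StarAlleleDefinition(
            name=str(name),
            core_variants=frozenset(core),
            suballeles={s: frozenset(vs) for s, vs in subs.items()},
            function=function,
            activity=activity,
            structural=structural,
        )
    return DefinitionTable(reference_name=reference_name, alleles=alleles)


def write_definition_table(table: DefinitionTable, path: str | Path) -> None:
    """Serialise a table so that ``parse_definition_table`` round-trips it."""
    rows = []
    for name in sorted(table.alleles, key=star_number):
        d = table.alleles[name]
        meta = {
            "allele": name,
            "function": d.function,
            "activity": "" if d.activity is None else f"{d.activity:g}",
            "structural": d.structural,
        }
        emitted = False
        for v in sorted(d.core_variants):
            rows.append({**meta, "suballele": "", "position": v.position, "ref": v.ref, "alt": v.alt})
            emitted = True
        for sub in sorted(d.suballeles, key=star_number):
            for v in sorted(d.suballeles[sub]):
                rows.append({**meta, "suballele": sub, "position": v.position, "ref": v.ref, "alt": v.alt})
                emitted = True
        if not emitted:
            rows.append({**meta, "suballele": "", "position": "", "ref": "", "alt": ""})
    df = pd.DataFrame(rows, columns=_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"#reference={table.reference_name}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_bundled_definitions(which: str = "current") -> DefinitionTable:
    """Load a definition table shipped with the package.

    ``current``: the 13 star alleles observed in the study cohort plus their
    suballeles. ``prior``: the pre-study state — the nine previously known
    alleles plus three unobserved alleles whose core sets contain variants
    later rediscovered on new backgrounds. Core-variant sets for previously
    known alleles are synthetic stand-ins (PharmVar content is not
    redistributed here); coordinates and novel-variant content follow the
    study reference.
    """
    fname = {"current": "star_alleles_current.tsv", "prior": "star_alleles_prior.tsv"}[which]
    with resources.as_file(resources.files("starcall.data").joinpath(fname)) as p:
        return parse_definition_table(p)
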