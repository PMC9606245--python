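"""Sequence-variant primitives on a single gene reference.

All coordinates are 1-based on one named reference sequence (position 1 =
first base of the reference), the convention used by RefSeqGene-style
pharmacogene references. Insertions are anchored at the position *after
which* the bases are inserted; no left-alignment is performed (one fixed
reference, repeats not assumed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

VariantKind = Literal["SNV", "insertion", "deletion"]

_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class VariantKey:
    """A single sequence change at a 1-based position on the gene reference.

    ``ref`` is empty for a pure insertion (bases in ``alt`` are inserted
    after ``position``); ``alt`` is empty for a pure deletion (bases in
    ``ref`` starting at ``position`` are removed).
    """

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for field, seq in (("ref", self.ref), ("alt", self.alt)):
            if not set(seq) <= _BASES:
                raise ValueError(f"{field} must be uppercase ACGT, got {seq!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not self.ref and not self.alt:
            raise ValueError("ref and alt cannot both be empty")
        if self.ref and self.alt and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError(
                "only SNVs (1->1), pure insertions (0->n) and pure deletions "
                f"(n->0) are supported, got {self.ref!r}>{self.alt!r}"
            )

    @property
    def kind(self) -> VariantKind:
        if self.ref and self.alt:
            return "SNV"
        return "insertion" if self.alt else "deletion"

    def __str__(self) -> str:
        if self.kind == "SNV":
            return f"{self.position}{self.ref}>{self.alt}"
        if self.kind == "insertion":
            return f"{self.position}ins{self.alt}"
        return f"{self.position}del{self.ref}"


_SNV_RE = re.compile(r"^(\d+)([ACGT])>([ACGT])$")
_INS_RE = re.compile(r"^(\d+)ins([ACGT]+)$")
_DEL_RE = re.compile(r"^(\d+)del([ACGT]+)$")


def parse_variant(text: str) -> VariantKey:
    """Parse the compact notation used in tables: ``6528G>A``, ``8406insAGCACC``,
    ``1234delCT``."""
    text = text.strip()
    if m := _SNV_RE.match(text):
        return VariantKey(int(m.group(1)), m.group(2), m.group(3))
    if m := _INS_RE.match(text):
        return VariantKey(int(m.group(1)), "", m.group(2))
    if m := _DEL_RE.match(text):
        return VariantKey(int(m.group(1)), m.group(2), "")
    raise ValueError(f"unparseable variant notation: {text!r}")


def parse_variant_set(text: str) -> frozenset[VariantKey]:
    """Parse a comma/semicolon separated list of variants; blank -> empty set."""
    text = text.strip()
    if not text or text in {"-", "."}:
        return frozenset()
    parts = re.split(r"[;,]\s*", text)
    return frozenset(parse_variant(p) for p in parts if p)


def format_variant_set(variants: frozenset[VariantKey] | set[VariantKey]) -> str:
    return ",".join(str(v) for v in sorted(variants))
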