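"""HLA allele nomenclature: parsing, ordering, and resolution.

HLA alleles are named ``LOCUS*f1:f2:f3:f4`` with one to four colon-separated
numeric fields and an optional trailing expression suffix (e.g. ``A*24:02:01:01``
or ``B*44:02:01:02S``).  More fields means higher resolution; a two-field name
identifies the protein, four fields identify a unique genomic sequence.  Typing
assays commonly report two-field names, whereas reference databases hold
four-field sequences, so a typed allele must be *resolved* to a concrete
database allele: the one with the lowest four-field name consistent with the
typed name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

#: Classical HLA loci recognized by this package.
RECOGNIZED_LOCI = frozenset(
    ["A", "B", "C", "DPA1", "DPB1", "DQA1", "DQB1", "DRB1", "DRB3", "DRB4", "DRB5"]
)

#: IMGT/HLA expression suffixes (null, questionable, low, secreted, aberrant, cytoplasm).
EXPRESSION_SUFFIXES = frozenset("NQLSAC")

_CLASS_I_LOCI = frozenset(["A", "B", "C"])

_NAME_RE = re.compile(
    r"^(?P<locus>[A-Z]+[0-9]*)\*(?P<fields>\d+(?::\d+){0,3})(?P<suffix>[NQLSAC]?)$"
)


class LocusClass(Enum):
    """Major histocompatibility complex class of an HLA locus."""

    CLASS_I = "I"
    CLASS_II = "II"


class AlleleNameError(ValueError):
    """Raised when an allele name cannot be parsed or violates nomenclature rules."""


class AlleleResolutionError(KeyError):
    """Raised when a typed allele matches no database allele."""


@dataclass(frozen=True, order=False)
class AlleleName:
    """A parsed HLA allele name.

    Parameters
    ----------
    locus
        Gene symbol without the ``HLA-`` prefix, e.g. ``"DQB1"``.
    fields
        One to four positive integers, highest-order first.
    suffix
        Optional single expression-suffix character, or ``""``.
    """

    locus: str
    fields: tuple[int, ...]
    suffix: str = ""

    def __post_init__(self) -> None:
        if self.locus not in RECOGNIZED_LOCI:
            raise AlleleNameError(f"unrecognized HLA locus {self.locus!r}")
        if not 1 <= len(self.fields) <= 4:
            raise AlleleNameError(
                f"allele name must have 1-4 fields, got {len(self.fields)}"
            )
        if any(f <= 0 for f in self.fields):
            raise AlleleNameError(f"allele fields must be positive: {self.fields}")
        if self.suffix and self.suffix not in EXPRESSION_SUFFIXES:
            raise AlleleNameError(f"invalid expression suffix {self.suffix!r}")

    @classmethod
    def parse(cls, text: str) -> "AlleleName":
        """Parse ``"DQB1*05:03:01:01"`` style names (optional ``HLA-`` prefix)."""
        s = text.strip()
        if s.startswith("HLA-"):
            s = s[4:]
        m = _NAME_RE.match(s)
        if m is None:
            raise AlleleNameError(f"cannot parse allele name {text!r}")
        fields = tuple(int(x) for x in m.group("fields").split(":"))
        return cls(m.group("locus"), fields, m.group("suffix"))

    def __str__(self) -> str:
        return f"{self.locus}*{':'.join(f'{f:02d}' for f in self.fields)}{self.suffix}"

    @property
    def locus_class(self) -> LocusClass:
        return LocusClass.CLASS_I if self.locus in _CLASS_I_LOCI else LocusClass.CLASS_II

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    def is_prefix_of(self, other: "AlleleName") -> bool:
        """True if ``other`` refines this name: same locus, same leading fields."""
        return (
            self.locus == other.locus
            and len(self.fields) <= len(other.fields)
            and other.fields[: len(self.fields)] == self.fields
        )

    def sort_key(self) -> tuple:
        """Field-wise numeric order; on full-field ties, no suffix sorts first."""
        return (self.locus, self.fields, self.suffix != "", self.suffix)


def lowest_consistent(typed: AlleleName, candidates: Iterable[AlleleName]) -> AlleleName:
    """Return the lowest-named candidate that ``typed`` is a field-prefix of.

    Ordering compares fields numerically position by position; among names
    identical in all fields, an allele without an expression suffix is
    preferred, then suffixes compare by character.
    """
    consistent = [c for c in candidates if typed.is_prefix_of(c)]
    if not consistent:
        raise AlleleResolutionError(
            f"no database allele consistent with typed allele {typed}"
        )
    return min(consistent, key=AlleleName.sort_key)
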