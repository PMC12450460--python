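"""Library-validation rates and localization-overlap statistics.

Desk-scale arithmetic for characterizing a tagged-strain library:
pass rates of validation assays (survival, integration PCR, expected
molecular mass), the compound lower bound on bona fide strains, and
cross-library agreement between two protein -> compartment assignment
tables (e.g. a GFP-tagged reference screen versus an epitope-tag
screen).

Percentages are rounded half-up to one decimal place, the convention
used in reporting such rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


def _round_half_up_1dp(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ValidationCounts:
    total: int
    passed: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValueError("total must be >= 1")
        if not (0 <= self.passed <= self.total):
            raise ValueError("passed must lie in [0, total]")


def pass_rate(c: ValidationCounts) -> float:
    """100 * passed / total, rounded half-up to one decimal."""
    return _round_half_up_1dp(100.0 * c.passed / c.total)


def estimate_validated_strains(
    total: int, survival_rate: float, inframe_rate: float
) -> int:
    """Lower bound on validated strains: floor(total * survival * in-frame)."""
    for name, rate in (("survival_rate", survival_rate), ("inframe_rate", inframe_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {rate}")
    return math.floor(total * survival_rate * inframe_rate)


@dataclass
class LocalizationTable:
    """Mapping protein id -> set of compartment labels."""

    assignments: dict[str, frozenset[str]]
    vocabulary: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.assignments = {
            pid: frozenset(comps) for pid, comps in self.assignments.items()
        }
        if self.vocabulary is None:
            vocab: set[str] = set()
            for comps in self.assignments.values():
                vocab |= comps
            self.vocabulary = frozenset(vocab)
        else:
            self.vocabulary = frozenset(self.vocabulary)
            for pid, comps in self.assignments.items():
                unknown = comps - self.vocabulary
                if unknown:
                    raise ValueError(
                        f"protein {pid}: compartments {sorted(unknown)} outside vocabulary"
                    )

    def proteins_in(self, compartment: str) -> set[str]:
        return {p for p, comps in self.assignments.items() if compartment in comps}

    def pairs(self) -> set[tuple[str, str]]:
        return {
            (p, c) for p, comps in self.assignments.items() for c in comps
        }

    @classmethod
    def from_pairs(cls, pairs) -> "LocalizationTable":
        assignments: dict[str, set[str]] = {}
        for protein, compartment in pairs:
            assignments.setdefault(protein, set()).add(compartment)
        return cls({p: frozenset(c) for p, c in assignments.items()})


def compartment_agreement(
    reference: LocalizationTable,
    query: LocalizationTable,
    compartment: str,
    include_missing: bool = False,
) -> float:
    """Percentage of reference proteins of a compartment confirmed in the query.

    Among proteins assigned to ``compartment`` in the reference, the
    percentage also assigned to it in the query. By default proteins
    entirely absent from the query (not screened / no signal) are
    excluded from the denominator; with ``include_missing=True`` they
    count as disagreements.
    """
    if compartment not in (reference.vocabulary | query.vocabulary):
        raise ValueError(f"unknown compartment {compartment!r}")
    ref_set = reference.proteins_in(compartment)
    if include_missing:
        denominator = ref_set
    else:
        denominator = ref_set & set(query.assignments)
    if not denominator:
        raise ValueError(
            f"no proteins in the denominator for compartment {compartment!r}"
        )
    agreeing = {p for p in denominator if compartment in query.assignments.get(p, ())}
    return _round_half_up_1dp(100.0 * len(agreeing) / len(denominator))


def novel_assignment_fraction(
    query: LocalizationTable, reference: LocalizationTable
) -> float:
    """Percentage of query (protein, compartment) pairs absent from the reference."""
    query_pairs = query.pairs()
    if not query_pairs:
        raise ValueError("query table is empty")
    novel = query_pairs - reference.pairs()
    return _round_half_up_1dp(100.0 * len(novel) / len(query_pairs))
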