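"""Duplication statistics and analytic collision probabilities.

Pattern duplication asks: among a roster, how many members share the
same value on a chosen key (initials alone, initials+age, ...)?  A
member counts as *duplicated* if their key occurs at least twice.
Complete duplication is the end-stage failure: two assignments that
produce the identical 16-character string.

The analytic side treats the key as a product of independent
categorical fields (a structured birthday problem): two independent
draws match on a field set F with probability prod_{f in F} sum_i
p_{f,i}^2, and among n roster members the expected number of matching
pairs is C(n,2) times that.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Iterable, Mapping, Optional, Sequence

from .codec import FIELD_NAMES, IDCode, decode_id, validate_id

__all__ = [
    "DuplicationReport",
    "IDDuplicationStats",
    "CollisionModel",
    "percent_half_up",
    "pattern_duplication_stats",
    "id_duplication_stats",
    "explain_nonduplication",
    "pair_match_probability",
    "expected_duplicate_pairs",
]


def percent_half_up(numerator: int, denominator: int) -> float:
    """100*numerator/denominator rounded half-up to one decimal.

    Half-up (not banker's) rounding reproduces printed one-decimal
    percentages from their fractions, e.g. 43/89 -> 48.3, 2/890 -> 0.2,
    888/890 -> 99.8.  Exact decimal arithmetic avoids binary-float
    artefacts near ties.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DuplicationReport:
    """Pattern- and item-level duplication counts for one key choice.

    Accounting identities are asserted at construction:
    ``n_singletons + n_items_in_duplicated == n_items`` and
    ``n_singletons + n_duplicated_patterns == n_patterns``.
    """

    n_items: int
    n_patterns: int
    n_duplicated_patterns: int
    n_items_in_duplicated: int
    percent_items_in_duplicated: float

    def __post_init__(self) -> None:
        n_singletons = self.n_items - self.n_items_in_duplicated
        if n_singletons + self.n_duplicated_patterns != self.n_patterns:
            raise ValueError(
                "inconsistent report: "
                f"{n_singletons} singletons + {self.n_duplicated_patterns} duplicated "
                f"patterns != {self.n_patterns} patterns"
            )
        if not 0.0 <= self.percent_items_in_duplicated <= 100.0:
            raise ValueError("percentage out of [0, 100]")

    @property
    def n_singletons(self) -> int:
        return self.n_items - self.n_items_in_duplicated


def pattern_duplication_stats(keys: Sequence[Hashable]) -> DuplicationReport:
    """Duplication report for a multiset of opaque keys.

    An item is duplicated when its key occurs at least twice; the
    percentage is item-level (duplicated items / all items).
    """
    keys = list(keys)
    if not keys:
        raise ValueError("keys must be non-empty")
    counts = Counter(keys)
    n_items = len(keys)
    n_dup_patterns = sum(1 for c in counts.values() if c >= 2)
    n_items_in_dup = sum(c for c in counts.values() if c >= 2)
    return DuplicationReport(
        n_items=n_items,
        n_patterns=len(counts),
        n_duplicated_patterns=n_dup_patterns,
        n_items_in_duplicated=n_items_in_dup,
        percent_items_in_duplicated=percent_half_up(n_items_in_dup, n_items),
    )


@dataclass(frozen=True)
class IDDuplicationStats:
    """Complete-duplication summary for a list of 16-character IDs."""

    report: DuplicationReport
    n_complete_duplicates: int  # IDs whose exact string occurs >= 2 times
    n_unique: int
    percent_duplicates: float
    percent_unique: float


def id_duplication_stats(ids: Sequence[str | IDCode]) -> IDDuplicationStats:
    """Complete-duplication statistics over canonical (or display) IDs.

    Every input must pass the grammar; an invalid entry raises with its
    1-based line number.
    """
    canon: list[str] = []
    for lineno, item in enumerate(ids, start=1):
        s = item.canonical if isinstance(item, IDCode) else item
        violations = validate_id(s)
        if violations:
            raise ValueError(f"invalid ID on line {lineno}: {violations[0]}")
        canon.append(s if len(s) == 16 else s[:7] + s[8:])
    report = pattern_duplication_stats(canon)
    n = report.n_items
    n_dup = report.n_items_in_duplicated
    return IDDuplicationStats(
        report=report,
        n_complete_duplicates=n_dup,
        n_unique=n - n_dup,
        percent_duplicates=percent_half_up(n_dup, n),
        percent_unique=percent_half_up(n - n_dup, n),
    )


def explain_nonduplication(a: str | IDCode, b: str | IDCode) -> list[str]:
    """Names of the fields where two IDs differ, in positional order.

    An empty list means complete duplication.  This is the diagnostic
    behind near-collision audits: for two responders sharing a responder
    block, the returned fields (typically the triage minute or the
    casualty's initial) are what kept their codes distinct.
    """
    da = (a if isinstance(a, IDCode) else decode_id(a)).fields
    db = (b if isinstance(b, IDCode) else decode_id(b)).fields
    return [name for name in FIELD_NAMES if getattr(da, name) != getattr(db, name)]


@dataclass(frozen=True)
class CollisionModel:
    """Independent categorical distributions, one per identifying field.

    ``fields`` maps a field name to a value->probability mapping.  Each
    distribution must sum to 1 within 1e-9; mutual independence across
    fields is the model assumption (use the Monte-Carlo simulator for
    dependent structures).
    """

    fields: Mapping[str, Mapping[Hashable, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, dist in self.fields.items():
            if not dist:
                raise ValueError(f"field {name!r} has an empty distribution")
            total = math.fsum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"field {name!r} probabilities sum to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"field {name!r} has a negative probability")


def pair_match_probability(
    model: CollisionModel, fields: Optional[Iterable[str]] = None
) -> float:
    """P(two independent draws agree on every requested field).

    With independent fields this is the product over fields of the
    Simpson concentration sum_i p_i^2; it equals 1 when every requested
    field is deterministic and can only shrink as fields are added.
    """
    names = list(model.fields) if fields is None else list(fields)
    prob = 1.0
    for name in names:
        if name not in model.fields:
            raise KeyError(f"unknown field {name!r}")
        prob *= math.fsum(p * p for p in model.fields[name].values())
    return prob


def expected_duplicate_pairs(
    model: CollisionModel, n: int, fields: Optional[Iterable[str]] = None
) -> float:
    """Expected number of matching pairs among ``n`` independent draws.

    The structured birthday problem: C(n,2) * pair_match_probability.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    return math.comb(n, 2) * pair_match_probability(model, fields)
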