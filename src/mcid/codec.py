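"""Fixed-width 16-character casualty identification codec.

A first responder at a mass-casualty scene writes a 16-character
alphanumeric code on each triage tag.  The code concatenates a
7-character *responder block* and a 9-character *casualty block*:

====  ========  =====================================================
pos   field     content
====  ========  =====================================================
1     job       responder job category: D(octor), N(urse),
                P(aramedic), V(olunteer)
2-3   initials  responder's family- and given-name initials, A-Z
4-5   age       responder age in years, modulo 100, zero-padded
6-7   serial    serial triage number modulo 100 (case 1 -> "01",
                case 100 -> "00", case 101 -> "01" again)
8-9   day       day of month of triage, 01-31
10-11 hour      hour of triage, 00-23 (24-h wall clock)
12-13 minute    minute of triage, 00-59
14    decade    casualty age-group digit: floor(age/10) capped at 9
                (age <10 -> 0, 65 -> 6, >=90 -> 9), or the estimated
                decade, or 'u' if unknown
15    gender    M, F, or 'u'
16    initial   casualty name initial A-Z, or 'u'
====  ========  =====================================================

Casualty information that cannot be obtained at first contact is
written as a lowercase ``u``; because all real letters are uppercase,
``u`` is unambiguous even for people whose initial is U.

Canonical storage is the bare 16-character string.  The human-facing
*display* form inserts a hyphen between the two blocks
(``DKS3501-0101010MK``); both forms are accepted on input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "JOB_CATEGORIES",
    "UNKNOWN",
    "FIELD_LAYOUT",
    "FIELD_NAMES",
    "ResponderProfile",
    "CasualtyRecord",
    "IDCode",
    "DecodedID",
    "Violation",
    "FieldValidationError",
    "IDFormatError",
    "encode_responder_block",
    "encode_casualty_block",
    "encode_id",
    "decode_id",
    "validate_id",
    "age_decade_digit",
]

JOB_CATEGORIES = ("D", "N", "P", "V")
UNKNOWN = "u"

_TRIAGE_CLASSES = ("O", "I", "II", "III")  # START: Black/Red/Yellow/Green
_UPPER = re.compile(r"[A-Z]\Z")


class FieldValidationError(ValueError):
    """A domain object failed validation; ``field`` names the offender."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


class IDFormatError(ValueError):
    """A string does not parse as a 16-character ID.

    Carries the full list of positional violations in ``violations``.
    """

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


@dataclass
class ResponderProfile:
    """One responder's identifying attributes plus a running serial counter.

    ``next_triage_number`` is 1-based: it is the serial number the
    responder's *next* encoded casualty will receive, and
    :func:`encode_id` advances it by one per casualty.
    """

    job_category: str
    initial_1: str  # family-name initial
    initial_2: str  # given-name initial
    age_years: int
    next_triage_number: int = 1

    def validate(self) -> None:
        if self.job_category not in JOB_CATEGORIES:
            raise FieldValidationError(
                "job_category",
                f"{self.job_category!r} is not one of {'/'.join(JOB_CATEGORIES)}",
            )
        for name in ("initial_1", "initial_2"):
            v = getattr(self, name)
            if not isinstance(v, str) or not _UPPER.match(v):
                raise FieldValidationError(name, f"{v!r} is not an uppercase letter A-Z")
        if not isinstance(self.age_years, int) or self.age_years < 0:
            raise FieldValidationError("age_years", f"{self.age_years!r} is not a non-negative integer")
        if not isinstance(self.next_triage_number, int) or self.next_triage_number < 1:
            raise FieldValidationError(
                "next_triage_number", f"{self.next_triage_number!r} is not a positive integer"
            )


@dataclass
class CasualtyRecord:
    """A casualty's attributes as known or estimated at first contact.

    Unknowns are explicit: ``age_years`` and ``age_decade_estimate`` may
    both be absent (age unknown; at most one may be set), ``gender`` may
    be ``"u"``, and ``name_initial`` may be ``None``.  ``hour``/``minute``
    may be ``None`` for a casualty that has not yet been triaged (for
    example a row read from a scenario file before the simulated clock
    stamps it); encoding then fails with a validation error.

    ``triage_class`` is a carried label produced elsewhere (START
    categories O/I/II/III = Black/Red/Yellow/Green); it is not encoded.
    ``triage_number`` is the printed serial on the casualty's handout,
    used by the desk-study design where every responder copies it.
    """

    day_of_month: int
    hour: Optional[int] = None
    minute: Optional[int] = None
    age_years: Optional[int] = None
    age_decade_estimate: Optional[int] = None
    gender: str = UNKNOWN
    name_initial: Optional[str] = None
    triage_class: Optional[str] = None
    triage_number: Optional[int] = None

    def validate(self, require_time: bool = True) -> None:
        if not isinstance(self.day_of_month, int) or not 1 <= self.day_of_month <= 31:
            raise FieldValidationError("day_of_month", f"{self.day_of_month!r} not in 1..31")
        if require_time or self.hour is not None:
            if not isinstance(self.hour, int) or not 0 <= self.hour <= 23:
                raise FieldValidationError("hour", f"{self.hour!r} not in 0..23")
        if require_time or self.minute is not None:
            if not isinstance(self.minute, int) or not 0 <= self.minute <= 59:
                raise FieldValidationError("minute", f"{self.minute!r} not in 0..59")
        if self.age_years is not None and self.age_decade_estimate is not None:
            raise FieldValidationError(
                "age_years", "age_years and age_decade_estimate are mutually exclusive"
            )
        if self.age_years is not None and (not isinstance(self.age_years, int) or self.age_years < 0):
            raise FieldValidationError("age_years", f"{self.age_years!r} is not a non-negative integer")
        if self.age_decade_estimate is not None and not (
            isinstance(self.age_decade_estimate, int) and 0 <= self.age_decade_estimate <= 9
        ):
            raise FieldValidationError("age_decade_estimate", f"{self.age_decade_estimate!r} not in 0..9")
        if self.gender not in ("M", "F", UNKNOWN):
            raise FieldValidationError("gender", f"{self.gender!r} is not M, F or {UNKNOWN!r}")
        if self.name_initial is not None and not _UPPER.match(str(self.name_initial)):
            raise FieldValidationError("name_initial", f"{self.name_initial!r} is not an uppercase letter")
        if self.triage_class is not None and self.triage_class not in _TRIAGE_CLASSES:
            raise FieldValidationError("triage_class", f"{self.triage_class!r} not in {_TRIAGE_CLASSES}")

    def stamped(self, hour: int, minute: int) -> "CasualtyRecord":
        """Return a copy carrying the given triage wall-clock time."""
        return replace(self, hour=hour, minute=minute)


# (name, start, stop) in 0-based canonical-string coordinates.
FIELD_LAYOUT: tuple[tuple[str, int, int], ...] = (
    ("job", 0, 1),
    ("initial_1", 1, 2),
    ("initial_2", 2, 3),
    ("responder_age", 3, 5),
    ("serial", 5, 7),
    ("day", 7, 9),
    ("hour", 9, 11),
    ("minute", 11, 13),
    ("age_decade", 13, 14),
    ("gender", 14, 15),
    ("casualty_initial", 15, 16),
)
FIELD_NAMES: tuple[str, ...] = tuple(name for name, _, _ in FIELD_LAYOUT)


@dataclass(frozen=True)
class Violation:
    """One failed positional rule: 1-based position span and expectation."""

    field: str
    position: tuple[int, int]  # 1-based inclusive span in the canonical string
    expected: str
    found: str

    def __str__(self) -> str:
        lo, hi = self.position
        span = str(lo) if lo == hi else f"{lo}-{hi}"
        return f"position {span} ({self.field}): expected {self.expected}, found {self.found!r}"


@dataclass(frozen=True)
class DecodedID:
    """All named fields of a parsed ID; ``None`` marks decoded unknowns."""

    job: str
    initial_1: str
    initial_2: str
    responder_age: int  # 0-99, the encoded (mod-100) value
    serial: int  # 0-99, the encoded (mod-100) value
    day: int
    hour: int
    minute: int
    age_decade: Optional[int]
    gender: str  # "M", "F" or "u"
    casualty_initial: Optional[str]


@dataclass(frozen=True)
class IDCode:
    """A validated 16-character code with named blocks and renderings."""

    canonical: str
    fields: DecodedID = field(compare=False)

    @property
    def responder_block(self) -> str:
        return self.canonical[:7]

    @property
    def casualty_block(self) -> str:
        return self.canonical[7:]

    @property
    def display(self) -> str:
        return self.responder_block + "-" + self.casualty_block

    def __str__(self) -> str:
        return self.canonical


def age_decade_digit(c: CasualtyRecord) -> str:
    """Age-group character: exact age wins, then the estimate, else 'u'.

    Exact ages map to ``min(age // 10, 9)``: <10 years -> ``0``,
    65 -> ``6``, 90 or above -> ``9``.
    """
    if c.age_years is not None:
        return str(min(c.age_years // 10, 9))
    if c.age_decade_estimate is not None:
        return str(c.age_decade_estimate)
    return UNKNOWN


def encode_responder_block(r: ResponderProfile) -> str:
    """Encode the 7-character responder block.

    Age and serial are written modulo 100 with zero padding, so the
    100th case is ``"00"`` and the 101st is ``"01"`` again.
    """
    r.validate()
    return (
        f"{r.job_category}{r.initial_1}{r.initial_2}"
        f"{r.age_years % 100:02d}{r.next_triage_number % 100:02d}"
    )


def encode_casualty_block(c: CasualtyRecord) -> str:
    """Encode the 9-character casualty block (DDHHMM + decade + gender + initial)."""
    c.validate(require_time=True)
    return (
        f"{c.day_of_month:02d}{c.hour:02d}{c.minute:02d}"
        f"{age_decade_digit(c)}{c.gender}{c.name_initial or UNKNOWN}"
    )


def encode_id(r: ResponderProfile, c: CasualtyRecord) -> IDCode:
    """Encode one casualty for one responder and advance the serial counter."""
    canonical = encode_responder_block(r) + encode_casualty_block(c)
    r.next_triage_number += 1
    return IDCode(canonical=canonical, fields=_parse(canonical))


def _check_field(name: str, text: str) -> Optional[str]:
    """Return the expectation string if ``text`` violates the field's rule."""
    if name == "job":
        return None if text in JOB_CATEGORIES else "one of D/N/P/V"
    if name in ("initial_1", "initial_2"):
        return None if _UPPER.match(text) else "letter A-Z"
    if name in ("responder_age", "serial"):
        return None if text.isascii() and text.isdigit() else "two digits 00-99"
    if name == "day":
        ok = text.isascii() and text.isdigit() and 1 <= int(text) <= 31
        return None if ok else "day 01-31"
    if name == "hour":
        ok = text.isascii() and text.isdigit() and int(text) <= 23
        return None if ok else "hour 00-23"
    if name == "minute":
        ok = text.isascii() and text.isdigit() and int(text) <= 59
        return None if ok else "minute 00-59"
    if name == "age_decade":
        ok = text == UNKNOWN or (text.isascii() and text.isdigit())
        return None if ok else "digit 0-9 or 'u'"
    if name == "gender":
        return None if text in ("M", "F", UNKNOWN) else "M, F or 'u'"
    if name == "casualty_initial":
        ok = text == UNKNOWN or bool(_UPPER.match(text))
        return None if ok else "letter A-Z or 'u'"
    raise KeyError(name)


def _normalise(s: str) -> tuple[Optional[str], Optional[Violation]]:
    """Strip the display hyphen; report length/hyphen problems."""
    if not isinstance(s, str):
        return None, Violation("id", (1, 16), "a string", type(s).__name__)
    if len(s) == 17:
        if s[7] != "-":
            return None, Violation("separator", (8, 8), "hyphen after the responder block", s[7])
        s = s[:7] + s[8:]
    if len(s) != 16:
        return None, Violation(
            "length", (1, 16), "16 characters (or 17 with hyphen)", f"{len(s)} characters"
        )
    return s, None


def validate_id(s: str) -> list[Violation]:
    """Check a string against the positional grammar; empty list means valid.

    Total function: never raises.  Accepts canonical (16) and display
    (17 with hyphen) forms.
    """
    canon, problem = _normalise(s)
    if problem is not None:
        return [problem]
    assert canon is not None
    violations = []
    for name, start, stop in FIELD_LAYOUT:
        expected = _check_field(name, canon[start:stop])
        if expected is not None:
            violations.append(Violation(name, (start + 1, stop), expected, canon[start:stop]))
    return violations


def _parse(canon: str) -> DecodedID:
    f = {name: canon[start:stop] for name, start, stop in FIELD_LAYOUT}
    return DecodedID(
        job=f["job"],
        initial_1=f["initial_1"],
        initial_2=f["initial_2"],
        responder_age=int(f["responder_age"]),
        serial=int(f["serial"]),
        day=int(f["day"]),
        hour=int(f["hour"]),
        minute=int(f["minute"]),
        age_decade=None if f["age_decade"] == UNKNOWN else int(f["age_decade"]),
        gender=f["gender"],
        casualty_initial=None if f["casualty_initial"] == UNKNOWN else f["casualty_initial"],
    )


def decode_id(s: str) -> IDCode:
    """Parse a canonical or display string into an :class:`IDCode`.

    Raises :class:`IDFormatError` carrying every positional violation if
    the string fails the grammar.  Unknown markers decode to explicit
    unknown states (``None`` for the decade and initial, ``"u"`` gender).
    """
    violations = validate_id(s)
    if violations:
        raise IDFormatError(violations)
    canon, _ = _normalise(s)
    assert canon is not None
    return IDCode(canonical=canon, fields=_parse(canon))
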