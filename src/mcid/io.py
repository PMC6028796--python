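"""Readers and writers for rosters, casualty lists, ID lists and reports.

All files are plain text, UTF-8.  CSVs are comma-separated with a
required header; empty cells mean "unknown".  Ages known only to a
decade are written with the ``Ns`` notation (``70s``, ``30s``).  ID
lists hold one canonical or display code per line; ``#`` starts a
comment.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Sequence

import pandas as pd

from .codec import CasualtyRecord, IDCode, ResponderProfile, validate_id

__all__ = [
    "read_casualties",
    "read_roster",
    "read_ids",
    "write_ids",
    "write_report",
]

CASUALTY_COLUMNS = [
    "casualty_id", "day", "triage_number", "age", "age_decade",
    "gender", "name_initial", "triage_class",
]
ROSTER_COLUMNS = ["responder_id", "job", "initial_family", "initial_given", "age"]

_DECADE_RE = re.compile(r"(\d)0s\Z")


def _cell(row, col) -> str | None:
    v = row[col]
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v).strip()
    return s or None


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def read_casualties(path) -> list[CasualtyRecord]:
    """Read a casualty CSV into records with explicit unknown states.

    The ``age`` column takes an exact age in years or a decade string
    like ``70s`` (parsed as an estimated decade); ``age_decade`` takes a
    bare decade digit.  Empty ``gender``/``name_initial`` cells mean
    unknown.  Triage time is not part of the file — the records come
    back unstamped.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no casualty rows")
    _require_columns(df, CASUALTY_COLUMNS, path)
    records = []
    for idx, row in df.iterrows():
        loc = f"{path}: row {idx + 2}"  # header is line 1
        try:
            age_years = None
            age_decade = None
            age_cell = _cell(row, "age")
            if age_cell is not None:
                m = _DECADE_RE.match(age_cell)
                if m:
                    age_decade = int(m.group(1))
                elif age_cell.isdigit():
                    age_years = int(age_cell)
                else:
                    raise ValueError(f"column 'age': {age_cell!r} is neither years nor 'Ns'")
            decade_cell = _cell(row, "age_decade")
            if decade_cell is not None:
                if age_years is not None or age_decade is not None:
                    raise ValueError("column 'age_decade': both age and age_decade given")
                age_decade = int(decade_cell)
            rec = CasualtyRecord(
                day_of_month=int(_cell(row, "day") or 0),
                age_years=age_years,
                age_decade_estimate=age_decade,
                gender=_cell(row, "gender") or "u",
                name_initial=_cell(row, "name_initial"),
                triage_class=_cell(row, "triage_class"),
                triage_number=int(_cell(row, "triage_number")) if _cell(row, "triage_number") else None,
            )
            rec.validate(require_time=False)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{loc}: {exc}") from exc
        records.append(rec)
    return records


def read_roster(path) -> list[ResponderProfile]:
    """Read a responder roster CSV.

    Serial counters start at 1 unless a ``start_serial`` column is
    present.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no roster rows")
    _require_columns(df, ROSTER_COLUMNS, path)
    roster = []
    for idx, row in df.iterrows():
        loc = f"{path}: row {idx + 2}"
        try:
            profile = ResponderProfile(
                job_category=_cell(row, "job") or "",
                initial_1=_cell(row, "initial_family") or "",
                initial_2=_cell(row, "initial_given") or "",
                age_years=int(_cell(row, "age") or -1),
                next_triage_number=int(_cell(row, "start_serial") or 1)
                if "start_serial" in df.columns
                else 1,
            )
            profile.validate()
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{loc}: {exc}") from exc
        roster.append(profile)
    return roster


def read_ids(path) -> list[str]:
    """Read an ID list file into canonical 16-character strings."""
    out = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        violations = validate_id(text)
        if violations:
            raise ValueError(f"{path}: line {lineno}: {violations[0]}")
        out.append(text if len(text) == 16 else text[:7] + text[8:])
    return out


def write_ids(path, ids: Sequence[IDCode | str], display: bool = False) -> None:
    """Write one code per line, canonical by default, display on request."""
    lines = []
    for item in ids:
        if isinstance(item, IDCode):
            lines.append(item.display if display else item.canonical)
        else:
            canon = item if len(item) == 16 else item[:7] + item[8:]
            lines.append(canon[:7] + "-" + canon[7:] if display else canon)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_report(path, report) -> None:
    """Serialise a report dataclass (or dict of them) to pretty JSON."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n", encoding="utf-8")
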