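"""Core record types shared across the pipeline.

Spontaneous reporting systems carry dates in a numeric ``YYYYMMDD`` form
where the day, or day and month, may be absent (``YYYYMM`` / ``YYYY``).
:class:`PartialDate` models that directly: a partial date is usable for
year-level filtering but is flagged incomplete for day-resolution
arithmetic such as time-to-onset.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence


class InvalidDate:
    """Sentinel for a date field that was present but unparseable.

    Distinct from ``None`` (absent) so downstream exclusion logs can
    distinguish ``incomplete_date`` from ``unparseable``.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "INVALID_DATE"


INVALID_DATE = InvalidDate()


@dataclass(frozen=True)
class PartialDate:
    """A calendar date whose month and day may be unknown."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day without month")

    @property
    def is_complete(self) -> bool:
        return self.month is not None and self.day is not None

    def to_date(self) -> _dt.date:
        if not self.is_complete:
            raise ValueError(f"partial date {self} has no day resolution")
        return _dt.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple:
        """Orderable key; unknown components sort before any known one."""
        return (self.year, self.month or 0, self.day or 0)

    def to_faers(self) -> str:
        """Render in FAERS numeric form (YYYYMMDD / YYYYMM / YYYY)."""
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    @classmethod
    def from_date(cls, d: _dt.date) -> "PartialDate":
        return cls(d.year, d.month, d.day)


def parse_date(value):
    """Parse a FAERS-style numeric date field.

    Returns a :class:`PartialDate`, ``None`` for an empty/absent field,
    or :data:`INVALID_DATE` for a value that is present but not a valid
    YYYY / YYYYMM / YYYYMMDD date.
    """
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", "nan", "None", "NA"):
        return None
    if s.endswith(".0"):  # pandas float round-trip
        s = s[:-2]
    if not s.isdigit():
        return INVALID_DATE
    try:
        if len(s) == 4:
            return PartialDate(int(s))
        if len(s) == 6:
            pd_ = PartialDate(int(s[:4]), int(s[4:6]))
            if not 1 <= pd_.month <= 12:
                return INVALID_DATE
            return pd_
        if len(s) == 8:
            d = _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
            return PartialDate.from_date(d)
    except ValueError:
        return INVALID_DATE
    return INVALID_DATE


@dataclass
class DrugEntry:
    """One drug row of a report: verbatim name, role code, therapy start."""

    name: str
    role: str = "PS"  # PS | SS | C | I
    start_date: object = None  # PartialDate | None | INVALID_DATE


@dataclass
class RawCase:
    """One version of one spontaneous report, as loaded (pre-dedup)."""

    primary_id: str
    case_id: str
    receipt_date: object = None  # PartialDate | None
    event_date: object = None  # PartialDate | None | INVALID_DATE
    sex: Optional[str] = None  # verbatim code, e.g. F/M
    age: Optional[float] = None
    age_unit: Optional[str] = None  # YR/MON/WK/DY/HR/DEC
    weight: Optional[float] = None
    weight_unit: Optional[str] = None  # KG/LBS
    country: Optional[str] = None
    reporter_qual: Optional[str] = None
    drugs: list = field(default_factory=list)  # list[DrugEntry]
    reactions: list = field(default_factory=list)  # verbatim PT strings
    outcomes: list = field(default_factory=list)  # outcome codes
    indications: list = field(default_factory=list)


#: Outcome codes recognised in the FAERS dialect.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "RI", "OT")


@dataclass
class CleanReport:
    """One deduplicated, harmonised spontaneous report.

    Produced by :func:`pvkit.srs_io.filter_primary_suspect`; the unit of
    counting for every downstream stage.
    """

    report_id: str
    sex: str = "unknown"  # female | male | unknown
    age_years: Optional[float] = None
    weight_kg: Optional[float] = None
    outcome_codes: tuple = ()
    drug_entries: list = field(default_factory=list)  # list[DrugEntry]
    reaction_pts: tuple = ()  # deduplicated, uppercase
    event_date: object = None
    country: Optional[str] = None
    indications: tuple = ()
    pt_soc: Optional[dict] = None  # PT -> SOC, set by map_pt_to_soc

    def socs(self) -> tuple:
        """Distinct SOCs of this report (requires map_pt_to_soc)."""
        if self.pt_soc is None:
            raise ValueError("report not annotated; run map_pt_to_soc first")
        return tuple(sorted(set(self.pt_soc.values())))


def normalize_sex(code) -> str:
    if code is None:
        return "unknown"
    c = str(code).strip().upper()
    if c in ("F", "FEMALE", "2"):
        return "female"
    if c in ("M", "MALE", "1"):
        return "male"
    return "unknown"


#: Multiplier from FAERS age-unit code to years. DEC = decades.
_AGE_UNIT_YEARS = {
    "YR": 1.0,
    "YEAR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
}


def age_to_years(value, unit) -> Optional[float]:
    """Convert a FAERS (age, unit-code) pair to years; unparseable → None."""
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if v < 0:
        return None
    if unit is None or str(unit).strip() == "":
        u = "YR"
    else:
        u = str(unit).strip().upper()
    factor = _AGE_UNIT_YEARS.get(u)
    if factor is None:  # HR and unknown codes: not meaningful as years
        return None
    return v * factor


def weight_to_kg(value, unit) -> Optional[float]:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if v < 0:
        return None
    u = "KG" if unit is None or str(unit).strip() == "" else str(unit).strip().upper()
    if u == "KG":
        return v
    if u in ("LBS", "LB"):
        return v * 0.45359237
    return None


def normalize_pts(pts: Sequence[str]) -> tuple:
    """Uppercase, strip, and deduplicate preferred terms, keeping order."""
    seen = {}
    for p in pts:
        if p is None:
            continue
        s = str(p).strip().upper()
        if s and s not in seen:
            seen[s] = None
    return tuple(seen)
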