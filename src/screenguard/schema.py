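"""Screening-record data model, field roles, and value normalization.

Every value is normalized to a canonical form *before* any duplicate
matching or quota evaluation. Matching is always exact on canonical forms:
two submissions "share a phone number" iff the canonical phone strings are
equal and neither is missing. Empty or whitespace-only raw values map to
the MISSING sentinel, and MISSING never equals MISSING — two blank
optional fields are not evidence that two people are the same person.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Literal, Mapping, Optional
from zoneinfo import ZoneInfo

import pandas as pd

__all__ = [
    "MISSING",
    "FieldRole",
    "NormalizerKind",
    "FieldSpec",
    "Schema",
    "ScreeningRecord",
    "ConfigError",
    "normalize_value",
    "load_records",
]


class ConfigError(ValueError):
    """A configuration (schema/criteria/quota) inconsistency, as opposed to bad data."""


class _Missing:
    """Sentinel for an absent canonical value. Never compares equal to itself
    for matching purposes (see fields_agree); identity checks use ``is MISSING``."""

    _instance: Optional["_Missing"] = None

    def __new__(cls) -> "_Missing":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

FieldRole = Literal["identifier", "eligibility", "demographic", "other"]
NormalizerKind = Literal["exact", "text", "email", "phone", "date"]

_ROLES = ("identifier", "eligibility", "demographic", "other")
_NORMALIZERS = ("exact", "text", "email", "phone", "date")

_WS_RE = re.compile(r"\s+")
_NON_DIGIT_RE = re.compile(r"\D")


@dataclass(frozen=True)
class FieldSpec:
    """One screening-survey field selected for matching or quota use.

    Parameters
    ----------
    name : str
        Unique short key; must match a column of the screening CSV.
    role : {"identifier", "eligibility", "demographic", "other"}
        What the field represents. Identifier-role fields are the ones a
        fraudster might mutate between resubmissions, and are the fields
        reported by the intent profile.
    normalizer : {"exact", "text", "email", "phone", "date"}
        How raw strings are canonicalised before comparison.
    """

    name: str
    role: FieldRole = "other"
    normalizer: NormalizerKind = "exact"

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ConfigError("field name must be non-empty")
        if self.role not in _ROLES:
            raise ConfigError(f"unknown field role {self.role!r} for field {self.name!r}")
        if self.normalizer not in _NORMALIZERS:
            raise ConfigError(
                f"unknown normalizer {self.normalizer!r} for field {self.name!r}"
            )


@dataclass(frozen=True)
class Schema:
    """The ordered collection of declared fields; names are unique."""

    fields: tuple[FieldSpec, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.fields]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"duplicate field names in schema: {sorted(dupes)}")

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields)

    def __contains__(self, name: str) -> bool:
        return name in self.field_names

    def __getitem__(self, name: str) -> FieldSpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    def identifier_fields(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields if f.role == "identifier")

    def require(self, names: Iterable[str], context: str) -> None:
        """Raise ConfigError if any name is not declared in the schema."""
        unknown = [n for n in names if n not in self]
        if unknown:
            raise ConfigError(f"{context} references unknown field(s): {unknown}")


def _norm_text(raw: str) -> str:
    # iterate to a fixpoint: case-folding can produce non-NFC output on
    # exotic code points, which would break idempotence after one pass
    s = raw
    for _ in range(4):
        nxt = unicodedata.normalize("NFC", s)
        nxt = _WS_RE.sub(" ", nxt.strip()).casefold()
        if nxt == s:
            break
        s = nxt
    return s


def _norm_phone(raw: str) -> str:
    digits = _NON_DIGIT_RE.sub("", raw)
    # compare on the national number: keep the last 10 digits when a
    # country code is present, so "+1 843 555 0101" == "8435550101"
    if len(digits) > 10:
        digits = digits[-10:]
    return digits


def _norm_date(raw: str) -> str:
    try:
        ts = pd.Timestamp(raw.strip())
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date value {raw!r}") from exc
    return ts.date().isoformat()


def normalize_value(spec: FieldSpec, raw: str):
    """Canonicalise one raw value under the field's normalizer.

    Deterministic and idempotent; empty/whitespace-only input -> MISSING.
    """
    if raw is None:
        return MISSING
    raw = str(raw)
    if not raw.strip():
        return MISSING
    kind = spec.normalizer
    if kind == "exact":
        return raw.strip()
    if kind == "text":
        return _norm_text(raw)
    if kind == "email":
        return raw.strip().casefold()
    if kind == "phone":
        out = _norm_phone(raw)
        return out if out else MISSING
    if kind == "date":
        return _norm_date(raw)
    raise ConfigError(f"unknown normalizer kind {kind!r}")  # pragma: no cover


@dataclass(frozen=True)
class ScreeningRecord:
    """One screening-survey submission after normalization.

    Records order by (submitted_at, record_id); that ordering defines which
    member of a duplicate set is the "original".
    """

    record_id: str
    submitted_at: datetime
    values: Mapping[str, str] = field(default_factory=dict)
    norm_values: Mapping[str, object] = field(default_factory=dict)

    @property
    def sort_key(self) -> tuple[datetime, str]:
        return (self.submitted_at, self.record_id)

    def date(self) -> date:
        return self.submitted_at.date()

    def __lt__(self, other: "ScreeningRecord") -> bool:
        return self.sort_key < other.sort_key


def make_record(
    record_id: str,
    submitted_at,
    values: Mapping[str, str],
    schema: Schema,
    tz: str | None = None,
) -> ScreeningRecord:
    """Build a normalized record. Timestamps are localised to the study
    timezone when naive; "same day" downstream means same calendar date there."""
    ts = pd.Timestamp(submitted_at)
    if pd.isna(ts):
        raise ValueError(f"record {record_id!r}: missing/unparseable timestamp")
    if tz is not None:
        tzinfo = ZoneInfo(tz)
        ts = ts.tz_localize(tzinfo) if ts.tzinfo is None else ts.tz_convert(tzinfo)
    norm = {
        f.name: normalize_value(f, values.get(f.name, "")) for f in schema.fields
    }
    raw = {f.name: str(values.get(f.name, "") or "") for f in schema.fields}
    return ScreeningRecord(
        record_id=str(record_id),
        submitted_at=ts.to_pydatetime(),
        values=raw,
        norm_values=norm,
    )


def load_records(
    table: pd.DataFrame,
    schema: Schema,
    tz: str | None = None,
    id_column: str = "record_id",
    time_column: str = "submitted_at",
) -> list[ScreeningRecord]:
    """Load a screening export into an ordered record store.

    The table must carry ``record_id`` and ``submitted_at`` columns plus
    every schema field. Returns records sorted by (submitted_at, record_id);
    the row count is preserved (no silent drops).

    Raises
    ------
    ValueError
        On a duplicated record_id or an unparseable timestamp (the error
        names the offending row).
    ConfigError
        When a schema field is absent from the table.
    """
    for col in (id_column, time_column):
        if col not in table.columns:
            raise ValueError(f"input table lacks required column {col!r}")
    missing_cols = [f.name for f in schema.fields if f.name not in table.columns]
    if missing_cols:
        raise ConfigError(f"input table lacks schema field column(s): {missing_cols}")

    ids = table[id_column].astype(str)
    dup_ids = ids[ids.duplicated()].unique().tolist()
    if dup_ids:
        raise ValueError(f"duplicate record_id values: {dup_ids}")

    records: list[ScreeningRecord] = []
    for i, row in enumerate(table.itertuples(index=False)):
        rowd = dict(zip(table.columns, row))
        raw_ts = rowd[time_column]
        try:
            rec = make_record(
                str(rowd[id_column]), raw_ts, rowd, schema, tz=tz
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"row {i} (record_id={rowd[id_column]!r}): bad timestamp {raw_ts!r}"
            ) from exc
        records.append(rec)
    records.sort(key=lambda r: r.sort_key)
    assert len(records) == len(table)
    return records


def fields_agree(a: ScreeningRecord, b: ScreeningRecord, field_name: str) -> bool:
    """True iff both records carry the same canonical value and neither is MISSING."""
    va = a.norm_values.get(field_name, MISSING)
    vb = b.norm_values.get(field_name, MISSING)
    if va is MISSING or vb is MISSING:
        return False
    return va == vb
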