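"""The duplicate-detection criteria language.

A criteria set is a disjunction of conjunctive criteria evaluated within a
time window: two submissions form a duplicate pair when at least one
criterion matches (every field in that criterion agrees on canonical
values, none missing) AND the submissions fall within ``window_days``
calendar days of one another (boundary inclusive, date resolution).

Example — the classic screening rule "identical first and last name, OR
identical email, OR identical phone, within 6 months"::

    cs = CriteriaSet(
        criteria=(
            MatchCriterion("name", ("first_name", "last_name")),
            MatchCriterion("email", ("email",)),
            MatchCriterion("phone", ("phone",)),
        ),
        window_days=183,
    )
"""

from __future__ import annotations

from dataclasses import dataclass

from .schema import ConfigError, Schema, ScreeningRecord, fields_agree

__all__ = [
    "MatchCriterion",
    "CriteriaSet",
    "criterion_matches",
    "matched_criteria",
    "within_window",
    "is_duplicate_pair",
    "gap_days",
]


@dataclass(frozen=True)
class MatchCriterion:
    """One conjunctive block: ALL listed fields must agree for a match."""

    label: str
    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.fields:
            raise ConfigError(f"criterion {self.label!r} lists no fields")
        if len(set(self.fields)) != len(self.fields):
            raise ConfigError(f"criterion {self.label!r} lists a field twice")
        object.__setattr__(self, "fields", tuple(self.fields))

    def validate(self, schema: Schema) -> None:
        schema.require(self.fields, f"criterion {self.label!r}")


@dataclass(frozen=True)
class CriteriaSet:
    """Disjunction of criteria plus the shared time window (in days)."""

    criteria: tuple[MatchCriterion, ...]
    window_days: int = 183

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ConfigError("criteria set must contain at least one criterion")
        if int(self.window_days) < 1:
            raise ConfigError("window_days must be >= 1")
        labels = [c.label for c in self.criteria]
        if len(set(labels)) != len(labels):
            raise ConfigError("criterion labels must be unique")
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(self, "window_days", int(self.window_days))

    def validate(self, schema: Schema) -> None:
        for c in self.criteria:
            c.validate(schema)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.criteria)


def criterion_matches(
    a: ScreeningRecord, b: ScreeningRecord, c: MatchCriterion
) -> bool:
    """True iff every field of the criterion agrees between the two records
    on canonical values, with no side missing. Symmetric in (a, b)."""
    return all(fields_agree(a, b, f) for f in c.fields)


def matched_criteria(
    a: ScreeningRecord, b: ScreeningRecord, cs: CriteriaSet
) -> list[str]:
    """Labels of ALL criteria satisfied by the pair (not just the first).

    The full list is what study staff see when reviewing a flag: it shows
    which identifier combinations the submitter kept intact.
    """
    return [c.label for c in cs.criteria if criterion_matches(a, b, c)]


def gap_days(a: ScreeningRecord, b: ScreeningRecord) -> int:
    """Absolute gap between the two submissions in whole calendar days
    (study-timezone dates; same day -> 0)."""
    return abs((a.date() - b.date()).days)


def within_window(a: ScreeningRecord, b: ScreeningRecord, window_days: int) -> bool:
    """True iff the pair's calendar-date gap is <= window_days (inclusive)."""
    return gap_days(a, b) <= window_days


def is_duplicate_pair(
    a: ScreeningRecord, b: ScreeningRecord, cs: CriteriaSet
) -> bool:
    """The duplicate-pair oracle used everywhere downstream: at least one
    criterion matches and the pair lies within the window."""
    return within_window(a, b, cs.window_days) and bool(matched_criteria(a, b, cs))
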