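"""Duplicate-detection engine for screening streams.

Two entry points cover the two ways the rule is used in practice:

* :func:`check_incoming` — streaming mode, one submission at a time against
  the store of prior submissions, as a screening survey would run it. The
  flag carries *every* matching prior record with the criterion labels that
  fired, so staff reviewing it can see which fields the submitter kept and
  which they changed. A flagged record still enters the store: later
  resubmissions must match the whole chain, not only the first record.
* :func:`build_duplicate_sets` / :func:`classify` — batch mode over a full
  export. Duplicate sets are the connected components (size >= 2) of the
  graph whose edges are duplicate pairs, so a chain A-B, B-C groups
  {A, B, C} even when A and C do not match directly — exactly what chained
  identifier mutation by one person produces. The earliest member of each
  set is its "original"; the rest are "duplicate entries".

Counts follow the convention: duplicate records = originals + entries;
the duplicate rate is that total over all submissions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import networkx as nx

from .matching import CriteriaSet, gap_days, matched_criteria, within_window
from .schema import MISSING, Schema, ScreeningRecord

__all__ = [
    "Decision",
    "GapCategory",
    "DuplicateFlag",
    "DuplicateSet",
    "EntryProfile",
    "DedupResult",
    "check_incoming",
    "build_duplicate_sets",
    "classify",
    "intent_profile",
    "dedupe",
    "gap_category",
]

Decision = Literal["auto_rejected", "needs_review", "clean"]
GapCategory = Literal["same_day", "within_week", "within_month", "over_month"]

GAP_CATEGORIES: tuple[GapCategory, ...] = (
    "same_day",
    "within_week",
    "within_month",
    "over_month",
)


def gap_category(days: int) -> GapCategory:
    """Bucket a day gap: 0 / 1-7 / 8-31 / >=32."""
    if days < 0:
        raise ValueError("gap must be non-negative")
    if days == 0:
        return "same_day"
    if days <= 7:
        return "within_week"
    if days <= 31:
        return "within_month"
    return "over_month"


@dataclass(frozen=True)
class DuplicateFlag:
    """Outcome of checking one incoming submission against the prior store."""

    record_id: str
    matched: tuple[tuple[str, tuple[str, ...], int], ...]  # (prior_id, labels, gap_days)
    decision: Decision

    @property
    def is_flagged(self) -> bool:
        return self.decision != "clean"

    @property
    def min_gap_days(self) -> Optional[int]:
        return min((g for _, _, g in self.matched), default=None)


@dataclass(frozen=True)
class DuplicateSet:
    """A transitive group of mutually linked submissions (size >= 2)."""

    members: tuple[ScreeningRecord, ...]  # sorted by (submitted_at, record_id)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.members, key=lambda r: r.sort_key))
        object.__setattr__(self, "members", ordered)
        if len(ordered) < 2:
            raise ValueError("a duplicate set needs at least 2 members")

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(r.record_id for r in self.members)

    @property
    def original(self) -> ScreeningRecord:
        return self.members[0]

    @property
    def original_id(self) -> str:
        return self.members[0].record_id

    @property
    def entries(self) -> tuple[ScreeningRecord, ...]:
        return self.members[1:]

    @property
    def entry_ids(self) -> tuple[str, ...]:
        return tuple(r.record_id for r in self.members[1:])

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EntryProfile:
    """Descriptive profile of one duplicate entry against its nearest
    earlier match; no fraud verdict is attached — that is a staff decision."""

    entry_id: str
    nearest_match_id: str
    gap_days: int
    gap_category: GapCategory
    kept_fields: tuple[str, ...]     # criterion fields identical to the match
    changed_fields: tuple[str, ...]  # identifier-role fields that differ


@dataclass
class DedupResult:
    """Batch dedup outcome with the summary tallies."""

    total_records: int
    duplicate_sets: list[DuplicateSet]
    entry_profiles: list[EntryProfile] = field(default_factory=list)

    @property
    def n_original_duplicates(self) -> int:
        return len(self.duplicate_sets)

    @property
    def n_duplicate_entries(self) -> int:
        return sum(len(s) - 1 for s in self.duplicate_sets)

    @property
    def n_duplicate_records(self) -> int:
        return self.n_original_duplicates + self.n_duplicate_entries

    @property
    def duplicate_rate_pct(self) -> float:
        if self.total_records == 0:
            return 0.0
        return 100.0 * self.n_duplicate_records / self.total_records

    @property
    def max_set_size(self) -> int:
        return max((len(s) for s in self.duplicate_sets), default=0)

    @property
    def gap_counts(self) -> Counter:
        c = Counter({g: 0 for g in GAP_CATEGORIES})
        c.update(p.gap_category for p in self.entry_profiles)
        return c

    @property
    def field_profile_counts(self) -> Counter:
        """Tally of duplicated-fields patterns across entries, keyed by
        'kept=<a+b>|changed=<c+d>'. A reconstruction of the per-field
        breakdown staff reports show; category definitions are ours."""
        c: Counter = Counter()
        for p in self.entry_profiles:
            key = "kept={}|changed={}".format(
                "+".join(p.kept_fields) or "-", "+".join(p.changed_fields) or "-"
            )
            c[key] += 1
        return c


def check_incoming(
    record: ScreeningRecord,
    store: list[ScreeningRecord],
    cs: CriteriaSet,
    mode: Literal["auto", "review"] = "review",
) -> DuplicateFlag:
    """Flag one incoming submission against all prior submissions.

    Compares the record against every prior record within the time window
    and reports *all* matches (prior id, criterion labels, day gap). The
    decision is ``auto_rejected`` (mode=auto, any match), ``needs_review``
    (mode=review, any match) or ``clean``. The record is appended to the
    store regardless of the decision.
    """
    if any(r.record_id == record.record_id for r in store):
        raise ValueError(f"record {record.record_id!r} already in store")
    matched: list[tuple[str, tuple[str, ...], int]] = []
    for prior in store:
        if not within_window(record, prior, cs.window_days):
            continue
        labels = matched_criteria(record, prior, cs)
        if labels:
            matched.append((prior.record_id, tuple(labels), gap_days(record, prior)))
    store.append(record)
    if not matched:
        decision: Decision = "clean"
    elif mode == "auto":
        decision = "auto_rejected"
    else:
        decision = "needs_review"
    return DuplicateFlag(record.record_id, tuple(matched), decision)


def _pair_edges(
    records: Sequence[ScreeningRecord], cs: CriteriaSet
) -> Iterable[tuple[str, str]]:
    """Duplicate-pair edges via criterion-key blocking: only records sharing
    every canonical value of some criterion can pair, so group on that key
    and compare within groups (window check per pair)."""
    seen: set[tuple[str, str]] = set()
    for crit in cs.criteria:
        groups: dict[tuple, list[ScreeningRecord]] = {}
        for r in records:
            key = tuple(r.norm_values.get(f, MISSING) for f in crit.fields)
            if any(v is MISSING for v in key):
                continue
            groups.setdefault(key, []).append(r)
        for group in groups.values():
            if len(group) < 2:
                continue
            group.sort(key=lambda r: r.sort_key)
            for i, a in enumerate(group):
                for b in group[i + 1 :]:
                    if gap_days(a, b) > cs.window_days:
                        continue
                    e = tuple(sorted((a.record_id, b.record_id)))
                    if e not in seen:
                        seen.add(e)
                        yield e


def build_duplicate_sets(
    store: Sequence[ScreeningRecord], cs: CriteriaSet
) -> list[DuplicateSet]:
    """Connected components (size >= 2) of the duplicate-pair graph.

    Output order is deterministic: by the original member's
    (submitted_at, record_id).
    """
    by_id = {r.record_id: r for r in store}
    if len(by_id) != len(store):
        raise ValueError("store contains duplicated record_id values")
    g = nx.Graph()
    g.add_edges_from(_pair_edges(store, cs))
    sets = [
        DuplicateSet(members=tuple(by_id[rid] for rid in comp))
        for comp in nx.connected_components(g)
        if len(comp) >= 2
    ]
    sets.sort(key=lambda s: s.original.sort_key)
    return sets


def _nearest_earlier_match(
    entry: ScreeningRecord, dset: DuplicateSet, cs: CriteriaSet
) -> Optional[tuple[ScreeningRecord, list[str]]]:
    """The earlier set member with the smallest day gap that directly
    matches the entry; ties broken toward the later (closer) submission."""
    best: Optional[tuple[int, tuple, ScreeningRecord, list[str]]] = None
    for other in dset.members:
        if not other.sort_key < entry.sort_key:
            continue
        if not within_window(entry, other, cs.window_days):
            continue
        labels = matched_criteria(entry, other, cs)
        if not labels:
            continue
        g = gap_days(entry, other)
        cand = (g, (other.submitted_at, other.record_id), other, labels)
        # smallest gap wins; equal gaps resolve toward the later submission
        if best is None or cand[0] < best[0] or (
            cand[0] == best[0] and cand[1] > best[1]
        ):
            best = cand
    if best is None:
        return None
    return best[2], best[3]


def classify(
    sets: Sequence[DuplicateSet],
    total_records: int,
    cs: Optional[CriteriaSet] = None,
    schema: Optional[Schema] = None,
) -> DedupResult:
    """Assemble the batch result: originals = number of sets, entries =
    sum of (set size - 1), plus per-entry gap/field profiles when the
    criteria set (and optionally the schema, for identifier roles) is given.

    A transitively linked entry can sit outside the window of every earlier
    direct match only in pathological chains; such entries are profiled
    against their nearest earlier set member by raw gap instead.
    """
    n_members = sum(len(s) for s in sets)
    if total_records < n_members:
        raise ValueError(
            f"total_records={total_records} < records in duplicate sets ({n_members})"
        )
    profiles: list[EntryProfile] = []
    if cs is not None:
        id_fields = schema.identifier_fields() if schema is not None else ()
        for dset in sets:
            for entry in dset.entries:
                hit = _nearest_earlier_match(entry, dset, cs)
                if hit is None:
                    # chained component: no in-window direct match; fall back
                    # to the nearest earlier member for the gap bucket
                    other = min(
                        (m for m in dset.members if m.sort_key < entry.sort_key),
                        key=lambda m: gap_days(entry, m),
                    )
                    labels: list[str] = []
                else:
                    other, labels = hit
                kept = tuple(
                    dict.fromkeys(
                        f
                        for c in (cs.criteria if cs else ())
                        if c.label in labels
                        for f in c.fields
                    )
                )
                changed = tuple(
                    f
                    for f in id_fields
                    if f not in kept
                    and not _same_value(entry, other, f)
                )
                g = gap_days(entry, other)
                profiles.append(
                    EntryProfile(
                        entry_id=entry.record_id,
                        nearest_match_id=other.record_id,
                        gap_days=g,
                        gap_category=gap_category(g),
                        kept_fields=kept,
                        changed_fields=changed,
                    )
                )
    return DedupResult(
        total_records=total_records,
        duplicate_sets=list(sets),
        entry_profiles=profiles,
    )


def _same_value(a: ScreeningRecord, b: ScreeningRecord, field_name: str) -> bool:
    va = a.norm_values.get(field_name, MISSING)
    vb = b.norm_values.get(field_name, MISSING)
    if va is MISSING and vb is MISSING:
        return True  # both blank: not "changed", just absent
    return va == vb


def intent_profile(result: DedupResult) -> list[EntryProfile]:
    """Per-entry (gap category, changed fields, kept fields) tuples —
    the descriptive input staff use to separate accidental resubmission
    (same-day, nothing changed) from likely intentional fraud (same-day,
    identifiers selectively changed). Purely descriptive."""
    return list(result.entry_profiles)


def dedupe(
    store: Sequence[ScreeningRecord],
    cs: CriteriaSet,
    schema: Optional[Schema] = None,
) -> DedupResult:
    """Batch convenience: build sets then classify with profiles."""
    sets = build_duplicate_sets(store, cs)
    return classify(sets, len(store), cs=cs, schema=schema)
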