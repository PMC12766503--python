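"""Synthetic screening-stream generator with ground truth.

Real screening exports cannot be shared (they are identifiable by nature),
so detection and quota behaviour are exercised against a simulated stream
containing the three populations a remote screening survey actually sees:

* **honest** applicants — one submission each, globally unique identifiers;
* **mistake** resubmitters — people who accidentally complete the survey
  again, copying all their identifiers, typically after a longer delay;
* **fraud** resubmitters — people probing eligibility by re-submitting
  rapidly (often the same day) while mutating a subset of identifier
  fields per resubmission to dodge duplicate checks.

All identifiers are fabricated (example.org emails, 555-prefix phone
numbers, names from a fixed synthetic list); no real personal data appears
anywhere. Generation is fully deterministic given the seed, and mutated
values are always drawn fresh — a fraudster never reverts to an earlier
value, so spurious direct matches between non-adjacent submissions cannot
arise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import datetime, timedelta
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dedup import DuplicateFlag
from .schema import FieldSpec, Schema, ScreeningRecord, load_records

__all__ = [
    "SimParams",
    "StreamTruth",
    "ConfusionResult",
    "default_sim_schema",
    "generate_stream",
    "stream_to_frame",
    "truth_confusion",
]

IDENTIFIER_FIELDS = ("first_name", "last_name", "email", "phone")

# fixed synthetic name pool; uniqueness of (first, last) pairs is enforced
# with a numeric suffix once combinations run out
_FIRST = (
    "ada alan beth caleb dana eli fern gita hana ivan jade kofi lena marco "
    "nia omar pria quinn rosa sami tara umar vera wade ximena yara zane "
    "arlo bree cyrus dot edna flip gus henna iris juno kira liv moss nell"
).split()
_LAST = (
    "abbott blake cortez dalton ebert flores grady holt ibarra joyce kerr "
    "lowell meyer novak ortiz pratt quint reyes stone tran ueda vance "
    "whitman xu yates zhou adler burke cole dietz eng ferris gold hale"
).split()


def _default_fraud_gaps() -> dict[int, float]:
    # rapid-succession probing: most resubmissions land on the same day
    return {0: 0.70, 1: 0.10, 2: 0.05, 5: 0.05, 12: 0.05, 40: 0.05}


def _default_mistake_gaps() -> dict[int, float]:
    # genuine mistakes mostly come back after weeks to months
    return {0: 0.05, 3: 0.10, 10: 0.15, 21: 0.20, 45: 0.30, 120: 0.20}


def _default_mutation_probs() -> dict[str, float]:
    return {"first_name": 0.4, "last_name": 0.4, "email": 0.3, "phone": 0.3}


def _default_category_mix() -> dict[str, dict[str, float]]:
    # smoking-level bins typical of a cessation-trial screener
    return {
        "cpd_bin": {"1-5": 0.2, "6-10": 0.2, "11-15": 0.2, "16+": 0.2, "quit": 0.2}
    }


@dataclass(frozen=True)
class SimParams:
    """Knobs of the simulated screening world.

    ``fraud_resubmissions`` is the inclusive (low, high) range of *total*
    submissions a fraud identity makes (uniform draw); up to 15 mirrors the
    worst observed repeat-submitters. ``mutation_probs`` give the per-field,
    per-resubmission probability a fraudster changes that identifier.
    """

    n_identities: int = 300
    fraud_fraction: float = 0.10
    mistake_fraction: float = 0.08
    fraud_resubmissions: tuple[int, int] = (2, 15)
    mistake_resubmissions: tuple[int, int] = (2, 2)
    mutation_probs: Mapping[str, float] = dc_field(
        default_factory=_default_mutation_probs
    )
    fraud_gap_model: Mapping[int, float] = dc_field(default_factory=_default_fraud_gaps)
    mistake_gap_model: Mapping[int, float] = dc_field(
        default_factory=_default_mistake_gaps
    )
    category_mix: Mapping[str, Mapping[str, float]] = dc_field(
        default_factory=_default_category_mix
    )
    mean_interarrival_days: float = 0.25
    start: str = "2024-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_identities < 1:
            raise ValueError("n_identities must be >= 1")
        for name in ("fraud_fraction", "mistake_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fraud_fraction + self.mistake_fraction > 1.0 + 1e-12:
            raise ValueError("fraud_fraction + mistake_fraction must be <= 1")
        lo, hi = self.fraud_resubmissions
        if not (2 <= lo <= hi):
            raise ValueError("fraud_resubmissions must be a range with low >= 2")
        for f, p in self.mutation_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mutation prob for {f!r} out of [0, 1]")
        for name in ("fraud_gap_model", "mistake_gap_model"):
            gm = getattr(self, name)
            if not gm or any(d < 0 for d in gm) or any(p < 0 for p in gm.values()):
                raise ValueError(f"{name} must map day gaps >= 0 to weights >= 0")


@dataclass(frozen=True)
class TruthRow:
    record_id: str
    identity_id: str
    label: Literal["honest", "mistake", "fraud"]
    submission_index: int


@dataclass
class StreamTruth:
    """Ground truth for a generated stream, indexable by record id."""

    rows: list[TruthRow]

    def by_record(self) -> dict[str, TruthRow]:
        return {r.record_id: r for r in self.rows}

    def true_duplicate_entries(self) -> set[str]:
        """Records that are resubmissions (index >= 1) of some identity."""
        return {r.record_id for r in self.rows if r.submission_index >= 1}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "record_id": r.record_id,
                    "identity_id": r.identity_id,
                    "label": r.label,
                    "submission_index": r.submission_index,
                }
                for r in self.rows
            ]
        )


def default_sim_schema(params: SimParams) -> Schema:
    """Schema matching the simulator's output columns: the four synthetic
    identifier fields plus one demographic field per category mix entry."""
    fields = [
        FieldSpec("first_name", "identifier", "text"),
        FieldSpec("last_name", "identifier", "text"),
        FieldSpec("email", "identifier", "email"),
        FieldSpec("phone", "identifier", "phone"),
    ]
    fields += [FieldSpec(name, "demographic", "exact") for name in params.category_mix]
    return Schema(tuple(fields))


class _IdentityForge:
    """Seeded fabricator of unique synthetic identities and fresh mutated
    values. Collision checking is global so no two identities (and no two
    mutation draws) ever share a name pair, email or phone."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self.used_names: set[tuple[str, str]] = set()
        self.used_emails: set[str] = set()
        self.used_phones: set[str] = set()
        self._serial = 0

    def _next_serial(self) -> int:
        self._serial += 1
        return self._serial

    def name_pair(self) -> tuple[str, str]:
        for _ in range(50):
            first = _FIRST[self.rng.integers(len(_FIRST))]
            last = _LAST[self.rng.integers(len(_LAST))]
            if (first, last) not in self.used_names:
                self.used_names.add((first, last))
                return first.capitalize(), last.capitalize()
        last = f"{_LAST[self.rng.integers(len(_LAST))]}{self._next_serial()}"
        first = _FIRST[self.rng.integers(len(_FIRST))]
        self.used_names.add((first, last))
        return first.capitalize(), last.capitalize()

    def email(self, first: str, last: str) -> str:
        while True:
            addr = (
                f"{first.lower()}.{last.lower()}{self.rng.integers(1, 10_000)}"
                "@example.org"
            )
            if addr not in self.used_emails:
                self.used_emails.add(addr)
                return addr

    def phone(self) -> str:
        while True:
            num = f"555{self.rng.integers(0, 10_000_000):07d}"
            if num not in self.used_phones:
                self.used_phones.add(num)
                return num

    def fresh_value(self, field_name: str, current: Mapping[str, str]) -> dict[str, str]:
        """A brand-new value for one identifier field, checked so the
        *resulting* identity (e.g. new first + kept last name) collides with
        no previously seen one."""
        if field_name in ("first_name", "last_name"):
            pool = _FIRST if field_name == "first_name" else _LAST
            other = (
                current["last_name"] if field_name == "first_name" else current["first_name"]
            ).lower()
            for attempt in range(60):
                comp = pool[self.rng.integers(len(pool))]
                if attempt >= 50:
                    comp = f"{comp}{self._next_serial()}"
                pair = (comp, other) if field_name == "first_name" else (other, comp)
                if pair not in self.used_names:
                    self.used_names.add(pair)
                    return {field_name: comp.capitalize()}
            raise RuntimeError("could not fabricate a unique name")  # pragma: no cover
        if field_name == "email":
            base = f"{current['first_name']}.{current['last_name']}".lower()
            return {"email": self.email(*base.split(".", 1))}
        if field_name == "phone":
            return {"phone": self.phone()}
        raise ValueError(f"not an identifier field: {field_name!r}")


def _sample_gap(rng: np.random.Generator, model: Mapping[int, float]) -> int:
    days = np.array(sorted(model), dtype=int)
    w = np.array([model[int(d)] for d in days], dtype=float)
    return int(rng.choice(days, p=w / w.sum()))


def generate_stream(
    params: SimParams,
) -> tuple[list[ScreeningRecord], StreamTruth]:
    """Generate one screening stream plus its ground truth.

    Deterministic given ``params.seed``. Records come back sorted by
    (submitted_at, record_id) under :func:`default_sim_schema`; record ids
    are assigned in that submission order.
    """
    rng = np.random.default_rng(params.seed)
    forge = _IdentityForge(rng)
    schema = default_sim_schema(params)
    start = pd.Timestamp(params.start)

    cat_fields = list(params.category_mix)
    cat_values = {
        f: (list(mix.keys()), np.array(list(mix.values()), dtype=float))
        for f, mix in params.category_mix.items()
    }

    rows: list[dict] = []  # raw field values + _ts + _identity meta
    arrival = start
    for i in range(params.n_identities):
        arrival = arrival + pd.Timedelta(
            days=float(rng.exponential(params.mean_interarrival_days))
        )
        u = rng.random()
        if u < params.fraud_fraction:
            label = "fraud"
            lo, hi = params.fraud_resubmissions
            n_sub = int(rng.integers(lo, hi + 1))
            gap_model = params.fraud_gap_model
        elif u < params.fraud_fraction + params.mistake_fraction:
            label = "mistake"
            lo, hi = params.mistake_resubmissions
            n_sub = int(rng.integers(lo, hi + 1))
            gap_model = params.mistake_gap_model
        else:
            label = "honest"
            n_sub = 1
            gap_model = params.mistake_gap_model

        first, last = forge.name_pair()
        values = {
            "first_name": first,
            "last_name": last,
            "email": forge.email(first.lower(), last.lower()),
            "phone": forge.phone(),
        }
        for f in cat_fields:
            vals, w = cat_values[f]
            values[f] = str(vals[rng.choice(len(vals), p=w / w.sum())])

        identity_id = f"ID{i:05d}"
        day = arrival.normalize()
        for j in range(n_sub):
            if j > 0:
                day = day + pd.Timedelta(days=_sample_gap(rng, gap_model))
                if label == "fraud":
                    for f, p in params.mutation_probs.items():
                        if f in values and rng.random() < p:
                            values.update(forge.fresh_value(f, values))
            rows.append(
                {
                    **values,
                    "_day": day,
                    "_identity": identity_id,
                    "_label": label,
                    "_index": j,
                }
            )

    # assign intra-day seconds so submission order within an identity-day is
    # preserved by the global (timestamp, record_id) ordering
    by_identity_day: dict[tuple[str, pd.Timestamp], list[dict]] = {}
    for r in rows:
        by_identity_day.setdefault((r["_identity"], r["_day"]), []).append(r)
    for group in by_identity_day.values():
        secs = sorted(
            int(s) for s in rng.choice(86_400, size=len(group), replace=False)
        )
        for r, s in zip(group, secs):
            r["_ts"] = r["_day"] + pd.Timedelta(seconds=s)

    rows.sort(key=lambda r: (r["_ts"], r["_identity"], r["_index"]))
    frame_rows = []
    truth_rows = []
    for k, r in enumerate(rows):
        rid = f"R{k + 1:06d}"
        frame_rows.append(
            {
                "record_id": rid,
                "submitted_at": r["_ts"].isoformat(),
                **{f.name: r[f.name] for f in schema.fields},
            }
        )
        truth_rows.append(TruthRow(rid, r["_identity"], r["_label"], r["_index"]))

    table = pd.DataFrame(frame_rows)
    records = load_records(table, schema)
    return records, StreamTruth(truth_rows)


def stream_to_frame(records: Sequence[ScreeningRecord]) -> pd.DataFrame:
    """Render records back to the screening CSV dialect (raw values)."""
    return pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "submitted_at": r.submitted_at.isoformat(),
                **dict(r.values),
            }
            for r in records
        ]
    )


@dataclass(frozen=True)
class ConfusionResult:
    """Detection quality over duplicate *entries* (resubmissions)."""

    precision: float
    recall: float
    n_true_entries: int
    n_flagged: int
    n_honest_flagged: int


def truth_confusion(
    flags: Iterable[DuplicateFlag], truth: StreamTruth
) -> ConfusionResult:
    """Precision/recall of streaming flags against simulator ground truth.

    Recall: flagged true duplicate entries over all true duplicate entries.
    Precision: flagged true duplicate entries over all flagged records.
    Degenerate denominators (nothing to find / nothing flagged) count as 1.
    Also reports how many records of honest identities were flagged.
    """
    flagged = {f.record_id for f in flags if f.is_flagged}
    true_entries = truth.true_duplicate_entries()
    by_rec = truth.by_record()
    hits = flagged & true_entries
    recall = len(hits) / len(true_entries) if true_entries else 1.0
    precision = len(hits) / len(flagged) if flagged else 1.0
    honest_flagged = sum(1 for rid in flagged if by_rec[rid].label == "honest")
    return ConfusionResult(
        precision=precision,
        recall=recall,
        n_true_entries=len(true_entries),
        n_flagged=len(flagged),
        n_honest_flagged=honest_flagged,
    )
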