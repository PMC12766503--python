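from __future__ import annotations

import numpy as np
import pytest

from screenguard import (
    CriteriaSet,
    FieldSpec,
    MatchCriterion,
    QuotaConfigSpec,
    QuotaPredicate,
    QuotaRule,
    Schema,
    make_record,
)

CPD_CATEGORIES = ("1-5", "6-10", "11-15", "16+", "quit")


@pytest.fixture
def schema() -> Schema:
    return Schema(
        (
            FieldSpec("first_name", "identifier", "text"),
            FieldSpec("last_name", "identifier", "text"),
            FieldSpec("email", "identifier", "email"),
            FieldSpec("phone", "identifier", "phone"),
            FieldSpec("cpd_bin", "demographic", "exact"),
        )
    )


@pytest.fixture
def criteria() -> CriteriaSet:
    """Name-pair OR email OR phone, within ~6 months."""
    return CriteriaSet(
        (
            MatchCriterion("name", ("first_name", "last_name")),
            MatchCriterion("email", ("email",)),
            MatchCriterion("phone", ("phone",)),
        ),
        window_days=183,
    )


@pytest.fixture
def rec(schema):
    """Record factory: rec(id, date, **field values)."""

    def _make(record_id: str, submitted_at: str, **values):
        return make_record(record_id, submitted_at, values, schema)

    return _make


def cessation_quota_spec(**overrides) -> QuotaConfigSpec:
    """Smoking-cessation enrollment minimums: >=23 in each of four
    cigarettes-per-day bins and >=36 recent quitters, sample of 143."""
    rules = tuple(
        QuotaRule(
            label=f"bin_{c}",
            predicate=QuotaPredicate((("cpd_bin", c),)),
            bound="minimum",
            amount=23 if c != "quit" else 36,
            amount_kind="count",
        )
        for c in CPD_CATEGORIES
    )
    kwargs = dict(total_n=143, rules=rules)
    kwargs.update(overrides)
    return QuotaConfigSpec(**kwargs)


def category_candidates(n: int, seed: int, schema: Schema):
    """n eligible candidates with uniform category mix, one per day-ish."""
    rng = np.random.default_rng(seed)
    cats = rng.choice(CPD_CATEGORIES, size=n)
    recs = []
    base = np.datetime64("2024-01-01")
    for i, c in enumerate(cats):
        ts = str(base + np.timedelta64(i * 97, "m"))
        recs.append(
            make_record(
                f"c{i:04d}",
                ts,
                {
                    "first_name": f"f{i}",
                    "last_name": f"l{i}",
                    "email": f"u{i}@example.org",
                    "phone": f"555{i:07d}",
                    "cpd_bin": str(c),
                },
                schema,
            )
        )
    return recs
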