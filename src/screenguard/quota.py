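"""Quota-based enrollment control.

Eligible candidates are admitted or deferred so that configured enrollment
minimums and maximums hold at completion. Bounds can be counts or percents
of the sample, can be "nested" (a conjunction over several characteristics,
e.g. rural AND woman), and can be enforced over the full sample or within
consecutive equal-sized enrollment blocks.

The one non-obvious piece is *reserved-slot* logic for minimums: once the
remaining open slots are exactly what is needed to satisfy an unmet
minimum, candidates who do not help that minimum are rejected. With a 25%
minimum for women in a sample of N, after 75% of slots fill with non-women
only women are admitted. Two modes handle minimums whose predicates
overlap:

* ``independent`` (default): each unmet minimum claims its own reserved
  slots (shortfalls are summed). Safe, but over-reserves when one future
  candidate could satisfy two overlapping minimums at once.
* ``exact``: computes the true minimum number of future admits that could
  cover all shortfalls, by covering shortfalls with jointly satisfiable
  rule subsets (exhaustive search with memoisation at realistic sizes).

Invariants maintained: no ledger state ever violates a maximum, and the
enrolled count never exceeds the target sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from math import ceil, floor
from typing import Iterable, Literal, Optional, Sequence

from .schema import MISSING, ConfigError, Schema, ScreeningRecord

__all__ = [
    "QuotaPredicate",
    "QuotaRule",
    "QuotaConfigSpec",
    "QuotaLedger",
    "QuotaDecision",
    "QuotaFieldError",
    "effective_count",
    "evaluate",
    "replay",
    "AttainmentRow",
]

Bound = Literal["minimum", "maximum"]
AmountKind = Literal["count", "percent"]
Decision = Literal["admit", "reject_full", "reject_maximum", "reject_reserved"]


class QuotaFieldError(ValueError):
    """A candidate is missing a field a quota rule needs — a data problem,
    distinct from a quota rejection."""


@dataclass(frozen=True)
class QuotaPredicate:
    """Conjunction of (field, required canonical value) conditions."""

    conditions: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("quota predicate must have at least one condition")
        object.__setattr__(
            self, "conditions", tuple((str(f), str(v)) for f, v in self.conditions)
        )

    @property
    def fields(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.conditions)

    def validate(self, schema: Schema, context: str) -> None:
        schema.require(self.fields, context)

    def matches(self, record: ScreeningRecord) -> bool:
        for f, v in self.conditions:
            got = record.norm_values.get(f, MISSING)
            if got is MISSING:
                raise QuotaFieldError(
                    f"record {record.record_id!r} has no value for quota field {f!r}"
                )
            if got != v:
                return False
        return True

    def compatible_with(self, other: "QuotaPredicate") -> bool:
        """Whether one candidate could satisfy both predicates at once:
        no shared field demanding two different values."""
        mine = dict(self.conditions)
        for f, v in other.conditions:
            if f in mine and mine[f] != v:
                return False
        return True


@dataclass(frozen=True)
class QuotaRule:
    """One enrollment bound on candidates matching the predicate."""

    label: str
    predicate: QuotaPredicate
    bound: Bound
    amount: float
    amount_kind: AmountKind = "count"

    def __post_init__(self) -> None:
        if self.bound not in ("minimum", "maximum"):
            raise ConfigError(f"rule {self.label!r}: bound must be minimum|maximum")
        if self.amount_kind not in ("count", "percent"):
            raise ConfigError(f"rule {self.label!r}: kind must be count|percent")
        if self.amount <= 0:
            raise ConfigError(f"rule {self.label!r}: amount must be positive")
        if self.amount_kind == "percent" and self.amount > 100:
            raise ConfigError(f"rule {self.label!r}: percent must be in (0, 100]")
        if self.amount_kind == "count" and self.amount != int(self.amount):
            raise ConfigError(f"rule {self.label!r}: count amount must be an integer")


def effective_count(
    rule: QuotaRule, scope_size: int, total_n: Optional[int] = None
) -> int:
    """The integer bound the rule implies for a scope of ``scope_size`` slots.

    Percent amounts resolve against the scope size: ceiling for minimums
    (a 25% minimum must guarantee at least that share), floor for maximums.
    Count amounts pass through unchanged at full-sample scope; in a block
    scope (``total_n`` given and different from ``scope_size``) they are
    pro-rated by scope_size/total_n with the same rounding, and minimums
    are capped at the scope size so a short final block stays reachable.
    """
    if scope_size < 1:
        raise ValueError("scope_size must be >= 1")
    if rule.amount_kind == "percent":
        frac = Fraction(str(rule.amount)) * scope_size / 100
    else:
        if total_n is None or scope_size == total_n:
            return int(rule.amount)
        frac = Fraction(int(rule.amount)) * scope_size / total_n
    n = ceil(frac) if rule.bound == "minimum" else floor(frac)
    if rule.bound == "minimum":
        n = min(n, scope_size)
    return int(n)


@dataclass(frozen=True)
class QuotaConfigSpec:
    """Full quota configuration: target N, optional block size, rules."""

    total_n: int
    rules: tuple[QuotaRule, ...] = ()
    block_size: Optional[int] = None
    check_time: Literal["screening", "enrollment"] = "screening"
    reserve_mode: Literal["independent", "exact"] = "independent"

    def __post_init__(self) -> None:
        if self.total_n < 1:
            raise ConfigError("total_n must be >= 1")
        if self.block_size is not None and not (1 <= self.block_size <= self.total_n):
            raise ConfigError("block_size must be in [1, total_n]")
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise ConfigError("quota rule labels must be unique")
        object.__setattr__(self, "rules", tuple(self.rules))

    @property
    def blocked(self) -> bool:
        return self.block_size is not None and self.block_size < self.total_n

    def min_rules(self) -> tuple[QuotaRule, ...]:
        return tuple(r for r in self.rules if r.bound == "minimum")

    def max_rules(self) -> tuple[QuotaRule, ...]:
        return tuple(r for r in self.rules if r.bound == "maximum")

    def validate(self, schema: Optional[Schema] = None) -> None:
        """Cross-reference and provable-infeasibility checks.

        Minimum rules whose predicates are pairwise mutually exclusive
        compete for disjoint candidates, so their effective counts must fit
        in every scope. Only provable infeasibility is rejected.
        """
        if schema is not None:
            for r in self.rules:
                r.predicate.validate(schema, f"quota rule {r.label!r}")
        scopes = [self.total_n]
        if self.blocked:
            assert self.block_size is not None
            scopes.append(self.block_size)
            rem = self.total_n % self.block_size
            if rem:
                scopes.append(rem)
        mins = self.min_rules()
        if len(mins) > 16:  # subset enumeration guard; fall back to pairs
            groups: list[tuple[QuotaRule, ...]] = [
                (a, b)
                for i, a in enumerate(mins)
                for b in mins[i + 1 :]
                if not a.predicate.compatible_with(b.predicate)
            ]
        else:
            groups = []
            for mask in range(1, 1 << len(mins)):
                subset = [r for i, r in enumerate(mins) if mask >> i & 1]
                if len(subset) < 2:
                    continue
                if all(
                    not a.predicate.compatible_with(b.predicate)
                    for i, a in enumerate(subset)
                    for b in subset[i + 1 :]
                ):
                    groups.append(tuple(subset))
        for scope in scopes:
            for subset in groups:
                total = sum(
                    effective_count(r, scope, self.total_n) for r in subset
                )
                if total > scope:
                    raise ConfigError(
                        "infeasible quota config: mutually exclusive minimums "
                        f"{[r.label for r in subset]} need {total} slots in a "
                        f"scope of {scope}"
                    )


@dataclass
class LedgerEntry:
    record_id: str
    block_index: int
    categories: dict[str, str]
    check_time: str


@dataclass
class QuotaLedger:
    """Running enrollment state: who is in, in which block, with which
    quota-relevant category values."""

    spec: QuotaConfigSpec
    enrolled: list[LedgerEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.enrolled)

    @property
    def is_full(self) -> bool:
        return len(self.enrolled) >= self.spec.total_n

    def _block_of(self, position: int) -> int:
        if not self.spec.blocked:
            return 0
        assert self.spec.block_size is not None
        return position // self.spec.block_size

    def current_scope(self) -> tuple[int, int, int]:
        """(block index, slots already filled in scope, scope size) for the
        slot the next admit would occupy."""
        pos = len(self.enrolled)
        if not self.spec.blocked:
            return 0, pos, self.spec.total_n
        assert self.spec.block_size is not None
        b = self._block_of(pos)
        start = b * self.spec.block_size
        scope_size = min(self.spec.block_size, self.spec.total_n - start)
        return b, pos - start, scope_size

    def count(self, rule: QuotaRule, block_index: Optional[int] = None) -> int:
        """Enrollees satisfying the rule's predicate, overall or per block."""
        n = 0
        for e in self.enrolled:
            if block_index is not None and e.block_index != block_index:
                continue
            if _entry_matches(e, rule.predicate):
                n += 1
        return n

    def admit(self, record: ScreeningRecord) -> LedgerEntry:
        if self.is_full:
            raise ValueError("ledger is full")
        pos = len(self.enrolled)
        cats = {
            f: str(record.norm_values.get(f))
            for r in self.spec.rules
            for f in r.predicate.fields
        }
        entry = LedgerEntry(
            record_id=record.record_id,
            block_index=self._block_of(pos),
            categories=cats,
            check_time=self.spec.check_time,
        )
        self.enrolled.append(entry)
        return entry

    def recount(self) -> dict[str, int]:
        """Self-consistency oracle: per-rule tallies recomputed from scratch."""
        return {r.label: self.count(r) for r in self.spec.rules}


def _entry_matches(entry: LedgerEntry, pred: QuotaPredicate) -> bool:
    return all(entry.categories.get(f) == v for f, v in pred.conditions)


def _needed_slots_exact(
    shortfalls: dict[str, int], rules: dict[str, QuotaRule]
) -> int:
    """Minimum number of future admits that can cover all shortfalls when
    one admit may satisfy several jointly satisfiable minimums at once.

    Pairwise compatibility of conjunctive equality predicates implies joint
    satisfiability, so candidate 'types' are the maximal pairwise-compatible
    subsets of unmet rules. Exhaustive memoised search; the state space is
    tiny for realistic rule counts and shortfalls.
    """
    active = tuple(sorted(l for l, s in shortfalls.items() if s > 0))
    if not active:
        return 0
    compat = {
        (a, b): rules[a].predicate.compatible_with(rules[b].predicate)
        for a in active
        for b in active
    }
    # maximal pairwise-compatible subsets (greedy expansion over all seeds;
    # complete because every maximal clique contains each of its members)
    subsets: set[frozenset[str]] = set()
    for mask in range(1, 1 << len(active)):
        s = frozenset(l for i, l in enumerate(active) if mask >> i & 1)
        if all(compat[(a, b)] for a in s for b in s if a < b):
            subsets.add(s)
    maximal = [s for s in subsets if not any(s < t for t in subsets)]

    order = {l: i for i, l in enumerate(active)}

    @lru_cache(maxsize=None)
    def solve(state: tuple[int, ...]) -> int:
        if all(v == 0 for v in state):
            return 0
        best = sum(state)  # one admit per unit of shortfall always works
        for s in maximal:
            nxt = list(state)
            hit = False
            for l in s:
                i = order[l]
                if nxt[i] > 0:
                    nxt[i] -= 1
                    hit = True
            if hit:
                best = min(best, 1 + solve(tuple(nxt)))
        return best

    total = sum(shortfalls[l] for l in active)
    if total > 30:  # guard: greedy upper bound for degenerate configs
        state = [shortfalls[l] for l in active]
        admits = 0
        while any(v > 0 for v in state):
            s = max(maximal, key=lambda s: sum(state[order[l]] > 0 for l in s))
            for l in s:
                if state[order[l]] > 0:
                    state[order[l]] -= 1
            admits += 1
        return admits
    return solve(tuple(shortfalls[l] for l in active))


@dataclass(frozen=True)
class QuotaDecision:
    record_id: str
    decision: Decision
    rule_labels: tuple[str, ...]


def evaluate(
    record: ScreeningRecord, ledger: QuotaLedger, spec: QuotaConfigSpec
) -> QuotaDecision:
    """Decide one candidate and, on admit, update the ledger.

    Order of checks: full -> maximum -> reserved -> admit. The decision
    carries the labels of the rules implicated (violated maximums, or the
    unmet minimums the candidate does not help).
    """
    if ledger.spec is not spec and ledger.spec != spec:
        raise ValueError("ledger was built for a different quota spec")
    # evaluate all predicates up front so missing fields error out before
    # any rejection decision
    satisfies = {r.label: r.predicate.matches(record) for r in spec.rules}

    if ledger.is_full:
        return QuotaDecision(record.record_id, "reject_full", ())

    block, filled, scope_size = ledger.current_scope()
    scope_block = block if spec.blocked else None

    violated_max = tuple(
        r.label
        for r in spec.max_rules()
        if satisfies[r.label]
        and ledger.count(r, scope_block) + 1
        > effective_count(r, scope_size, spec.total_n)
    )
    if violated_max:
        return QuotaDecision(record.record_id, "reject_maximum", violated_max)

    open_after = scope_size - filled - 1  # slots left in scope if we admit
    mins = spec.min_rules()
    shortfalls = {
        r.label: max(
            0,
            effective_count(r, scope_size, spec.total_n)
            - ledger.count(r, scope_block)
            - (1 if satisfies[r.label] else 0),
        )
        for r in mins
    }
    if spec.reserve_mode == "exact":
        needed = _needed_slots_exact(shortfalls, {r.label: r for r in mins})
    else:
        needed = sum(shortfalls.values())
    if needed > open_after:
        implicated = tuple(
            r.label for r in mins if shortfalls[r.label] > 0 and not satisfies[r.label]
        )
        return QuotaDecision(record.record_id, "reject_reserved", implicated)

    ledger.admit(record)
    return QuotaDecision(record.record_id, "admit", ())


@dataclass(frozen=True)
class AttainmentRow:
    label: str
    bound: Bound
    target: int
    achieved_n: int
    achieved_pct: int
    met: bool


def _round_half_away(x: Fraction) -> int:
    return int(floor(x + Fraction(1, 2))) if x >= 0 else -int(floor(-x + Fraction(1, 2)))


def attainment(ledger: QuotaLedger, spec: QuotaConfigSpec) -> list[AttainmentRow]:
    """Per-rule attainment over the whole enrollment: effective target at
    full-sample scope, achieved count, achieved percent of final N
    (integer, half away from zero)."""
    final_n = len(ledger)
    rows = []
    for r in spec.rules:
        n = ledger.count(r)
        target = effective_count(r, spec.total_n)
        pct = _round_half_away(Fraction(100 * n, final_n)) if final_n else 0
        met = n >= target if r.bound == "minimum" else n <= target
        rows.append(AttainmentRow(r.label, r.bound, target, n, pct, met))
    return rows


def replay(
    stream: Iterable[ScreeningRecord], spec: QuotaConfigSpec
) -> tuple[QuotaLedger, list[AttainmentRow], list[QuotaDecision]]:
    """Apply :func:`evaluate` to candidates in screening order until the
    sample is full or the stream is exhausted.

    An unmet minimum at exhaustion is reported via ``warnings.warn`` and in
    the attainment table (``met=False``); it is not a crash — real
    recruitment can simply run dry.
    """
    ledger = QuotaLedger(spec=spec)
    decisions: list[QuotaDecision] = []
    for record in stream:
        decisions.append(evaluate(record, ledger, spec))
        if ledger.is_full:
            break
    table = attainment(ledger, spec)
    unmet = [row.label for row in table if row.bound == "minimum" and not row.met]
    if unmet:
        warnings.warn(
            f"stream exhausted with unmet minimum(s): {unmet}", stacklevel=2
        )
    return ledger, table, decisions
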