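"""Quota engine: bounds, reserved slots, blocks, percent arithmetic."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from screenguard import (
    ConfigError,
    FieldSpec,
    QuotaConfigSpec,
    QuotaLedger,
    QuotaPredicate,
    QuotaRule,
    Schema,
    effective_count,
    evaluate,
    make_record,
    replay,
)
from screenguard.quota import QuotaFieldError, attainment

from conftest import CPD_CATEGORIES, category_candidates, cessation_quota_spec

SEX_SCHEMA = Schema((FieldSpec("sex", "demographic", "exact"),
                     FieldSpec("area", "demographic", "exact")))


def sex_rec(i, sex, area="urban"):
    return make_record(
        f"r{i:03d}", f"2024-01-01T{i % 24:02d}:{i % 60:02d}", {"sex": sex, "area": area}, SEX_SCHEMA
    )


def min_rule(label, field, value, amount, kind="count"):
    return QuotaRule(label, QuotaPredicate(((field, value),)), "minimum", amount, kind)


def max_rule(label, field, value, amount, kind="count"):
    return QuotaRule(label, QuotaPredicate(((field, value),)), "maximum", amount, kind)


class TestEffectiveCount:
    @pytest.mark.parametrize(
        "bound,amount,kind,scope,expected",
        [
            ("minimum", 25, "percent", 143, 36),   # ceil(35.75)
            ("maximum", 50, "percent", 7, 3),      # floor(3.5)
            ("minimum", 23, "count", 999, 23),     # counts pass through
            ("minimum", 100, "percent", 5, 5),
        ],
    )
    def test_rounding(self, bound, amount, kind, scope, expected):
        r = QuotaRule("q", QuotaPredicate((("sex", "w"),)), bound, amount, kind)
        assert effective_count(r, scope) == expected

    def test_count_prorated_in_block_scope(self):
        r = min_rule("w", "sex", "w", 36)
        assert effective_count(r, 143, total_n=143) == 36
        # block of 48 out of 143: ceil(36*48/143) = ceil(12.08) = 13
        assert effective_count(r, 48, total_n=143) == 13

    def test_partial_block_minimum_capped(self):
        r = min_rule("w", "sex", "w", 90, "percent")
        assert effective_count(r, 3, total_n=100) == 3  # capped at scope


class TestEvaluate:
    def test_maximum_enforced(self):
        """Sample of 6 with at most 2 male enrollees: the third male
        candidate is turned away, others admitted."""
        spec = QuotaConfigSpec(total_n=6, rules=(max_rule("male-max", "sex", "male", 2),))
        led = QuotaLedger(spec=spec)
        seq = ["male", "male", "male"] + ["female"] * 5
        decisions = [evaluate(sex_rec(i, s), led, spec) for i, s in enumerate(seq)]
        assert decisions[0].decision == decisions[1].decision == "admit"
        assert decisions[2].decision == "reject_maximum"
        assert decisions[2].rule_labels == ("male-max",)
        assert [d.decision for d in decisions[3:]] == ["admit"] * 4 + ["reject_full"]

    def test_empty_ledger_admits(self):
        spec = QuotaConfigSpec(total_n=4, rules=(min_rule("w", "sex", "woman", 2),))
        led = QuotaLedger(spec=spec)
        assert evaluate(sex_rec(0, "man"), led, spec).decision == "admit"

    def test_reserved_slots(self):
        """Total 8 with a minimum of 2 women: after 6 non-women the 7th
        non-woman is rejected (slots reserved), a woman is admitted."""
        spec = QuotaConfigSpec(total_n=8, rules=(min_rule("w", "sex", "woman", 2),))
        led = QuotaLedger(spec=spec)
        for i in range(6):
            assert evaluate(sex_rec(i, "man"), led, spec).decision == "admit"
        d = evaluate(sex_rec(6, "man"), led, spec)
        assert d.decision == "reject_reserved" and d.rule_labels == ("w",)
        assert evaluate(sex_rec(7, "woman"), led, spec).decision == "admit"

    def test_reserved_matches_brute_force_oracle(self):
        """Admit iff some completion of the remaining slots can still meet
        every minimum — checked by enumerating all category fillings."""
        spec = QuotaConfigSpec(
            total_n=6,
            rules=(min_rule("w", "sex", "woman", 2), min_rule("m", "sex", "man", 2)),
        )

        def oracle_admissible(counts, filled, candidate_sex):
            counts = dict(counts)
            counts[candidate_sex] += 1
            open_slots = spec.total_n - filled - 1
            for filling in itertools.product(["woman", "man", "other"], repeat=open_slots):
                c = dict(counts)
                for s in filling:
                    c[s] += 1
                if c["woman"] >= 2 and c["man"] >= 2:
                    return True
            return False

        rng = np.random.default_rng(42)
        for _ in range(25):
            led = QuotaLedger(spec=spec)
            counts = {"woman": 0, "man": 0, "other": 0}
            i = 0
            while not led.is_full and i < 30:
                s = str(rng.choice(["woman", "man", "other"]))
                expected = oracle_admissible(counts, len(led), s)
                got = evaluate(sex_rec(i, s), led, spec)
                assert (got.decision == "admit") == expected, (counts, s)
                if got.decision == "admit":
                    counts[s] += 1
                i += 1

    def test_missing_quota_field_is_error_not_rejection(self):
        spec = QuotaConfigSpec(total_n=4, rules=(min_rule("w", "sex", "woman", 2),))
        led = QuotaLedger(spec=spec)
        bad = make_record("x", "2024-01-01", {"sex": "", "area": "urban"}, SEX_SCHEMA)
        with pytest.raises(QuotaFieldError):
            evaluate(bad, led, spec)

    def test_exact_mode_credits_overlapping_minimums(self):
        """One rural woman satisfies both a woman-minimum and a rural-minimum;
        exact mode admits a non-target candidate the independent mode would
        turn away by double-reserving."""
        rules = (min_rule("w", "sex", "woman", 2), min_rule("r", "area", "rural", 2))
        indep = QuotaConfigSpec(total_n=4, rules=rules, reserve_mode="independent")
        exact = QuotaConfigSpec(total_n=4, rules=rules, reserve_mode="exact")
        cand = sex_rec(0, "man", "urban")
        assert evaluate(cand, QuotaLedger(spec=indep), indep).decision == "reject_reserved"
        led = QuotaLedger(spec=exact)
        assert evaluate(cand, led, exact).decision == "admit"
        # rural women can still complete both minimums
        for i in range(1, 3):
            assert evaluate(sex_rec(i, "woman", "rural"), led, exact).decision == "admit"
        assert evaluate(sex_rec(3, "man", "urban"), led, exact).decision == "admit"
        rows = {r.label: r for r in attainment(led, exact)}
        assert rows["w"].met and rows["r"].met


class TestReplayAndInvariants:
    def test_oversupplied_stream_meets_all_minimums(self, schema):
        spec = cessation_quota_spec()
        cands = category_candidates(600, seed=9, schema=schema)
        ledger, table, _ = replay(cands, spec)
        assert len(ledger) == 143
        assert all(row.met for row in table)
        assert min(row.achieved_n for row in table) >= 23

    def test_arrival_order_irrelevant_for_minimums(self, schema):
        spec = cessation_quota_spec()
        cands = category_candidates(600, seed=9, schema=schema)
        rng = np.random.default_rng(1)
        for _ in range(5):
            order = rng.permutation(len(cands))
            ledger, table, _ = replay([cands[i] for i in order], spec)
            assert len(ledger) == 143 and all(row.met for row in table)

    def test_unmet_minimum_warns_not_crashes(self, schema):
        """Zero members of a minimum's category in the stream: the slots stay
        reserved, the run completes, and the shortfall is reported."""
        spec = QuotaConfigSpec(
            total_n=20, rules=(min_rule("quit", "cpd_bin", "quit", 5),)
        )
        cands = [c for c in category_candidates(100, seed=3, schema=schema)
                 if c.norm_values["cpd_bin"] != "quit"][:30]
        with pytest.warns(UserWarning, match="unmet minimum"):
            ledger, table, _ = replay(cands, spec)
        assert len(ledger) == 15  # 5 slots stayed reserved for quitters
        assert not table[0].met

    def test_maximum_never_violated_along_the_way(self):
        spec = QuotaConfigSpec(
            total_n=30,
            rules=(max_rule("m", "sex", "man", 40, "percent"),
                   min_rule("w", "sex", "woman", 10)),
        )
        rng = np.random.default_rng(7)
        led = QuotaLedger(spec=spec)
        i = 0
        cap = effective_count(spec.rules[0], spec.total_n)
        while not led.is_full and i < 300:
            evaluate(sex_rec(i, str(rng.choice(["man", "woman", "other"]))), led, spec)
            assert led.count(spec.rules[0]) <= cap
            assert len(led) <= spec.total_n
            i += 1
        assert led.recount() == {r.label: led.count(r) for r in spec.rules}

    def test_percent_and_count_rules_equivalent(self, schema):
        """25% minimum of 143 and count-36 minimum produce the same
        decision sequence on the same stream."""
        cands = category_candidates(400, seed=5, schema=schema)
        base = tuple(
            min_rule(f"bin_{c}", "cpd_bin", c, 23) for c in CPD_CATEGORIES[:4]
        )
        spec_pct = QuotaConfigSpec(total_n=143, rules=base + (
            min_rule("quit", "cpd_bin", "quit", 25, "percent"),))
        spec_cnt = QuotaConfigSpec(total_n=143, rules=base + (
            min_rule("quit", "cpd_bin", "quit", 36),))
        assert effective_count(spec_pct.rules[-1], 143) == 36
        _, _, d1 = replay(cands, spec_pct)
        _, _, d2 = replay(cands, spec_cnt)
        assert [d.decision for d in d1] == [d.decision for d in d2]

    def test_block_size_total_n_equals_no_blocks(self, schema):
        cands = category_candidates(500, seed=13, schema=schema)
        plain = cessation_quota_spec()
        blocked = cessation_quota_spec(block_size=143)
        _, _, d1 = replay(cands, plain)
        _, _, d2 = replay(cands, blocked)
        assert [(d.record_id, d.decision) for d in d1] == [
            (d.record_id, d.decision) for d in d2
        ]

    def test_blocked_minimums_hold_per_completed_block(self):
        spec = QuotaConfigSpec(
            total_n=12, block_size=4,
            rules=(min_rule("w", "sex", "woman", 25, "percent"),),
        )
        rng = np.random.default_rng(21)
        led = QuotaLedger(spec=spec)
        i = 0
        while not led.is_full and i < 500:
            evaluate(sex_rec(i, str(rng.choice(["man", "man", "woman"]))), led, spec)
            i += 1
        assert len(led) == 12
        per_block = effective_count(spec.rules[0], 4, total_n=12)  # >= 1 woman
        for b in range(3):
            women = sum(
                1 for e in led.enrolled
                if e.block_index == b and e.categories["sex"] == "woman"
            )
            assert women >= per_block


class TestValidation:
    def test_infeasible_exclusive_minimums_rejected(self):
        spec = QuotaConfigSpec(
            total_n=4,
            rules=(min_rule("w", "sex", "woman", 3), min_rule("m", "sex", "man", 3)),
        )
        with pytest.raises(ConfigError, match="infeasible"):
            spec.validate()

    def test_overlapping_minimums_not_flagged(self):
        # woman-min and rural-min can share candidates: not provably infeasible
        spec = QuotaConfigSpec(
            total_n=4,
            rules=(min_rule("w", "sex", "woman", 3), min_rule("r", "area", "rural", 3)),
        )
        spec.validate()

    def test_bad_rule_parameters(self):
        with pytest.raises(ConfigError):
            QuotaRule("p", QuotaPredicate((("sex", "w"),)), "minimum", 120, "percent")
        with pytest.raises(ConfigError):
            QuotaRule("c", QuotaPredicate((("sex", "w"),)), "minimum", 2.5, "count")
        with pytest.raises(ConfigError):
            QuotaConfigSpec(total_n=5, block_size=9)
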