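# Methods

## Problem setting

Decentralized trials screen applicants through online surveys. Two failure
modes corrupt the resulting sample: repeat submissions (accidental, or
deliberate probing of eligibility criteria with mutated identifiers) and
drift of the enrolled sample away from required subgroup minimums.
`screenguard` implements rule-based duplicate detection on the screening
stream and quota-constrained admission at enrollment, plus a simulator that
generates labelled streams for validation.

## Duplicate model

**Normalization.** All matching is exact on canonical forms. Normalizers:
`text` = Unicode NFC + case-fold + trim + internal-whitespace collapse;
`email` = trim + case-fold; `phone` = strip non-digits, compare on the last
10 digits when more are present (drops country codes); `date` = ISO-8601
calendar date; `exact` = trim only. Blank raw values map to a MISSING
sentinel, and MISSING never equals MISSING — two blank optional fields are
not evidence of identity, which prevents mass false flags on sparsely
filled fields. Normalization is idempotent and total on strings. Whether a
production survey system compares raw or normalized values is generally
undocumented; we normalize and state it, since real submissions vary in
formatting ("(843) 555-0101" vs "8435550101") while denoting one person.

**Criteria.** A criteria set is a disjunction of conjunctive criteria (AND
within a criterion, OR across criteria) plus one shared window in days.
Records a, b are a duplicate pair iff some criterion matches on all its
fields (no side missing) and |date(a) − date(b)| ≤ window. Choices:

* The window is compared at **calendar-date resolution** in one configured
  study timezone, boundary **inclusive**. Day resolution matches how repeat
  submissions are reported ("same day"); inclusivity is our choice where
  the behaviour is otherwise unspecified, and is documented here.
* "6 months" ships as `window_days: 183`; calendar-month arithmetic is
  ambiguous and the window is a user setting anyway.
* No fuzzy matching (edit distance, phonetic codes): the detection rule is
  *identical canonical fields*. Fuzzy matching is an extension point, not a
  feature, because its false-positive behaviour needs study-specific
  calibration.

**Sets, originals, entries.** Duplicate sets are connected components
(size ≥ 2) of the pair graph — transitive closure, so A–B and B–C group
{A, B, C} even when A–C share nothing. Chained identifier mutation by one
person produces exactly such components (observed chains reach 13–15
submissions). The **original** is the earliest member by
(submitted_at, record_id) — the id breaks timestamp ties deterministically;
the remaining members are **duplicate entries**. Headline counts:
duplicate records = originals + entries; duplicate rate = 100 × duplicate
records / total screens.

**Streaming vs batch.** `check_incoming` flags each arriving record against
all prior records in the window and reports *every* match with its criterion
labels (staff see which identifiers were kept); the record then enters the
store regardless of the decision, so later submissions match the whole
chain. For any stream, the set of streaming-flagged records equals the set
of non-original members of the batch components (property-tested); batch
mode additionally uses criterion-key blocking (hash join on each
criterion's canonical value tuple) so it scales past quadratic pair
enumeration.

**Gap and field profiles.** Each duplicate entry is profiled against its
nearest *earlier* direct match (smallest day gap; ties resolve toward the
later submission): gap category — same_day (0), within_week (1–7),
within_month (8–31), over_month (≥ 32) — plus kept fields (fields of the
criteria that fired) and changed fields (identifier-role fields that
differ). These are descriptive inputs to a staff decision, not a fraud
verdict: same-day with nothing changed suggests an accidental
resubmission; same-day with names changed but contact details kept
suggests deliberate disguise. The field-profile categories are our
reconstruction of per-field flag breakdowns; published category definitions
for such tables are not available.

## Quota model

Rules are (predicate, bound, amount, kind): the predicate is a conjunction
of (field = category) conditions (nesting = multiple conditions), the bound
is a minimum or maximum, the amount a count or a percent.

**Effective counts.** Percent amounts resolve against the scope size with
ceiling for minimums and floor for maximums — a "25% minimum" must
guarantee at least that share (ceil(0.25 × 143) = 36). Counts pass through
unchanged at full-sample scope. Arithmetic uses exact rationals, so
floating-point edge cases cannot flip a rounding.

**Blocks.** With a block size b, rules are enforced within consecutive
blocks of b admissions: percent amounts resolve against b, count amounts
are pro-rated by b / total_n (same rounding), and the final partial block
uses ceiling-scaled minima capped at its size so a short block's quota
stays reachable. This makes block_size = total_n provably identical to the
no-blocks mode (property-tested). Per-block scoping is implemented exactly
as stated; the trade-off — a category rejected in an early full block must
wait for a later block — is inherent to blocked enforcement and is why
full-sample mode exists.

**Decision order.** For each candidate: error if a quota field is missing
(a data problem, never a rejection); `reject_full` if the sample (not the
block) is complete; `reject_maximum` if admitting would break any maximum
in the current scope — consequently no ledger state ever violates a
maximum; `reject_reserved` if admitting would leave fewer open slots than
the remaining minimum shortfalls require; else admit.

**Reserved slots with overlapping minimums.** When minimum predicates can
share candidates (e.g. a woman-minimum and a rural-minimum, with rural
women in the pool), two semantics ship:

* `independent` (default): shortfalls are summed. Correct for mutually
  exclusive predicates; over-reserves when predicates overlap (it books
  one future rural woman twice). Predictable and conservative.
* `exact`: computes the true minimum number of future admits covering all
  shortfalls. One admit may satisfy any *pairwise-compatible* subset of
  unmet rules (no shared field with conflicting values — for conjunctions
  of equality conditions pairwise compatibility implies joint
  satisfiability), so the cover is found by memoised exhaustive search over
  shortfall states, with a greedy fallback above 30 total shortfall units.

Production quota systems do not document overlap semantics; both modes are
ours and selectable per project.

**Feasibility.** Config validation rejects specs it can *prove* infeasible:
any set of pairwise mutually exclusive minimums whose effective counts
exceed a scope (full sample, block, or final partial block). Overlapping
minimums are never rejected — satisfiability then depends on the candidate
pool.

**Check time.** `check_time: screening` evaluates at survey completion;
`enrollment` defers the same evaluation to staff confirmation (the ledger
records which mode produced each decision). The engine is identical; only
the stream replayed differs. Survey-platform hook timing is out of scope.

## Simulator

`generate_stream` emulates the three populations a remote screener sees.
Identities arrive with exponential inter-arrival gaps (default mean 0.25
days ≈ a steady online campaign). Each identity is honest (1 submission),
a mistake resubmitter (2 identical submissions, long gaps) or a fraudster
(2–15 submissions, uniform; the high end mirrors the worst observed repeat
submitters). Defaults: 10% fraud, 8% mistake identities — unstated in any
source; chosen as a plausible mid-range for paid online studies. Fraud
resubmission gaps are same-day-heavy (default mass 0.70 at 0 days,
mirroring reported same-day shares above 70% in an adolescent campaign);
mistake gaps skew to weeks–months. Per resubmission a fraudster mutates
each identifier field independently (defaults: names 0.4, email/phone 0.3).

Identifiers are fabricated from fixed name pools, `@example.org` emails and
555-prefix phone numbers; collision checking guarantees global uniqueness of
name pairs, emails and phones across identities *and* across mutation draws
(a mutated value never reverts and never recreates another identity), so
honest-only streams are provably flag-free. Everything is driven by one
`numpy` generator seeded from `SimParams.seed`; output is byte-identical
across runs.

**What a green test establishes — and what it does not.** The simulator
yields exact-copy or field-mutating resubmissions with clean timestamps and
distinct identities. Real streams contain typos, shared household phones,
legitimately re-screening applicants, bots, and coordinated fraud rings —
none of which are modelled (IP/device fingerprinting is explicitly out of
scope). Green detection tests establish the engine's correctness under its
own matching semantics: recall is 1.0 exactly when every fraudster keeps at
least one full criterion intact between submissions, and provably 0 for
fraudsters who mutate every criterion field every time. That blind spot is a
property of exact-match screening itself, not of this implementation. With
default parameters the simulated duplicate share (~58% of records) is
higher than the ~25–31% reported in real adult campaigns, because the
uniform 2–15 resubmission range is heavier-tailed than typical observed
behaviour; the share is a consequence of the stated defaults, not a
calibration target, and no test depends on it.

## Reporting conventions

Duplicate rate: 2 decimals. Attainment percents: integers of the final
sample size. Both round half away from zero (implemented with
`decimal`/`Fraction`, not binary floats). Every summary number is copied
from the underlying result or recomputable from the ledger (round-trip
audited in tests).

## Known limitations

* Exact matching only; see the blind-spot discussion above.
* One time window for the whole criteria set (per-criterion windows are not
  supported, matching the deployed tools this engine mirrors).
* The `independent` reserve mode can defer candidates unnecessarily when
  minimum predicates overlap; use `exact` when overlap matters.
* Quota control is admission logic only — no power analysis, sample-size
  justification or randomization/arm allocation.
* The simulator does not model bots, IP/device signals or survey-timing
  features; those are extension points for composite fraud scores.
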