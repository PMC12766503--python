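"""Summary tables: duplicate-detection results and quota attainment.

Every number here is copied or computed straight from the underlying
result/ledger (round-trip auditable); rounding follows common reporting
precision — the duplicate rate to 2 decimals, attainment percents to whole
integers, half away from zero in both cases.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .dedup import GAP_CATEGORIES, DedupResult
from .quota import AttainmentRow, QuotaConfigSpec, QuotaLedger, attainment

__all__ = ["DedupSummary", "summarize_dedup", "summarize_quota", "rate_pct"]


def rate_pct(numer: int, denom: int, decimals: int = 2) -> float:
    """100 * numer / denom rounded half away from zero to ``decimals``."""
    if denom == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(numer) / Decimal(denom)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class DedupSummary:
    """One row of a results table for a screening campaign."""

    total_screens: int
    n_duplicate_records: int
    duplicate_rate_pct: float
    n_original_duplicates: int
    n_duplicate_entries: int
    max_set_size: int
    gap_counts: dict[str, int] = field(default_factory=dict)
    gap_pcts: dict[str, float] = field(default_factory=dict)
    field_profile_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        flat = {
            "total_screens": self.total_screens,
            "n_duplicate_records": self.n_duplicate_records,
            "duplicate_rate_pct": self.duplicate_rate_pct,
            "n_original_duplicates": self.n_original_duplicates,
            "n_duplicate_entries": self.n_duplicate_entries,
            "max_set_size": self.max_set_size,
        }
        for g in GAP_CATEGORIES:
            flat[f"gap_{g}_n"] = self.gap_counts.get(g, 0)
            flat[f"gap_{g}_pct"] = self.gap_pcts.get(g, 0.0)
        return pd.DataFrame([flat])


def summarize_dedup(result: DedupResult) -> DedupSummary:
    """Roll a batch dedup result up into the reporting summary.

    Counts are copied, never recomputed differently; the rate is
    100 x duplicate records / total screens at 2 decimals.
    """
    gap_counts = {g: int(result.gap_counts.get(g, 0)) for g in GAP_CATEGORIES}
    n_entries = result.n_duplicate_entries
    gap_pcts = {g: rate_pct(gap_counts[g], n_entries) for g in GAP_CATEGORIES}
    return DedupSummary(
        total_screens=result.total_records,
        n_duplicate_records=result.n_duplicate_records,
        duplicate_rate_pct=rate_pct(result.n_duplicate_records, result.total_records),
        n_original_duplicates=result.n_original_duplicates,
        n_duplicate_entries=n_entries,
        max_set_size=result.max_set_size,
        gap_counts=gap_counts,
        gap_pcts=gap_pcts,
        field_profile_counts=dict(result.field_profile_counts),
    )


def summarize_quota(
    ledger: QuotaLedger, spec: QuotaConfigSpec
) -> pd.DataFrame:
    """Attainment table: rule label, bound, effective target, achieved count
    and achieved percent of the final sample (integer, half away from zero)."""
    rows: list[AttainmentRow] = attainment(ledger, spec)
    return pd.DataFrame(
        [
            {
                "rule": r.label,
                "bound": r.bound,
                "target": r.target,
                "achieved_n": r.achieved_n,
                "achieved_pct": r.achieved_pct,
                "met": r.met,
            }
            for r in rows
        ]
    )
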