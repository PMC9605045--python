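"""Category summary tables and PCR pooling.

The summary mirrors the study's reporting shape: per category, total
candidates (a), duplicates found in multiple ascertainment sets (b),
unique calls (a-b), and the post-inspection split into shared / NP /
other, with "% retained" (shared / unique, integer percent) and the
shared/NP/other fractions of the grand total of unique calls (one
decimal).  All displayed percentages round half-up at their displayed
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

import pandas as pd

#: Canonical column order of the ten informative categories.
CATEGORY_COLUMNS = ("CM", "CO", "CS", "MO", "MS", "OS", "CMO", "CMS", "COS", "MOS")
THREE_GENOME_CATEGORIES = ("CMO", "CMS", "COS", "MOS")


class ReportError(ValueError):
    pass


def percent_half_up(numerator: int, denominator: int, decimals: int = 0) -> Optional[float]:
    """Percentage rounded half-up at the displayed precision; None for 0/0."""
    if denominator == 0:
        if numerator:
            raise ReportError("nonzero numerator with zero denominator")
        return None
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
    return float(value)


def _fmt(value: Optional[float], decimals: int) -> str:
    return "—" if value is None else f"{value:.{decimals}f}"


@dataclass
class CategoryCounts:
    total_candidates: int = 0
    duplicates: int = 0
    post_shared: int = 0
    post_np: int = 0
    post_other: int = 0

    @property
    def unique_calls(self) -> int:
        return self.total_candidates - self.duplicates

    @property
    def pct_retained(self) -> Optional[float]:
        return percent_half_up(self.post_shared, self.unique_calls, 0)

    def validate(self) -> None:
        if min(self.total_candidates, self.duplicates, self.post_shared,
               self.post_np, self.post_other) < 0:
            raise ReportError("counts must be non-negative")
        if self.duplicates > self.total_candidates:
            raise ReportError("duplicates exceed total candidates")
        if self.post_shared + self.post_np + self.post_other != self.unique_calls:
            raise ReportError(
                f"inspection outcomes ({self.post_shared}+{self.post_np}+{self.post_other}) "
                f"do not account for all {self.unique_calls} unique calls"
            )


@dataclass
class CategorySummary:
    per_category: dict[str, CategoryCounts] = field(default_factory=dict)

    @property
    def categories(self) -> list[str]:
        known = [c for c in CATEGORY_COLUMNS if c in self.per_category]
        extra = sorted(set(self.per_category) - set(CATEGORY_COLUMNS))
        return known + extra

    def _total(self, attr: str) -> int:
        return sum(getattr(c, attr) for c in self.per_category.values())

    @property
    def total_unique_calls(self) -> int:
        return self._total("unique_calls")

    @property
    def total_shared(self) -> int:
        return self._total("post_shared")

    @property
    def total_np(self) -> int:
        return self._total("post_np")

    @property
    def total_other(self) -> int:
        return self._total("post_other")

    @property
    def pct_shared(self) -> Optional[float]:
        return percent_half_up(self.total_shared, self.total_unique_calls, 1)

    @property
    def pct_np(self) -> Optional[float]:
        return percent_half_up(self.total_np, self.total_unique_calls, 1)

    @property
    def pct_other(self) -> Optional[float]:
        return percent_half_up(self.total_other, self.total_unique_calls, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for cat in self.categories:
            c = self.per_category[cat]
            rows[cat] = {
                "total_candidates": c.total_candidates,
                "in_multiple_sets": c.duplicates,
                "unique_calls": c.unique_calls,
                "post_align_shared": c.post_shared,
                "post_align_np": c.post_np,
                "post_align_other": c.post_other,
                "pct_retained": _fmt(c.pct_retained, 0),
            }
        return pd.DataFrame(rows).T

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        total = {
            "total_candidates": self._total("total_candidates"),
            "in_multiple_sets": self._total("duplicates"),
            "unique_calls": self.total_unique_calls,
            "post_align_shared": self.total_shared,
            "post_align_np": self.total_np,
            "post_align_other": self.total_other,
            "pct_retained": _fmt(percent_half_up(self.total_shared, self.total_unique_calls, 0), 0),
        }
        df.loc["Total"] = total
        df.to_csv(path, sep="\t", index_label="category")

    def to_dict(self) -> dict:
        return {
            "per_category": {
                cat: vars(self.per_category[cat]) | {"unique_calls": self.per_category[cat].unique_calls}
                for cat in self.categories
            },
            "total_unique_calls": self.total_unique_calls,
            "total_shared": self.total_shared,
            "total_np": self.total_np,
            "total_other": self.total_other,
            "pct_shared": self.pct_shared,
            "pct_np": self.pct_np,
            "pct_other": self.pct_other,
        }


def summarize_counts(
    total_candidates: Mapping[str, int],
    duplicates: Mapping[str, int],
    post_shared: Mapping[str, int],
    post_np: Mapping[str, int],
    post_other: Mapping[str, int],
) -> CategorySummary:
    """Build and validate a summary from per-category counts."""
    summary = CategorySummary()
    for cat in total_candidates:
        counts = CategoryCounts(
            total_candidates=total_candidates[cat],
            duplicates=duplicates.get(cat, 0),
            post_shared=post_shared.get(cat, 0),
            post_np=post_np.get(cat, 0),
            post_other=post_other.get(cat, 0),
        )
        counts.validate()
        summary.per_category[cat] = counts
    return summary


def summarize(records: Iterable, duplicates: Optional[Mapping[str, int]] = None) -> CategorySummary:
    """Summarise unique candidate records carrying inspection outcomes.

    ``records`` need ``.category`` and ``.outcome.verdict``; ``duplicates``
    is the per-category duplicate count removed by deduplication (each
    duplicate also counts toward that category's total candidates).
    """
    duplicates = dict(duplicates or {})
    shared: dict[str, int] = {}
    np_: dict[str, int] = {}
    other: dict[str, int] = {}
    for rec in records:
        outcome = getattr(rec, "outcome", None)
        if outcome is None or getattr(outcome, "verdict", None) is None:
            raise ReportError(f"record {getattr(rec, 'locus_id', rec)!r} has no inspection outcome")
        bucket = {"shared": shared, "near_parallel": np_, "other": other}[outcome.verdict]
        bucket[rec.category] = bucket.get(rec.category, 0) + 1
    cats = set(shared) | set(np_) | set(other) | set(duplicates)
    totals = {
        cat: shared.get(cat, 0) + np_.get(cat, 0) + other.get(cat, 0) + duplicates.get(cat, 0)
        for cat in cats
    }
    return summarize_counts(totals, duplicates, shared, np_, other)


@dataclass
class PcrSummary:
    """Pooled PCR confirmation for the three-of-four-genome categories."""

    per_category: dict[str, tuple[int, int, int]]  # cat -> (post_shared, analyzed, confirmed)

    @property
    def total_analyzed(self) -> int:
        return sum(a for _, a, _ in self.per_category.values())

    @property
    def total_confirmed(self) -> int:
        return sum(c for _, _, c in self.per_category.values())

    @property
    def pooled_pct(self) -> Optional[float]:
        return percent_half_up(self.total_confirmed, self.total_analyzed, 0)

    def pct_for(self, category: str) -> Optional[float]:
        _, analyzed, confirmed = self.per_category[category]
        return percent_half_up(confirmed, analyzed, 0)


def pool_pcr(
    per_category: Mapping[str, tuple[int, int]],
    post_shared: Optional[Mapping[str, int]] = None,
) -> PcrSummary:
    """Pool per-category (analyzed, confirmed) PCR counts.

    Validates confirmed <= analyzed (<= post_shared when provided); the
    pooled rate is sum(confirmed) / sum(analyzed) rendered as an integer
    percentage, undefined ("-") when nothing was analyzed.
    """
    table: dict[str, tuple[int, int, int]] = {}
    for cat, (analyzed, confirmed) in per_category.items():
        if analyzed < 0 or confirmed < 0:
            raise ReportError("PCR counts must be non-negative")
        if confirmed > analyzed:
            raise ReportError(f"{cat}: confirmed ({confirmed}) exceeds analyzed ({analyzed})")
        shared = post_shared.get(cat, analyzed) if post_shared else analyzed
        if analyzed > shared:
            raise ReportError(f"{cat}: analyzed ({analyzed}) exceeds post-align shared ({shared})")
        table[cat] = (shared, analyzed, confirmed)
    return PcrSummary(per_category=table)
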