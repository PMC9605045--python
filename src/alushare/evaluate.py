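"""Comparing pipeline output against simulator ground truth."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .pipeline import CohortResult
from .presence import CandidateRecord
from .simulate import ABSENT_LABEL, TruthRecord

#: Expected inspection verdict for each simulated event type.
EXPECTED_VERDICT = {
    "clean_shared": "shared",
    "near_parallel": "near_parallel",
    "n_run": "other",
    "truncated": "other",
    "present_in_all": "other",
}


def truth_by_contig(truth: Sequence[TruthRecord]) -> dict[str, TruthRecord]:
    return {t.locus_id: t for t in truth}


def contig_of(record: CandidateRecord) -> str:
    return record.locus_id.rsplit("|", 1)[0]


@dataclass
class RecoveryReport:
    n_truth: int  # loci with at least one ingroup carrier
    n_recovered: int  # truth loci with a unique call
    n_category_match: int
    n_pattern_match: int
    verdict_counts: dict[tuple[str, str], int]  # (event_type, verdict or "missing")
    clean_as_np: int

    @property
    def category_accuracy(self) -> float:
        return self.n_category_match / self.n_truth if self.n_truth else 1.0

    @property
    def diagonal_fraction(self) -> float:
        total = sum(self.verdict_counts.values())
        good = sum(
            n for (event, verdict), n in self.verdict_counts.items()
            if EXPECTED_VERDICT.get(event) == verdict
        )
        return good / total if total else 1.0


def compare_to_truth(result: CohortResult, truth: Sequence[TruthRecord]) -> RecoveryReport:
    """Join unique calls to the truth table and score recovery.

    Only loci with at least one ingroup carrier count: outgroup-private
    loci are never ascertained and are not part of the denominator.
    """
    by_contig = truth_by_contig(truth)
    unique_by_contig: dict[str, CandidateRecord] = {}
    for rec in result.dedupe.unique:
        unique_by_contig[contig_of(rec)] = rec
    n_truth = n_recovered = n_cat = n_pat = clean_np = 0
    verdicts: dict[tuple[str, str], int] = {}
    for t in by_contig.values():
        if t.true_category == ABSENT_LABEL or not any(t.true_pattern):
            continue
        n_truth += 1
        rec = unique_by_contig.get(t.locus_id)
        if rec is None:
            verdicts[(t.event_type, "missing")] = verdicts.get((t.event_type, "missing"), 0) + 1
            continue
        n_recovered += 1
        if rec.category == t.true_category:
            n_cat += 1
        if rec.pattern.present == t.true_pattern:
            n_pat += 1
        verdict = rec.outcome.verdict
        verdicts[(t.event_type, verdict)] = verdicts.get((t.event_type, verdict), 0) + 1
        if t.event_type == "clean_shared" and verdict == "near_parallel":
            clean_np += 1
    return RecoveryReport(
        n_truth=n_truth,
        n_recovered=n_recovered,
        n_category_match=n_cat,
        n_pattern_match=n_pat,
        verdict_counts=verdicts,
        clean_as_np=clean_np,
    )


def length_filter_pass_fraction(result: CohortResult) -> float:
    """Fraction of aligned candidates whose alignment passed the length filter."""
    counts = result.status_counts()
    aligned = sum(counts.get(s, 0) for s in ("scored", "no_presence", "length_filtered"))
    passed = counts.get("scored", 0) + counts.get("no_presence", 0)
    return passed / aligned if aligned else 1.0
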