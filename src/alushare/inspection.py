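"""Automated post-alignment inspection.

The source workflow validated shared insertions by eye: same genomic
position, matching target-site duplications (TSDs) and general sequence
congruence, with failures classed as near-parallel insertions (NP) or
"Other" (Ns in the sequence, truncated rows, or Alu fragments present in
all four genomes).  This module operationalises that judgement with
numeric knobs:

* carriers agree in position when their Alu start columns differ by at
  most ``np_offset_threshold`` (10 columns);
* a TSD is the longest duplicated word (within a mismatch allowance)
  whose left copy ends at the Alu 5' boundary and whose right copy begins
  within a small window around the estimated A-tail end;
* carrier TSDs are *compatible* when, allowing a +-3 bp registration
  shift, the copies agree to within ``tsd_compat_max_mismatch``
  substitutions -- lenient enough for ~20 my of independent decay of two
  identical-by-descent copies, far below the ~75% mismatch of two random
  target sites;
* a row is N-contaminated at >= 5% Ns, truncated below 80% of the
  expected flank span, and a nominally absent row "retains the Alu" when
  a local alignment of the consensus against it scores like a >= 40 bp
  well-matched fragment.

NP calls require positional disagreement *and* non-matching TSD evidence;
carriers whose TSD evidence is simply irrecoverable yield
other/tsd_unresolved rather than a spurious NP call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .consensus import ALUS_CONSENSUS, DEFAULT_LINEAGE_MAP, SUBFAMILY_LIBRARY
from .orthologs import FourWayAlignment
from .presence import PresenceCall, PresencePattern
from .scoring import DEFAULT_SCHEME, ScoringScheme, fragment_aligner
from .seqs import degap, n_fraction
from .simulate import GENOMES

OTHER_REASONS = ("has_N", "truncated", "present_in_all", "tsd_unresolved", "none")


class InspectionError(ValueError):
    pass


@dataclass(frozen=True)
class TsdCall:
    """A detected target-site duplication on an unaligned carrier sequence."""

    left_copy_span: tuple[int, int]
    right_copy_span: tuple[int, int]
    sequence: str
    mismatches: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class InspectionConfig:
    np_offset_threshold: int = 10  # alignment columns
    n_fraction_threshold: float = 0.05
    min_row_fraction: float = 0.8  # of the expected 1200 bp flank span
    expected_flank_total: int = 1200
    tsd_min_len: int = 6
    tsd_max_len: int = 25
    tsd_max_mismatch: int = 2  # within-carrier copy-vs-copy allowance
    tsd_slack: int = 5  # window half-width around the estimated A-tail end
    tsd_compat_max_mismatch: int = 3  # cross-carrier allowance
    tsd_compat_max_shift: int = 3
    fragment_min_score: float = 40.0


DEFAULT_INSPECTION = InspectionConfig()


@dataclass
class InspectionOutcome:
    verdict: str  # "shared" | "near_parallel" | "other"
    other_reason: str = "none"
    insertion_columns: Mapping[str, int] = field(default_factory=dict)
    tsd_calls: Mapping[str, Optional[TsdCall]] = field(default_factory=dict)
    subfamilies: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    precise_parallel_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if (self.verdict == "other") != (self.other_reason != "none"):
            raise ValueError("verdict=other iff other_reason != none")


def estimate_atail_end(seq: str, start: int, max_nonA_per: int = 10, search: int = 7) -> int:
    """End (exclusive) of the poly-A tail beginning near ``start``.

    The tail is the longest A-run allowing scattered non-A bases (at most
    one per ``max_nonA_per`` tail bases, never two in a row), starting at
    the first A within ``search`` bp of ``start`` (the located consensus
    end can overshoot the true Alu terminus by a base or two).  The run
    ends at its last A, so trailing non-A bases are never included.
    Returns ``start`` when no tail is found.
    """
    best = start
    for s0 in range(start, min(start + search, len(seq))):
        if seq[s0] != "A":
            continue
        used = 0
        end = s0 + 1
        prev_nonA = False
        for i in range(s0, len(seq)):
            if seq[i] == "A":
                end = i + 1
                prev_nonA = False
            else:
                if prev_nonA or used + 1 > 1 + (i - s0) // max_nonA_per:
                    break
                used += 1
                prev_nonA = True
        best = max(best, end)
    return best


def detect_tsd(
    carrier_seq: str,
    alu_span: tuple[int, int],
    min_len: int = 6,
    max_len: int = 25,
    max_mismatch: int = 1,
    slack: int = 5,
    tail_backtrack: int = 16,
    atail_end: Optional[int] = None,
) -> Optional[TsdCall]:
    """Find the target-site duplication flanking an insertion.

    Candidate words have their left copy ending exactly at the Alu 5'
    boundary (``alu_span[0]``) and their right copy beginning in the window
    ``[atail_end - slack - tail_backtrack, atail_end + slack]`` around the
    estimated A-tail end: the backtrack allows for TSDs that begin with
    adenines, which the A-run estimator absorbs into the tail.  Among words
    with at most ``max_mismatch`` substitutions between the copies, the
    longest wins; ties go to fewer mismatches, then to the leftmost
    right-copy start.
    """
    start, end = alu_span
    if atail_end is None:
        atail_end = estimate_atail_end(carrier_seq, end)
    best: Optional[tuple[tuple[int, int, int], TsdCall]] = None
    lo = max(end, atail_end - slack - tail_backtrack)
    hi = min(len(carrier_seq), atail_end + slack + 1)
    for s in range(lo, hi):
        for length in range(min_len, max_len + 1):
            if length > start or s + length > len(carrier_seq):
                continue
            left = carrier_seq[start - length : start]
            right = carrier_seq[s : s + length]
            mism = sum(a != b for a, b in zip(left, right))
            if mism > max_mismatch:
                continue
            key = (-length, mism, s)
            if best is None or key < best[0]:
                best = (key, TsdCall((start - length, start), (s, s + length), left, mism))
    return best[1] if best else None


def tsd_mismatches(call_a: TsdCall, call_b: TsdCall, max_shift: int = 3) -> tuple[int, int]:
    """Best (mismatches, overlap) between two TSD words, right-aligned with
    a small registration shift tolerance.

    Both words end at their carrier's Alu 5' boundary, so they are compared
    suffix-against-suffix; shifting absorbs boundary-location wobble of a
    base or two between carriers.
    """
    w1, w2 = call_a.sequence, call_b.sequence
    best = (len(w1) + len(w2), 0)
    for shift in range(-max_shift, max_shift + 1):
        # compare w1[-1 - i] against w2[-1 - i - shift]
        i_lo = max(0, -shift)
        i_hi = min(len(w1) - 1, len(w2) - 1 - shift)
        overlap = i_hi - i_lo + 1
        if overlap < 5:
            continue
        mism = sum(
            w1[len(w1) - 1 - i] != w2[len(w2) - 1 - i - shift]
            for i in range(i_lo, i_hi + 1)
        )
        if (mism, -overlap) < (best[0], -best[1]):
            best = (mism, overlap)
    return best


def assign_subfamily(
    alu_seq: str,
    library: Mapping[str, str] = SUBFAMILY_LIBRARY,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    threshold_fraction: float = 0.5,
) -> tuple[str, float]:
    """Best-scoring subfamily for an Alu body, with percent divergence.

    Divergence = mismatches / aligned columns.  Ties break alphabetically.
    Returns ("unclassified", nan) when no library member reaches the
    presence threshold.
    """
    if not library:
        raise ValueError("subfamily library must not be empty")
    if not alu_seq:
        return ("unclassified", math.nan)
    aligner = scheme.to_aligner()
    best_name, best_score, best_div = None, -math.inf, math.nan
    for name in sorted(library):
        member = library[name]
        aln = aligner.align(member, alu_seq)[0]
        if aln.score > best_score:
            counts = aln.counts()
            aligned = counts.identities + counts.mismatches
            best_name = name
            best_score = aln.score
            best_div = 100.0 * counts.mismatches / aligned if aligned else math.nan
    assert best_name is not None
    member = library[best_name]
    if best_score < threshold_fraction * scheme.max_score(len(member)):
        return ("unclassified", math.nan)
    return (best_name, best_div)


def flag_precise_parallel(
    outcome: InspectionOutcome,
    lineage_map: Mapping[str, str] = DEFAULT_LINEAGE_MAP,
) -> Optional[bool]:
    """Flag a validated shared insertion whose carriers' subfamilies belong
    to different subfamily lineages (probable precise parallel insertion).

    Same-lineage differences (e.g. two Ta15-derived calls) do not flag;
    any unclassified carrier makes the flag indeterminate (None).
    """
    if outcome.verdict != "shared":
        return None
    calls = [name for name, _ in outcome.subfamilies.values()]
    if not calls:
        return None
    if any(name == "unclassified" for name in calls):
        return None
    lineages = {lineage_map.get(name, name) for name in calls}
    return len(lineages) > 1


def classify_inspection(
    alignment: FourWayAlignment,
    pattern: PresencePattern,
    calls: Mapping[str, PresenceCall],
    config: InspectionConfig = DEFAULT_INSPECTION,
    consensus: str = ALUS_CONSENSUS,
    library: Mapping[str, str] = SUBFAMILY_LIBRARY,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    expected_genomes: Sequence[str] = GENOMES,
) -> InspectionOutcome:
    """Classify one aligned candidate as shared, near-parallel or other."""
    rows = alignment.rows
    carriers = pattern.carriers
    if any(g not in rows for g in carriers):
        raise InspectionError("pattern names carriers that have no alignment row")

    for g in rows:
        if n_fraction(rows[g]) >= config.n_fraction_threshold:
            return InspectionOutcome(verdict="other", other_reason="has_N")

    min_len = config.min_row_fraction * config.expected_flank_total
    for g in expected_genomes:
        if g not in rows or len(degap(rows[g])) < min_len:
            return InspectionOutcome(verdict="other", other_reason="truncated")

    frag = fragment_aligner()
    for g in expected_genomes:
        if g in carriers:
            continue
        if frag.score(consensus, degap(rows[g])) >= config.fragment_min_score:
            return InspectionOutcome(verdict="other", other_reason="present_in_all")

    columns: dict[str, int] = {}
    positions: dict[str, int] = {}
    tsds: dict[str, Optional[TsdCall]] = {}
    for g in carriers:
        call = calls[g]
        if call.row_start is None or call.row_end is None:
            raise InspectionError(f"carrier {g} has no located Alu span")
        seq = degap(rows[g])
        columns[g] = alignment.column_of(g, call.row_start)
        positions[g] = call.row_start
        tsds[g] = detect_tsd(
            seq,
            (call.row_start, call.row_end),
            min_len=config.tsd_min_len,
            max_len=config.tsd_max_len,
            max_mismatch=config.tsd_max_mismatch,
            slack=config.tsd_slack,
        )

    pairs = [(a, b) for i, a in enumerate(carriers) for b in carriers[i + 1 :]]
    def compatible(a: str, b: str) -> Optional[bool]:
        if tsds[a] is None or tsds[b] is None:
            return None
        mism, overlap = tsd_mismatches(tsds[a], tsds[b], config.tsd_compat_max_shift)
        if overlap < 5:
            return None
        return mism <= config.tsd_compat_max_mismatch

    # Positional agreement is judged in unaligned row coordinates (the rows
    # share the projected-region frame): the mismatch-free scoring scheme
    # lets the aligner stack two near-parallel Alus into the same columns,
    # so alignment columns hide exactly the offsets this test looks for.
    for a, b in pairs:
        if abs(positions[a] - positions[b]) > config.np_offset_threshold and compatible(a, b) is not True:
            out = InspectionOutcome(
                verdict="near_parallel", insertion_columns=columns, tsd_calls=tsds,
            )
            out.subfamilies = _subfamilies(rows, calls, carriers, library, scheme)
            return out

    positions_agree = all(
        abs(positions[a] - positions[b]) <= config.np_offset_threshold for a, b in pairs
    )
    tsds_ok = all(tsds[g] is not None for g in carriers)
    compat_ok = all(compatible(a, b) is True for a, b in pairs)
    if positions_agree and tsds_ok and compat_ok:
        subfams = _subfamilies(rows, calls, carriers, library, scheme)
        out = InspectionOutcome(
            verdict="shared", insertion_columns=columns, tsd_calls=tsds, subfamilies=subfams,
        )
        out.precise_parallel_flag = flag_precise_parallel(out)
        return out
    return InspectionOutcome(
        verdict="other", other_reason="tsd_unresolved",
        insertion_columns=columns, tsd_calls=tsds,
    )


def _subfamilies(rows, calls, carriers, library, scheme) -> dict[str, tuple[str, float]]:
    out = {}
    for g in carriers:
        call = calls[g]
        seq = degap(rows[g])[call.row_start : call.row_end]
        out[g] = assign_subfamily(seq, library, scheme)
    return out
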