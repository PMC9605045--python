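"""Consensus-based presence scoring, category assignment and deduplication.

Each alignment row is de-gapped and scored by globally aligning the AluS
consensus (as the aligner's target, so row overhangs cost almost nothing)
against it under the presence scheme.  A row carries the insertion when its
score reaches ``threshold_fraction`` (default 0.5) of the maximum attainable
score, 1.3 x consensus length; a clean Alu scores within a few points of the
maximum while a flank-only row scores far below half under the heavy
internal gap penalties.  The 4-bit presence vector over (capuchin, marmoset,
owl monkey, squirrel monkey) maps to one of the fifteen category labels
CMOS ... S; the all-absent vector is invalid for a candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .consensus import ALUS_CONSENSUS
from .scoring import DEFAULT_SCHEME, ScoringScheme, locator_aligner
from .seqs import degap
from .simulate import CATEGORY_LABELS, GENOMES, GENOME_LETTERS

DEFAULT_THRESHOLD_FRACTION = 0.5
DEFAULT_OVERLAP_TOLERANCE = 50

#: Table-2 ascertainment sets: the ten informative categories, each listing
#: its member genomes in C,M,O,S order; sets are numbered 1-24 in this order.
_SET_CATEGORIES = ("CM", "CO", "CS", "MO", "MS", "OS", "CMO", "CMS", "COS", "MOS")
ASCERTAINMENT_SETS: dict[tuple[str, str], int] = {}
_n = 0
for _cat in _SET_CATEGORIES:
    for _letter in _cat:
        _n += 1
        ASCERTAINMENT_SETS[(_cat, GENOMES[GENOME_LETTERS.index(_letter)])] = _n
del _n, _cat, _letter


class CategoryError(ValueError):
    pass


@dataclass(frozen=True)
class PresenceCall:
    """Score and verdict for one row, plus the located Alu span."""

    score: float
    present: bool
    row_start: Optional[int] = None  # Alu span in de-gapped row coordinates
    row_end: Optional[int] = None


@dataclass(frozen=True)
class PresencePattern:
    """Ordered presence 4-tuple in (C, M, O, S) genome order."""

    present: tuple[bool, bool, bool, bool]
    per_genome_score: Mapping[str, float] = field(default_factory=dict)

    @property
    def carriers(self) -> tuple[str, ...]:
        return tuple(g for g, p in zip(GENOMES, self.present) if p)


def score_alu_presence(
    row: str,
    consensus: str = ALUS_CONSENSUS,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> PresenceCall:
    """Score one (possibly gapped) alignment row for Alu presence.

    The score is the global alignment score of the consensus against the
    de-gapped row under the scheme; presence requires
    ``score >= threshold_fraction * 1.3 * len(consensus)``.  The reported
    Alu span comes from a sharper local locator alignment because the
    presence scheme's optimum is positionally degenerate (mismatches cost
    nothing and row overhangs extend freely).
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    seq = degap(row)
    if not seq:
        return PresenceCall(score=-math.inf, present=False)
    aligner = scheme.to_aligner()
    score = aligner.score(consensus, seq)
    present = score >= threshold_fraction * scheme.max_score(len(consensus))
    row_start = row_end = None
    if present:
        loc = locator_aligner().align(consensus, seq)[0]
        q_blocks = loc.aligned[1]
        row_start = int(q_blocks[0][0])
        row_end = int(q_blocks[-1][1])
    return PresenceCall(score=score, present=present, row_start=row_start, row_end=row_end)


def assign_category(pattern: PresencePattern | Sequence[bool]) -> str:
    """Map a presence vector to its Table-1 label (letters in C,M,O,S order)."""
    present = pattern.present if isinstance(pattern, PresencePattern) else tuple(pattern)
    if len(present) != 4:
        raise CategoryError("presence pattern must have exactly four entries")
    if not any(present):
        raise CategoryError("no insertion detected: the all-absent pattern is invalid")
    label = "".join(letter for letter, p in zip(GENOME_LETTERS, present) if p)
    assert label in CATEGORY_LABELS
    return label


def set_number(category: str, ascertainment_genome: str) -> Optional[int]:
    """Table-2 set number (1-24) for a category x ascertainment pairing."""
    return ASCERTAINMENT_SETS.get((category, ascertainment_genome))


@dataclass
class CandidateRecord:
    """One scored candidate insertion from one ascertainment genome."""

    locus_id: str
    ascertainment_genome: str
    category: str
    pattern: PresencePattern
    #: carrier genome -> (contig, insertion start in that genome's coordinates)
    coordinates: Mapping[str, tuple[str, int]]
    ascertainment_set: Optional[int] = None
    alignment: object = None
    outcome: object = None

    def __post_init__(self) -> None:
        missing = [g for g in self.pattern.carriers if g not in self.coordinates]
        if missing:
            raise ValueError(f"coordinates missing for present genomes: {missing}")
        if self.ascertainment_set is None:
            self.ascertainment_set = set_number(self.category, self.ascertainment_genome)


@dataclass
class DedupeResult:
    unique: list[CandidateRecord]
    duplicates_per_category: dict[str, int]
    groups: list[list[CandidateRecord]]

    @property
    def duplicate_count(self) -> int:
        return sum(self.duplicates_per_category.values())


def _reference_coordinate(rec: CandidateRecord) -> tuple[str, str, int]:
    """Project a record to its reference genome: the earliest carrier in
    C,M,O,S order (the ascertainment genome of the lowest-numbered set)."""
    for g in GENOMES:
        if g in rec.coordinates:
            contig, pos = rec.coordinates[g]
            return g, contig, pos
    raise ValueError("record has no carrier coordinates")


def _sort_key(rec: CandidateRecord) -> tuple:
    return (
        rec.ascertainment_set if rec.ascertainment_set is not None else 99,
        GENOMES.index(rec.ascertainment_genome),
        rec.locus_id,
    )


def dedupe_candidates(
    records: Iterable[CandidateRecord],
    overlap_tolerance: int = DEFAULT_OVERLAP_TOLERANCE,
) -> DedupeResult:
    """Collapse candidates ascertained from multiple genome sets.

    Records are projected onto a common reference (their earliest carrier
    genome) and grouped whenever projected insertion coordinates lie within
    ``overlap_tolerance`` bp on the same contig.  One representative per
    group is kept: the lowest set number.  The result is independent of
    input order.
    """
    keyed: dict[tuple[str, str], list[tuple[int, CandidateRecord]]] = {}
    for rec in records:
        ref_genome, contig, pos = _reference_coordinate(rec)
        keyed.setdefault((ref_genome, contig), []).append((pos, rec))
    unique: list[CandidateRecord] = []
    dup_counts: dict[str, int] = {}
    groups: list[list[CandidateRecord]] = []
    for key in sorted(keyed):
        entries = sorted(keyed[key], key=lambda e: (e[0], _sort_key(e[1])))
        cluster: list[tuple[int, CandidateRecord]] = []
        for pos, rec in entries:
            if cluster and pos - cluster[-1][0] > overlap_tolerance:
                groups.append([r for _, r in cluster])
                cluster = []
            cluster.append((pos, rec))
        if cluster:
            groups.append([r for _, r in cluster])
    for group in groups:
        group.sort(key=_sort_key)
        rep = group[0]
        unique.append(rep)
        if len(group) > 1:
            dup_counts[rep.category] = dup_counts.get(rep.category, 0) + len(group) - 1
    unique.sort(key=_sort_key)
    return DedupeResult(unique=unique, duplicates_per_category=dup_counts, groups=groups)
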