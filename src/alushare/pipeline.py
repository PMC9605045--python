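"""End-to-end orchestration: annotations -> candidates -> summary.

For every ingroup genome, full-length Alu loci are ascertained and carried
through the outgroup gap test, ortholog fetching, four-way alignment, the
1500-1600 column length filter, consensus presence scoring, category
assignment and automated inspection.  Candidates ascertained from several
genomes are then collapsed to unique calls and summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .consensus import ALUS_CONSENSUS, SUBFAMILY_LIBRARY
from .extract import AluLocus, extract_genome_loci
from .inspection import DEFAULT_INSPECTION, InspectionConfig, InspectionOutcome, classify_inspection
from .orthologs import (
    ALIGNMENT_MAX_BP,
    ALIGNMENT_MIN_BP,
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_GAP,
    FourWayAlignment,
    LineageCheck,
    align_four_way,
    check_lineage_specific,
    fetch_orthologs,
    filter_alignment_length,
)
from .presence import (
    CandidateRecord,
    DedupeResult,
    PresenceCall,
    PresencePattern,
    assign_category,
    dedupe_candidates,
    score_alu_presence,
)
from .report import CategorySummary, summarize
from .scoring import DEFAULT_SCHEME, ScoringScheme
from .simulate import GENOMES, OUTGROUP, CohortData


@dataclass
class PipelineConfig:
    consensus: str = ALUS_CONSENSUS
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    threshold_fraction: float = 0.5
    min_gap: int = DEFAULT_MIN_GAP
    max_gap: int = DEFAULT_MAX_GAP
    length_min: int = ALIGNMENT_MIN_BP
    length_max: int = ALIGNMENT_MAX_BP
    inspection: InspectionConfig = field(default_factory=InspectionConfig)
    overlap_tolerance: int = 50
    subfamily_library: Mapping[str, str] = field(default_factory=lambda: dict(SUBFAMILY_LIBRARY))
    muscle_path: Optional[str] = None


@dataclass
class LocusResult:
    """Per-candidate trace through the pipeline stages."""

    locus: AluLocus
    status: str  # scored | unmappable | outgroup_present | no_orthologs | length_filtered
    lineage: Optional[LineageCheck] = None
    alignment: Optional[FourWayAlignment] = None
    pattern: Optional[PresencePattern] = None
    category: Optional[str] = None
    outcome: Optional[InspectionOutcome] = None
    candidate: Optional[CandidateRecord] = None


@dataclass
class CohortResult:
    results: list[LocusResult]
    candidates: list[CandidateRecord]
    dedupe: DedupeResult
    summary: CategorySummary
    rejected: dict[str, list[tuple[object, str]]]

    def status_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.results:
            counts[r.status] = counts.get(r.status, 0) + 1
        return counts


def process_locus(
    locus: AluLocus,
    data: CohortData,
    config: PipelineConfig,
) -> LocusResult:
    """Run one ascertained locus through anchoring, alignment and scoring."""
    g = locus.genome_id
    lineage = check_lineage_specific(
        locus, data.anchors.get((locus.locus_id, OUTGROUP), []),
        min_gap=config.min_gap, max_gap=config.max_gap,
    )
    if lineage.is_lineage_specific is None:
        return LocusResult(locus, "unmappable", lineage)
    if lineage.is_lineage_specific is False:
        return LocusResult(locus, "outgroup_present", lineage)
    hits_by_genome = {
        t: data.anchors.get((locus.locus_id, t), []) for t in GENOMES if t != g
    }
    regions = fetch_orthologs(locus, data.genomes, hits_by_genome)
    sequences = {g: locus.query_sequence}
    sequences.update({t: r.sequence for t, r in regions.items()})
    if len(sequences) < 2:
        return LocusResult(locus, "no_orthologs", lineage)
    alignment = align_four_way(
        sequences, config.scheme, center_id=g,
        locus_id=locus.locus_id, muscle_path=config.muscle_path,
    )
    if not filter_alignment_length(alignment, config.length_min, config.length_max):
        return LocusResult(locus, "length_filtered", lineage, alignment)
    calls: dict[str, PresenceCall] = {
        t: score_alu_presence(row, config.consensus, config.scheme, config.threshold_fraction)
        for t, row in alignment.rows.items()
    }
    present = tuple(t in calls and calls[t].present for t in GENOMES)
    pattern = PresencePattern(
        present=present,  # type: ignore[arg-type]
        per_genome_score={t: c.score for t, c in calls.items()},
    )
    if not any(present):
        return LocusResult(locus, "no_presence", lineage, alignment, pattern)
    category = assign_category(pattern)
    coordinates: dict[str, tuple[str, int]] = {}
    for t in pattern.carriers:
        start = calls[t].row_start or 0
        if t == g:
            coordinates[t] = (locus.contig, locus.query_start + start)
        else:
            coordinates[t] = (regions[t].contig, regions[t].start + start)
    outcome = classify_inspection(
        alignment, pattern, calls, config.inspection,
        consensus=config.consensus, library=config.subfamily_library,
        scheme=config.scheme,
    )
    candidate = CandidateRecord(
        locus_id=locus.locus_id,
        ascertainment_genome=g,
        category=category,
        pattern=pattern,
        coordinates=coordinates,
        alignment=alignment,
        outcome=outcome,
    )
    return LocusResult(locus, "scored", lineage, alignment, pattern, category, outcome, candidate)


def run_cohort(data: CohortData, config: PipelineConfig | None = None) -> CohortResult:
    """Run the full pipeline over every ascertainable locus of a cohort."""
    config = config or PipelineConfig()
    results: list[LocusResult] = []
    rejected: dict[str, list[tuple[object, str]]] = {}
    for g in GENOMES:
        if g not in data.annotations:
            continue
        loci, rej = extract_genome_loci(data.genomes[g], data.annotations[g])
        rejected[g] = rej
        for locus in loci:
            results.append(process_locus(locus, data, config))
    candidates = [r.candidate for r in results if r.candidate is not None]
    dedupe = dedupe_candidates(candidates, config.overlap_tolerance)
    summary = summarize(dedupe.unique, dedupe.duplicates_per_category)
    return CohortResult(results, candidates, dedupe, summary, rejected)
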