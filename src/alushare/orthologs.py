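"""Lineage-specificity testing, ortholog fetching and four-way alignment.

A candidate locus (600 bp flank + Alu + 600 bp flank) is first tested
against the outgroup: the insertion is lineage specific when both flanks
anchor colinearly to one outgroup location with an insertion-sized
query-only gap (default 250-500 bp, roughly Alu + A-tail + TSD) between
them.  Orthologous regions are then pulled from the other ingroup genomes
via their anchor hits and aligned.  The multiple alignment is a
star-progressive alignment centred on the ascertainment genome's query,
built from pairwise alignments under the presence-scoring scheme; an
external MUSCLE binary can be swapped in for real-genome runs, but the
internal aligner is the dependency-free default and the one all recovery
guarantees are stated for.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .extract import AluLocus
from .psl import AnchorHit
from .scoring import DEFAULT_SCHEME, ScoringScheme
from .seqs import Genome, degap, read_fasta, write_fasta

DEFAULT_MIN_GAP = 250
DEFAULT_MAX_GAP = 500
ALIGNMENT_MIN_BP = 1500
ALIGNMENT_MAX_BP = 1600


@dataclass(frozen=True)
class LineageCheck:
    """Outcome of the outgroup gap test."""

    status: str  # "lineage_specific" | "outgroup_present" | "unmappable"
    gap: Optional[int] = None
    target_contig: Optional[str] = None

    @property
    def is_lineage_specific(self) -> Optional[bool]:
        if self.status == "unmappable":
            return None
        return self.status == "lineage_specific"


def _flank_coverage(hit: AnchorHit, qlen: int, flank: int) -> tuple[int, int]:
    left = right = 0
    for qs, _, ln in hit.blocks:
        qe = qs + ln
        left += max(0, min(qe, flank) - max(qs, 0))
        right += max(0, min(qe, qlen) - max(qs, qlen - flank))
    return left, right


def _insertion_gap(hit: AnchorHit, qlen: int, flank: int) -> int:
    """Largest unaligned query gap between consecutive blocks that overlaps
    the central (Alu) region of the query."""
    gap = 0
    for (qs1, _, ln1), (qs2, _, _) in zip(hit.blocks, hit.blocks[1:]):
        qe1 = qs1 + ln1
        if qe1 < qlen - flank + 1 and qs2 > flank - 1:
            gap = max(gap, qs2 - qe1)
    return gap


def check_lineage_specific(
    locus: AluLocus,
    outgroup_hits: Sequence[AnchorHit],
    min_gap: int = DEFAULT_MIN_GAP,
    max_gap: int = DEFAULT_MAX_GAP,
    min_flank_coverage: float = 0.8,
) -> LineageCheck:
    """Gap test against the outgroup.

    Lineage specific iff one hit anchors both flanks to a single outgroup
    contig and the unaligned query gap spanning the Alu is within
    [min_gap, max_gap].  A gap below min_gap (typically a single block
    covering the whole query) means the outgroup carries the insertion;
    no hit anchoring both flanks means the locus is unmappable.
    """
    qlen = len(locus.query_sequence)
    flank = locus.flank_length
    best: Optional[AnchorHit] = None
    for hit in outgroup_hits:
        left, right = _flank_coverage(hit, qlen, flank)
        if left >= min_flank_coverage * flank and right >= min_flank_coverage * flank:
            if best is None or hit.aligned_length > best.aligned_length:
                best = hit
    if best is None:
        return LineageCheck(status="unmappable")
    gap = _insertion_gap(best, qlen, flank)
    if min_gap <= gap <= max_gap:
        return LineageCheck(status="lineage_specific", gap=gap, target_contig=best.target_contig)
    return LineageCheck(status="outgroup_present", gap=gap, target_contig=best.target_contig)


@dataclass(frozen=True)
class OrthologRegion:
    genome_id: str
    contig: str
    start: int
    end: int
    sequence: str


def _best_hit(hits: Sequence[AnchorHit]) -> AnchorHit:
    # maximal summed block length; ties broken by lowest (contig, target start)
    return min(hits, key=lambda h: (-h.aligned_length, h.target_contig, h.target_span[0]))


def fetch_orthologs(
    locus: AluLocus,
    genomes: Mapping[str, Genome],
    hits_by_genome: Mapping[str, Sequence[AnchorHit]],
    min_anchor_bp: int = 300,
) -> dict[str, OrthologRegion]:
    """Fetch the orthologous region of each genome via its best anchor hit.

    The region spans the projection of the full query: the first block's
    target start minus the unaligned query prefix through the last block's
    target end plus the unaligned query suffix, clipped to the contig.
    Genomes without a qualifying hit (summed blocks < ``min_anchor_bp``)
    are simply absent from the result and flow to inspection as truncated.
    """
    qlen = len(locus.query_sequence)
    out: dict[str, OrthologRegion] = {}
    for genome_id, hits in hits_by_genome.items():
        qualifying = [h for h in hits if h.aligned_length >= min_anchor_bp]
        if not qualifying:
            continue
        hit = _best_hit(qualifying)
        contig = str(genomes[genome_id][hit.target_contig])
        (q0, q1), (t0, t1) = hit.query_span, hit.target_span
        start = max(0, t0 - q0)
        end = min(len(contig), t1 + (qlen - q1))
        out[genome_id] = OrthologRegion(genome_id, hit.target_contig, start, end, contig[start:end])
    return out


@dataclass
class FourWayAlignment:
    """Gapped rows of the orthologous block, keyed by genome."""

    locus_id: str
    rows: dict[str, str]
    source_genome: str
    aligner: str = "star"

    @property
    def column_count(self) -> int:
        return len(next(iter(self.rows.values())))

    def column_of(self, genome_id: str, ungapped_pos: int) -> int:
        """Alignment column of the given ungapped position in a row."""
        row = self.rows[genome_id]
        seen = 0
        for col, ch in enumerate(row):
            if ch != "-":
                if seen == ungapped_pos:
                    return col
                seen += 1
        raise IndexError(f"ungapped position {ungapped_pos} beyond row content")


class AlignmentError(ValueError):
    pass


def _pairwise_gap_profile(scheme: ScoringScheme, center: str, other: str) -> tuple[dict[int, str], list[str]]:
    """Align ``other`` to ``center``; return insertions before each center
    position and the per-center-position aligned characters."""
    if other == center:
        return {}, list(other)
    aligner = scheme.to_aligner()
    aln = aligner.align(center, other)[0]
    t_blocks, q_blocks = aln.aligned
    ins: dict[int, str] = {}
    aligned_chars = ["-"] * len(center)
    prev_t = prev_q = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if qs > prev_q:  # other-sequence bases falling between center positions
            ins[ts] = other[prev_q:qs]
        for t, q in zip(range(ts, te), range(qs, qe)):
            aligned_chars[t] = other[q]
        prev_t, prev_q = te, qe
    if prev_q < len(other):
        ins[len(center)] = other[prev_q:]
    return ins, aligned_chars


def align_star(
    sequences: Mapping[str, str],
    scheme: ScoringScheme,
    center_id: str,
    locus_id: str = "",
) -> FourWayAlignment:
    """Star-progressive multiple alignment centred on the ascertainment row.

    Every other sequence is aligned pairwise to the center under the scoring
    scheme; gap columns are merged by the usual once-a-gap-always-a-gap
    projection onto center coordinates.  The ungapped content of every row
    is exactly its input sequence.
    """
    if center_id not in sequences:
        raise AlignmentError(f"center {center_id!r} missing from sequences")
    if len(sequences) < 2:
        raise AlignmentError("at least two sequences are required for alignment")
    center = sequences[center_id]
    others = {g: s for g, s in sequences.items() if g != center_id}
    profiles = {g: _pairwise_gap_profile(scheme, center, s) for g, s in others.items()}
    n = len(center)
    master_ins = [0] * (n + 1)
    for ins, _ in profiles.values():
        for pos, chunk in ins.items():
            master_ins[pos] = max(master_ins[pos], len(chunk))
    rows: dict[str, str] = {}
    parts = []
    for i, ch in enumerate(center):
        parts.append("-" * master_ins[i])
        parts.append(ch)
    parts.append("-" * master_ins[n])
    rows[center_id] = "".join(parts)
    for g, (ins, aligned_chars) in profiles.items():
        parts = []
        for i in range(n):
            chunk = ins.get(i, "")
            parts.append(chunk + "-" * (master_ins[i] - len(chunk)))
            parts.append(aligned_chars[i])
        chunk = ins.get(n, "")
        parts.append(chunk + "-" * (master_ins[n] - len(chunk)))
        rows[g] = "".join(parts)
    return FourWayAlignment(locus_id=locus_id, rows=rows, source_genome=center_id, aligner="star")


def align_muscle(sequences: Mapping[str, str], center_id: str, locus_id: str = "",
                 muscle_path: str = "muscle") -> FourWayAlignment:
    """Align with an external MUSCLE executable (real-genome mode)."""
    if shutil.which(muscle_path) is None:
        raise AlignmentError(f"MUSCLE executable not found: {muscle_path!r}")
    with tempfile.TemporaryDirectory() as tmp:
        inp, outp = Path(tmp) / "in.fa", Path(tmp) / "out.fa"
        write_fasta(inp, sequences)
        subprocess.run(
            [muscle_path, "-align", str(inp), "-output", str(outp)],
            check=True, capture_output=True,
        )
        rows = read_fasta(outp)
    return FourWayAlignment(locus_id=locus_id, rows=rows, source_genome=center_id, aligner="muscle")


def align_four_way(
    sequences: Mapping[str, str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    center_id: Optional[str] = None,
    locus_id: str = "",
    muscle_path: Optional[str] = None,
) -> FourWayAlignment:
    """Multiple alignment of the 2-4 available orthologous sequences."""
    if center_id is None:
        center_id = next(iter(sequences))
    if muscle_path:
        return align_muscle(sequences, center_id, locus_id, muscle_path)
    return align_star(sequences, scheme, center_id, locus_id)


def filter_alignment_length(
    alignment: FourWayAlignment,
    min_bp: int = ALIGNMENT_MIN_BP,
    max_bp: int = ALIGNMENT_MAX_BP,
) -> bool:
    """True iff the alignment's column count is within [min_bp, max_bp]."""
    return min_bp <= alignment.column_count <= max_bp


def ungapped_rows_match(alignment: FourWayAlignment, sequences: Mapping[str, str]) -> bool:
    return all(degap(alignment.rows[g]) == sequences[g] for g in sequences)
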