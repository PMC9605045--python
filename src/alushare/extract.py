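"""Full-length Alu locus selection and flank extraction.

A full-length element is an annotated Alu at least 267 bp long whose match
begins no more than 4 bp into the repeat consensus (both bounds inclusive).
Each selected locus is extracted together with 600 bp of 5' and 3' flanking
sequence; loci too close to a contig edge to supply both full flanks are
rejected outright rather than silently shortened.  Minus-strand loci are
reverse-complemented at extraction so the Alu is always handed downstream in
consensus orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .rmout import RepeatAnnotation
from .seqs import Genome, revcomp

FULL_LENGTH_MIN_BP = 267
MAX_CONSENSUS_OFFSET = 4
FLANK_LENGTH = 600


class EdgeLocusError(ValueError):
    """The contig cannot supply a full flank on both sides of the Alu."""

    status = "edge_locus"


@dataclass(frozen=True)
class AluLocus:
    """One ascertained full-length Alu with its flanks.

    Sequences are stored in consensus orientation: for minus-strand
    annotations all three segments are reverse-complemented and the flanks
    swapped, so ``sequence_5flank`` is always 5' of the Alu as written.
    """

    locus_id: str
    genome_id: str
    contig: str
    alu_span: tuple[int, int]  # 0-based half-open, original genome coordinates
    strand: str
    subfamily_call: str
    sequence_5flank: str
    sequence_alu: str
    sequence_3flank: str
    flank_length: int = FLANK_LENGTH

    def __post_init__(self) -> None:
        if len(self.sequence_5flank) != self.flank_length or len(self.sequence_3flank) != self.flank_length:
            raise ValueError("flanks must both have exactly flank_length bases")
        if len(self.sequence_alu) < FULL_LENGTH_MIN_BP:
            raise ValueError(f"Alu body shorter than {FULL_LENGTH_MIN_BP} bp")

    @property
    def query_sequence(self) -> str:
        """flank + Alu + flank, the ~1.5 kb sequence used for anchoring."""
        return self.sequence_5flank + self.sequence_alu + self.sequence_3flank

    @property
    def query_start(self) -> int:
        """Genome coordinate of query position 0 (plus-strand loci)."""
        return self.alu_span[0] - self.flank_length


def select_full_length(
    annotations: Iterable[RepeatAnnotation],
    min_length: int = FULL_LENGTH_MIN_BP,
    max_consensus_offset: int = MAX_CONSENSUS_OFFSET,
) -> list[RepeatAnnotation]:
    """Keep Alu-class annotations that are full length (order preserved)."""
    return [
        a
        for a in annotations
        if a.is_alu and a.length >= min_length and a.consensus_offset <= max_consensus_offset
    ]


def extract_locus_with_flanks(
    genome: Genome,
    annotation: RepeatAnnotation,
    flank: int = FLANK_LENGTH,
) -> AluLocus:
    """Extract an annotated Alu with ``flank`` bp of context on both sides.

    Raises :class:`EdgeLocusError` if either flank would run off the contig,
    and :class:`LookupError` if the contig is absent from the genome.
    """
    if annotation.contig not in genome:
        raise LookupError(f"contig {annotation.contig!r} not in genome {annotation.genome_id!r}")
    contig = str(genome[annotation.contig])
    start, end = annotation.start, annotation.end
    if start - flank < 0 or end + flank > len(contig):
        raise EdgeLocusError(
            f"{annotation.contig}:{start}-{end} cannot supply {flank} bp flanks "
            f"(contig length {len(contig)})"
        )
    left = contig[start - flank : start]
    alu = contig[start:end]
    right = contig[end : end + flank]
    if annotation.strand == "-":
        left, alu, right = revcomp(right), revcomp(alu), revcomp(left)
    return AluLocus(
        locus_id=f"{annotation.contig}|{annotation.genome_id}",
        genome_id=annotation.genome_id,
        contig=annotation.contig,
        alu_span=(start, end),
        strand=annotation.strand,
        subfamily_call=annotation.repeat_name,
        sequence_5flank=left,
        sequence_alu=alu,
        sequence_3flank=right,
        flank_length=flank,
    )


def extract_genome_loci(
    genome: Genome,
    annotations: Sequence[RepeatAnnotation],
    flank: int = FLANK_LENGTH,
) -> tuple[list[AluLocus], list[tuple[RepeatAnnotation, str]]]:
    """Select and extract all full-length loci of one genome.

    Returns the extracted loci and a list of (annotation, status) rejections.
    """
    loci: list[AluLocus] = []
    rejected: list[tuple[RepeatAnnotation, str]] = []
    for ann in select_full_length(annotations):
        try:
            loci.append(extract_locus_with_flanks(genome, ann, flank))
        except EdgeLocusError:
            rejected.append((ann, "edge_locus"))
        except LookupError:
            rejected.append((ann, "missing_contig"))
    return loci, rejected
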