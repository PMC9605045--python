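"""Reading and writing RepeatMasker ``.out`` annotation tables.

The standard layout has three header lines followed by whitespace-delimited
records.  Genomic coordinates are 1-based inclusive in the file and stored
0-based half-open here.  Consensus coordinates come in two conventions:
plus-strand records carry ``begin end (left)`` and complement ('C') records
``(left) end begin``; both are normalised on parse to a 0-based 5' offset
into the consensus (``begin - 1``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Iterator

_HEADER = (
    "   SW   perc perc perc  query     position in query         matching"
    "    repeat          position in repeat\n"
    "score   div. del. ins.  sequence  begin  end      (left)    repeat"
    "      class/family  begin end   (left)  ID\n"
    "\n"
)


class RmOutParseError(ValueError):
    """Raised for a malformed ``.out`` data line; names the line number."""


@dataclass(frozen=True)
class RepeatAnnotation:
    """One RepeatMasker hit, coordinates normalised.

    ``start``/``end`` are 0-based half-open genomic coordinates;
    ``consensus_offset`` is the 0-based distance of the match start from the
    5' end of the repeat consensus (0 means the match begins at consensus
    position 1).
    """

    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str
    consensus_offset: int
    consensus_end: int
    consensus_left: int
    divergence_pct: float
    sw_score: int = 0
    annotation_id: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")
        if self.consensus_offset < 0:
            raise ValueError("consensus offset must be >= 0 after normalization")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_alu(self) -> bool:
        return self.repeat_class.startswith("SINE/Alu")


def _strip_parens(tok: str) -> int:
    return int(tok.strip("()"))


def parse_repeat_annotations(stream: IO[str] | Iterable[str], genome_id: str = "") -> list[RepeatAnnotation]:
    """Parse a ``.out`` stream into a list of :class:`RepeatAnnotation`."""
    out: list[RepeatAnnotation] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        toks = line.split()
        # header lines: first token is not an integer SW score
        if not toks[0].lstrip("-").isdigit():
            continue
        try:
            sw = int(toks[0])
            div = float(toks[1])
            contig = toks[4]
            qbegin = int(toks[5])
            qend = int(toks[6])
            strand = toks[8]
            repeat_name = toks[9]
            repeat_class = toks[10]
            c1, c2, c3 = toks[11], toks[12], toks[13]
            ann_id = int(toks[14]) if len(toks) > 14 and toks[14].isdigit() else 0
            if strand == "+":
                begin, end, left = int(c1), int(c2), _strip_parens(c3)
            elif strand in ("C", "-"):
                left, end, begin = _strip_parens(c1), int(c2), int(c3)
                strand = "-"
            else:
                raise ValueError(f"unknown strand {strand!r}")
            if begin < 1:
                raise ValueError(f"consensus begin must be >= 1, got {begin}")
            out.append(
                RepeatAnnotation(
                    genome_id=genome_id,
                    contig=contig,
                    start=qbegin - 1,
                    end=qend,
                    strand=strand,
                    repeat_name=repeat_name,
                    repeat_class=repeat_class,
                    consensus_offset=begin - 1,
                    consensus_end=end,
                    consensus_left=left,
                    divergence_pct=div,
                    sw_score=sw,
                    annotation_id=ann_id,
                )
            )
        except (ValueError, IndexError) as exc:
            raise RmOutParseError(f"malformed .out record at line {lineno}: {line!r}") from exc
    return out


def read_rmout(path, genome_id: str = "") -> list[RepeatAnnotation]:
    with open(path) as fh:
        return parse_repeat_annotations(fh, genome_id=genome_id)


def _format_record(ann: RepeatAnnotation) -> str:
    if ann.strand == "+":
        cons = f"{ann.consensus_offset + 1} {ann.consensus_end} ({ann.consensus_left})"
        strand = "+"
    else:
        cons = f"({ann.consensus_left}) {ann.consensus_end} {ann.consensus_offset + 1}"
        strand = "C"
    return (
        f"{ann.sw_score:5d} {ann.divergence_pct:5.1f}  0.0  0.0  {ann.contig} "
        f"{ann.start + 1} {ann.end} (0) {strand} {ann.repeat_name} {ann.repeat_class} "
        f"{cons} {ann.annotation_id}"
    )


def write_rmout(path, annotations: Iterable[RepeatAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for ann in annotations:
            fh.write(_format_record(ann) + "\n")
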