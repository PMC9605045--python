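"""Reading and writing PSL alignment hits (BLAT's tab-delimited format).

Only plus-strand hits are modelled; coordinates are 0-based half-open as in
the format itself.  Each :class:`AnchorHit` is one PSL line with its block
structure; blocks must be non-overlapping and ascending in both query and
target coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable


class PslParseError(ValueError):
    pass


@dataclass(frozen=True)
class AnchorHit:
    query_id: str
    target_genome: str
    target_contig: str
    query_size: int
    target_size: int
    strand: str = "+"
    #: list of (query_start, target_start, block_len)
    blocks: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)
    matches: int = 0

    def __post_init__(self) -> None:
        prev_q = prev_t = -1
        for qs, ts, ln in self.blocks:
            if ln <= 0:
                raise ValueError("block length must be positive")
            if qs < prev_q or ts < prev_t:
                raise ValueError("blocks must ascend in query and target coordinates")
            prev_q, prev_t = qs + ln, ts + ln

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.blocks[0][0], self.blocks[-1][0] + self.blocks[-1][2])

    @property
    def target_span(self) -> tuple[int, int]:
        return (self.blocks[0][1], self.blocks[-1][1] + self.blocks[-1][2])

    @property
    def aligned_length(self) -> int:
        return sum(b[2] for b in self.blocks)


def parse_psl(stream: IO[str] | Iterable[str], target_genome: str = "") -> list[AnchorHit]:
    hits: list[AnchorHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        toks = line.split("\t")
        if len(toks) == 1:
            toks = line.split()
        if not toks[0].isdigit():  # psLayout header lines
            continue
        try:
            if len(toks) < 21:
                raise ValueError("expected 21 columns")
            matches = int(toks[0])
            strand = toks[8]
            qname, qsize = toks[9], int(toks[10])
            tname, tsize = toks[13], int(toks[14])
            nblocks = int(toks[17])
            sizes = [int(x) for x in toks[18].rstrip(",").split(",")]
            qstarts = [int(x) for x in toks[19].rstrip(",").split(",")]
            tstarts = [int(x) for x in toks[20].rstrip(",").split(",")]
            if not (len(sizes) == len(qstarts) == len(tstarts) == nblocks):
                raise ValueError("block count mismatch")
            blocks = tuple(zip(qstarts, tstarts, sizes))
            hits.append(
                AnchorHit(
                    query_id=qname,
                    target_genome=target_genome,
                    target_contig=tname,
                    query_size=qsize,
                    target_size=tsize,
                    strand=strand,
                    blocks=blocks,
                    matches=matches,
                )
            )
        except ValueError as exc:
            raise PslParseError(f"malformed PSL record at line {lineno}: {line!r}") from exc
    return hits


def read_psl(path, target_genome: str = "") -> list[AnchorHit]:
    with open(path) as fh:
        return parse_psl(fh, target_genome=target_genome)


def write_psl(path, hits: Iterable[AnchorHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.query_span
            ts, te = h.target_span
            sizes = ",".join(str(b[2]) for b in h.blocks) + ","
            qstarts = ",".join(str(b[0]) for b in h.blocks) + ","
            tstarts = ",".join(str(b[1]) for b in h.blocks) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.matches, 0, 0, 0, 0, 0, 0, 0, h.strand,
                        h.query_id, h.query_size, qs, qe,
                        h.target_contig, h.target_size, ts, te,
                        len(h.blocks), sizes, qstarts, tstarts,
                    )
                )
                + "\n"
            )
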