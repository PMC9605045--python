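"""Pairwise alignment scoring scheme for Alu presence calling.

The scheme is an 18-parameter affine model with asymmetric end gaps: overhangs
of the genomic row relative to the consensus (left/right insertions in the
consensus, in Biopython's nomenclature) are nearly free, while internal gaps on
either side are heavily penalised (-5 open, -3 extend).  Matches score 1.3 and
mismatches 0, so a full-length consensus embedded in a 1.5 kb row scores within
a few points of 1.3 x consensus length, while a row containing only flanking
DNA scores far below half of that maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from Bio import Align


@dataclass(frozen=True)
class ScoringScheme:
    """Scores for the consensus-vs-row global alignment.

    ``target`` refers to the consensus (Biopython's first sequence) and
    ``query`` to the genomic row.  A gap in the target is an *insertion*
    (extra row bases), a gap in the query a *deletion* (missing row bases).
    """

    match: float = 1.3
    mismatch: float = 0.0
    target_left_open: float = -2.0
    target_left_extend: float = 0.0
    target_right_open: float = -1.0
    target_right_extend: float = 0.0
    target_internal_open: float = -5.0
    target_internal_extend: float = -3.0
    query_left_open: float = -1.0
    query_left_extend: float = -1.0
    query_right_open: float = -2.0
    query_right_extend: float = 0.0
    query_internal_open: float = -5.0
    query_internal_extend: float = -3.0

    def to_aligner(self) -> Align.PairwiseAligner:
        """Build a global PairwiseAligner configured with this scheme."""
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        # target gaps == insertions, query gaps == deletions (Biopython >= 1.88)
        a.open_left_insertion_score = self.target_left_open
        a.extend_left_insertion_score = self.target_left_extend
        a.open_right_insertion_score = self.target_right_open
        a.extend_right_insertion_score = self.target_right_extend
        a.open_internal_insertion_score = self.target_internal_open
        a.extend_internal_insertion_score = self.target_internal_extend
        a.open_left_deletion_score = self.query_left_open
        a.extend_left_deletion_score = self.query_left_extend
        a.open_right_deletion_score = self.query_right_open
        a.extend_right_deletion_score = self.query_right_extend
        a.open_internal_deletion_score = self.query_internal_open
        a.extend_internal_deletion_score = self.query_internal_extend
        return a

    def max_score(self, length: int) -> float:
        """Score of a gap-free identity alignment of the given length."""
        return self.match * length

    def replace(self, **kwargs) -> "ScoringScheme":
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(kwargs)
        return ScoringScheme(**values)


DEFAULT_SCHEME = ScoringScheme()


def locator_aligner() -> Align.PairwiseAligner:
    """Local aligner used to *locate* an Alu inside a row.

    The presence scheme scores mismatches at 0 and extends row overhangs for
    free, which makes its optimum degenerate in position: sliding the
    consensus a few bases into the flank costs nothing.  Positions
    (insertion columns, Alu spans handed to TSD detection) therefore come
    from this sharper local model; presence/absence decisions never do.
    """
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -1.0
    return a


def fragment_aligner() -> Align.PairwiseAligner:
    """Local aligner used to detect partial Alu fragments in 'absent' rows."""
    return locator_aligner()
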