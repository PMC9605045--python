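"""Outgroup gap test, ortholog fetching and the internal star aligner."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from alushare import (
    AnchorHit,
    DEFAULT_SCHEME,
    FourWayAlignment,
    align_four_way,
    check_lineage_specific,
    fetch_orthologs,
    filter_alignment_length,
)
from alushare.extract import AluLocus
from alushare.orthologs import AlignmentError, ungapped_rows_match
from alushare.seqs import degap


def _rng_seq(n, seed=0):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), n))


def _locus(alu_len=300, flank=600, seed=0):
    seq = _rng_seq(2 * flank + alu_len, seed)
    return AluLocus(
        locus_id="L|g", genome_id="g", contig="L", alu_span=(1000, 1000 + alu_len),
        strand="+", subfamily_call="AluSc",
        sequence_5flank=seq[:flank],
        sequence_alu=seq[flank : flank + alu_len],
        sequence_3flank=seq[flank + alu_len :],
        flank_length=flank,
    )


def _hit(blocks, qsize=1500, tsize=5000, contig="h1"):
    return AnchorHit(
        query_id="L|g", target_genome="human", target_contig=contig,
        query_size=qsize, target_size=tsize, blocks=tuple(blocks),
        matches=sum(b[2] for b in blocks),
    )


class TestLineageCheck:
    def test_insertion_sized_gap_is_lineage_specific(self):
        # both 600 bp flanks anchor contiguously with a 320 bp query-only gap
        hit = _hit([(0, 1000, 600), (920, 1600, 580)])
        check = check_lineage_specific(_locus(), [hit])
        assert check.is_lineage_specific is True
        assert check.gap == 320

    def test_full_cover_means_outgroup_shares_the_alu(self):
        hit = _hit([(0, 1000, 1500)])
        check = check_lineage_specific(_locus(), [hit])
        assert check.is_lineage_specific is False
        assert check.status == "outgroup_present"

    def test_flanks_on_two_contigs_is_unmappable(self):
        hits = [
            _hit([(0, 1000, 600)], contig="h1"),
            _hit([(900, 4000, 600)], contig="h2"),
        ]
        assert check_lineage_specific(_locus(), hits).status == "unmappable"

    def test_no_hits_is_unmappable_not_false(self):
        check = check_lineage_specific(_locus(), [])
        assert check.status == "unmappable"
        assert check.is_lineage_specific is None

    def test_oversized_gap_rejected(self):
        # flanks anchored (just) but the unaligned gap exceeds max_gap
        hit = _hit([(0, 1000, 480), (1020, 1600, 480)])
        check = check_lineage_specific(_locus(), [hit])
        assert check.gap == 540
        assert check.is_lineage_specific is False

    def test_simulator_loci_all_lineage_specific(self, clean_result):
        assert all(r.lineage.is_lineage_specific for r in clean_result.results)


class TestFetchOrthologs:
    def test_colinear_blocks_with_target_gap_include_the_insert(self):
        locus = _locus()
        contig = _rng_seq(5000, 3)
        hit = _hit([(0, 1000, 600), (600, 1910, 900)])  # 310 bp target-only gap
        regions = fetch_orthologs(locus, {"human": {"h1": contig}}, {"human": [hit]})
        region = regions["human"]
        assert (region.start, region.end) == (1000, 2810)
        assert len(region.sequence) == 1500 + 310

    def test_best_hit_ties_break_to_lowest_target_coordinate(self):
        locus = _locus()
        contig = _rng_seq(8000, 4)
        h_far = _hit([(0, 4000, 1500)])
        h_near = _hit([(0, 1000, 1500)])
        regions = fetch_orthologs(locus, {"human": {"h1": contig}}, {"human": [h_far, h_near]})
        assert regions["human"].start == 1000

    def test_genome_without_qualifying_hit_marked_missing(self):
        locus = _locus()
        weak = _hit([(0, 1000, 100)])
        regions = fetch_orthologs(locus, {"human": {"h1": _rng_seq(5000)}}, {"human": [weak]})
        assert regions == {}


class TestStarAligner:
    def test_identical_sequences_align_without_gaps(self):
        seq = _rng_seq(1500, 5)
        aln = align_four_way({g: seq for g in "abcd"}, center_id="a")
        assert aln.column_count == 1500
        assert all(row == seq for row in aln.rows.values())

    def test_identical_pair_scores_match_times_length(self):
        seq = _rng_seq(800, 6)
        assert DEFAULT_SCHEME.to_aligner().score(seq, seq) == pytest.approx(1.3 * 800)

    def test_single_substitution_keeps_column_count(self):
        seq = _rng_seq(1200, 7)
        other = seq[:600] + ("A" if seq[600] != "A" else "C") + seq[601:]
        aln = align_four_way({"a": seq, "b": other}, center_id="a")
        assert aln.column_count == 1200
        mismatch_cols = sum(
            a != b for a, b in zip(aln.rows["a"], aln.rows["b"])
        )
        assert mismatch_cols == 1

    def test_non_carrier_row_has_contiguous_gap_block(self):
        flank5, alu, flank3 = _rng_seq(600, 8), _rng_seq(300, 9), _rng_seq(600, 10)
        carrier = flank5 + alu + flank3
        non_carrier = flank5 + flank3
        aln = align_four_way({"a": carrier, "b": carrier, "c": carrier, "d": non_carrier},
                             center_id="a")
        row = aln.rows["d"]
        longest_gap = max(
            len(run) for run in "".join(ch if ch == "-" else " " for ch in row).split()
        )
        # end-gap freedom can shift a couple of mismatching terminal bases
        assert 1500 <= aln.column_count <= 1510
        assert 280 <= longest_gap <= 320

    def test_fewer_than_two_sequences_is_an_error(self):
        with pytest.raises(AlignmentError):
            align_four_way({"a": "ACGT"}, center_id="a")

    @given(st.integers(0, 2**31 - 1))
    def test_ungapped_rows_equal_inputs(self, seed):
        rng = np.random.default_rng(seed)
        center = "".join(rng.choice(list("ACGT"), 400))
        seqs = {"center": center}
        for g in "xyz":
            s = list(center)
            # random substitutions plus an indel to force gap columns
            for pos in rng.choice(400, 10, replace=False):
                s[pos] = "ACGT"[rng.integers(4)]
            cut = int(rng.integers(50, 350))
            if rng.random() < 0.5:
                s = s[:cut] + s[cut + int(rng.integers(1, 30)) :]
            else:
                s = s[:cut] + list("".join(rng.choice(list("ACGT"), int(rng.integers(1, 30))))) + s[cut:]
            seqs[g] = "".join(s)
        aln = align_four_way(seqs, center_id="center")
        assert ungapped_rows_match(aln, seqs)
        assert len({len(r) for r in aln.rows.values()}) == 1


class TestLengthFilter:
    @pytest.mark.parametrize(
        "columns,passes",
        [(1499, False), (1500, True), (1600, True), (1601, False)],
    )
    def test_inclusive_bounds(self, columns, passes):
        aln = FourWayAlignment(locus_id="L", rows={"a": "A" * columns, "b": "A" * columns},
                               source_genome="a")
        assert filter_alignment_length(aln) is passes
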