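"""Synthetic four-ingroup + outgroup genome simulator.

Each locus is an independent "contig": a random backbone shared by all five
genomes, with an Alu insertion (subfamily consensus + poly-A tail, flanked by
an exact target-site duplication) planted in the carrier genomes named by the
locus's category.  A shared insertion is identical by descent: every carrier
receives the *same* subfamily, TSD and A-tail at the same backbone position,
after which each lineage decays independently by site-wise substitution.
This is the incomplete-lineage-sorting data regime the pipeline is built to
read out: presence/absence patterns across capuchin (C), marmoset (M), owl
monkey (O) and squirrel monkey (S) that need not match any species tree.

Corruption events emulate the failure modes seen in real alignments:

* ``near_parallel`` -- one carrier's insertion is replaced by a different
  subfamily at a nearby (10-60 bp offset) position with its own TSD.
* ``n_run`` -- a 100 bp run of Ns overwrites part of one genome's flank.
* ``truncated`` -- one genome's contig ends 150 bp before the insertion site.
* ``present_in_all`` -- a nominally absent genome retains 5' and 3' fragments
  of the Alu around an internal deletion.
* ``outgroup_shared`` -- the insertion exists only in the outgroup
  (the "absent in all ingroup" category).

Randomness is organised in documented per-locus substreams so that any draw
can be replayed independently of sequence materialisation:
``default_rng([seed, locus_index, k])`` with k = 0 backbone bases, 1 insert
parameters (subfamily, TSD length, A-tail length), 2 category label,
3 corruption event (a single uniform draw, always consumed, followed by the
event's own parameters), 4..7 per-lineage divergence for C, M, O, S and
8 for the outgroup.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import SUBFAMILY_LIBRARY
from .psl import AnchorHit, read_psl, write_psl
from .rmout import RepeatAnnotation, read_rmout, write_rmout
from .seqs import read_fasta, write_fasta

GENOMES: tuple[str, ...] = ("capuchin", "marmoset", "owl_monkey", "squirrel_monkey")
OUTGROUP = "human"
GENOME_LETTERS = "CMOS"

#: Table-1 category labels in canonical order (letters in fixed C,M,O,S order).
CATEGORY_LABELS: tuple[str, ...] = (
    "CMOS", "CMO", "COS", "CMS", "MOS",
    "CM", "CO", "CS", "MO", "MS", "OS",
    "C", "M", "O", "S",
)
#: Extra weight key: insertion absent from every ingroup genome (outgroup-private).
ABSENT_LABEL = "NONE"

EVENT_TYPES = (
    "clean_shared", "near_parallel", "n_run", "truncated",
    "present_in_all", "outgroup_shared",
)


def pattern_of(label: str) -> tuple[bool, bool, bool, bool]:
    """Presence 4-tuple (C, M, O, S) for a category label."""
    if label == ABSENT_LABEL:
        return (False, False, False, False)
    if label not in CATEGORY_LABELS:
        raise ValueError(f"unknown category label {label!r}")
    return tuple(letter in label for letter in GENOME_LETTERS)  # type: ignore[return-value]


def default_category_weights() -> dict[str, float]:
    """Default locus category mix.

    The ten two- and three-genome categories follow the relative abundances
    of the unique calls observed in the source study (CS richest, CO
    poorest), scaled to 62% of loci; shared-by-all-four gets 18%,
    lineage-specific singletons 4% each and outgroup-private loci 4%.
    """
    ten = {"CM": 132, "CO": 73, "CS": 411, "MO": 223, "MS": 202,
           "OS": 165, "CMO": 192, "CMS": 238, "COS": 286, "MOS": 159}
    total = sum(ten.values())
    weights = {k: 0.62 * v / total for k, v in ten.items()}
    weights["CMOS"] = 0.18
    for letter in "CMOS":
        weights[letter] = 0.04
    weights[ABSENT_LABEL] = 0.04
    return weights


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_loci: int = 100
    backbone_length: int = 3000
    flank_unique_length: int = 700
    category_weights: Mapping[str, float] = field(default_factory=default_category_weights)
    tsd_length_range: tuple[int, int] = (8, 16)
    a_tail_length_range: tuple[int, int] = (10, 40)
    per_lineage_divergence: float = 0.02
    np_event_rate: float = 0.1
    n_run_rate: float = 0.05
    truncation_rate: float = 0.05
    fragment_rate: float = 0.05
    np_offset_range: tuple[int, int] = (10, 60)
    subfamily_library: Mapping[str, str] = field(default_factory=lambda: dict(SUBFAMILY_LIBRARY))

    def validate(self) -> None:
        if self.n_loci < 1:
            raise SimulationConfigError("n_loci must be >= 1")
        if not self.subfamily_library:
            raise SimulationConfigError("subfamily_library must not be empty")
        if self.flank_unique_length < 600:
            raise SimulationConfigError(
                "flank_unique_length must be >= 600 bp; the alignment stage "
                "requires 600 bp flanks on both sides of every insertion"
            )
        if self.backbone_length // 2 < self.flank_unique_length:
            raise SimulationConfigError("backbone_length too short for the requested unique flanks")
        for name, rng_ in (("tsd_length_range", self.tsd_length_range),
                           ("a_tail_length_range", self.a_tail_length_range),
                           ("np_offset_range", self.np_offset_range)):
            lo, hi = rng_
            if lo < 1 or hi < lo:
                raise SimulationConfigError(f"{name} must be positive with min <= max")
        weight_sum = sum(self.category_weights.values())
        if abs(weight_sum - 1.0) > 1e-9:
            raise SimulationConfigError(f"category_weights must sum to 1 (got {weight_sum!r})")
        unknown = set(self.category_weights) - set(CATEGORY_LABELS) - {ABSENT_LABEL}
        if unknown:
            raise SimulationConfigError(f"unknown category labels in weights: {sorted(unknown)}")
        if any(w < 0 for w in self.category_weights.values()):
            raise SimulationConfigError("category weights must be non-negative")
        rate_sum = self.np_event_rate + self.n_run_rate + self.truncation_rate + self.fragment_rate
        if not (0 <= rate_sum <= 1):
            raise SimulationConfigError("corruption rates must be in [0, 1] and sum to <= 1")
        if not (0 <= self.per_lineage_divergence < 1):
            raise SimulationConfigError("per_lineage_divergence must be in [0, 1)")

    @property
    def insertion_position(self) -> int:
        return self.backbone_length // 2


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated locus."""

    locus_id: str
    true_pattern: tuple[bool, bool, bool, bool]
    true_category: str  # Table-1 label, or "NONE" for outgroup-private loci
    event_type: str
    planted_subfamily: Mapping[str, str]  # carrier genome -> subfamily name
    insertion_position: Mapping[str, int]  # carrier genome -> Alu start (contig coords)
    tsd_sequence: str
    corrupt_genome: str = ""
    np_offset: int = 0

    @property
    def carriers(self) -> tuple[str, ...]:
        return tuple(g for g, p in zip(GENOMES, self.true_pattern) if p)


def plant_insertion(backbone: str, position: int, alu: str, tsd_len: int, a_tail_len: int) -> str:
    """Insert ``alu`` + poly-A into ``backbone`` with an exact TSD.

    The ``tsd_len`` bases at ``backbone[position:position + tsd_len]`` end up
    duplicated: once immediately 5' of the Alu and again immediately 3' of
    the A-tail.  Output length = len(backbone) + len(alu) + a_tail_len +
    tsd_len.
    """
    if tsd_len < 1:
        raise ValueError("tsd_len must be >= 1")
    if a_tail_len < 0:
        raise ValueError("a_tail_len must be >= 0")
    if not (0 < position < len(backbone)):
        raise ValueError(f"position {position} outside backbone (len {len(backbone)})")
    if position - tsd_len < 0:
        raise ValueError("duplication window underflows the start of the backbone")
    if position + tsd_len > len(backbone):
        raise ValueError("duplication window overflows the end of the backbone")
    return backbone[: position + tsd_len] + alu + "A" * a_tail_len + backbone[position:]


# ---------------------------------------------------------------------------
# per-locus planning

@dataclass
class _Insert:
    position: int  # backbone insertion point
    tsd_len: int
    tail_len: int
    subfamily: str
    alu: str  # planted Alu body (possibly fragmented)
    full_len: int  # length of the intact subfamily consensus

    @property
    def alu_start(self) -> int:  # contig coordinate of the Alu 5' end
        return self.position + self.tsd_len

    @property
    def block_len(self) -> int:  # inserted block between the two TSD copies
        return len(self.alu) + self.tail_len


@dataclass
class _GenomePlan:
    insert: Optional[_Insert] = None
    cut: Optional[int] = None  # truncation: contig[:cut]
    n_run: Optional[tuple[int, int]] = None  # (start, length) in backbone coords
    fragment: Optional[tuple[int, int]] = None  # deleted alu interval [a, b)


@dataclass
class _LocusPlan:
    index: int
    locus_id: str
    backbone: str
    category: str
    pattern: tuple[bool, bool, bool, bool]
    event_type: str
    genome_plans: dict[str, _GenomePlan]  # keyed by GENOMES + OUTGROUP
    tsd_sequence: str
    corrupt_genome: str = ""
    np_offset: int = 0


def _stream(cfg: SimulationConfig, i: int, k: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, i, k])


_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASE_ARR, n).tobytes().decode()


def _plan_locus(cfg: SimulationConfig, i: int) -> _LocusPlan:
    locus_id = f"L{i:05d}"
    pos = cfg.insertion_position
    backbone = _random_seq(_stream(cfg, i, 0), cfg.backbone_length)

    ins_rng = _stream(cfg, i, 1)
    names = sorted(cfg.subfamily_library)
    subfamily = names[ins_rng.integers(0, len(names))]
    tsd_len = int(ins_rng.integers(cfg.tsd_length_range[0], cfg.tsd_length_range[1] + 1))
    tail_len = int(ins_rng.integers(cfg.a_tail_length_range[0], cfg.a_tail_length_range[1] + 1))

    labels = list(CATEGORY_LABELS) + [ABSENT_LABEL]
    weights = np.array([cfg.category_weights.get(lbl, 0.0) for lbl in labels])
    cat_rng = _stream(cfg, i, 2)
    category = labels[cat_rng.choice(len(labels), p=weights / weights.sum())]
    pattern = pattern_of(category)
    carriers = [g for g, p in zip(GENOMES, pattern) if p]

    alu_seq = cfg.subfamily_library[subfamily]
    shared = _Insert(pos, tsd_len, tail_len, subfamily, alu_seq, len(alu_seq))
    plans = {g: _GenomePlan() for g in (*GENOMES, OUTGROUP)}
    for g in carriers:
        plans[g].insert = replace(shared)

    # corruption event: one uniform draw per locus, always consumed
    ev = _stream(cfg, i, 3)
    u = float(ev.random())
    event = "clean_shared"
    corrupt = ""
    np_offset = 0
    c_np = cfg.np_event_rate
    c_nrun = c_np + cfg.n_run_rate
    c_trunc = c_nrun + cfg.truncation_rate
    c_frag = c_trunc + cfg.fragment_rate
    if category == ABSENT_LABEL:
        event = "outgroup_shared"
        plans[OUTGROUP].insert = replace(shared)
    elif u < c_np and len(carriers) >= 2:
        event = "near_parallel"
        np_genome = carriers[1 + int(ev.integers(0, len(carriers) - 1))]
        offset = int(ev.integers(cfg.np_offset_range[0], cfg.np_offset_range[1] + 1))
        if ev.random() < 0.5:
            offset = -offset
        np_offset = offset
        others = [n for n in names if n != subfamily] or names
        np_sub = others[int(ev.integers(0, len(others)))]
        np_tsd = int(ev.integers(cfg.tsd_length_range[0], cfg.tsd_length_range[1] + 1))
        np_tail = int(ev.integers(cfg.a_tail_length_range[0], cfg.a_tail_length_range[1] + 1))
        np_alu = cfg.subfamily_library[np_sub]
        plans[np_genome].insert = _Insert(pos + offset, np_tsd, np_tail, np_sub, np_alu, len(np_alu))
        corrupt = np_genome
    elif u < c_nrun:
        event = "n_run"
        g = GENOMES[int(ev.integers(0, 4))]
        plans[g].n_run = (pos - 300, 100)
        corrupt = g
    elif u < c_trunc:
        event = "truncated"
        eligible = [g for g in GENOMES if not carriers or g != carriers[0]]
        g = eligible[int(ev.integers(0, len(eligible)))]
        plans[g].cut = pos - 150
        corrupt = g
    elif u < c_frag and 1 <= len(carriers) <= 3:
        event = "present_in_all"
        absent = [g for g in GENOMES if g not in carriers]
        g = absent[int(ev.integers(0, len(absent)))]
        # keep a 60-90 bp head and a 15-25 bp tail of the Alu: enough to be
        # unmistakable fragments, far too little to score as a presence
        a = int(ev.integers(60, 91))
        b = int(ev.integers(275, 286))
        frag = replace(shared)
        frag.alu = alu_seq[:a] + alu_seq[b:]
        plans[g].fragment = (a, b)
        plans[g].insert = frag
        corrupt = g
    return _LocusPlan(
        index=i,
        locus_id=locus_id,
        backbone=backbone,
        category=category,
        pattern=pattern,
        event_type=event,
        genome_plans=plans,
        tsd_sequence=backbone[pos : pos + tsd_len],
        corrupt_genome=corrupt,
        np_offset=np_offset,
    )


def _truth_from_plan(plan: _LocusPlan) -> TruthRecord:
    subs: dict[str, str] = {}
    positions: dict[str, int] = {}
    for g, p in zip(GENOMES, plan.pattern):
        gp = plan.genome_plans[g]
        if p and gp.insert is not None:
            subs[g] = gp.insert.subfamily
            positions[g] = gp.insert.alu_start
    return TruthRecord(
        locus_id=plan.locus_id,
        true_pattern=plan.pattern,
        true_category=plan.category,
        event_type=plan.event_type,
        planted_subfamily=subs,
        insertion_position=positions,
        tsd_sequence=plan.tsd_sequence,
        corrupt_genome=plan.corrupt_genome,
        np_offset=plan.np_offset,
    )


# ---------------------------------------------------------------------------
# materialisation

def _mutate(seq: str, rng: np.random.Generator, p: float) -> str:
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    idx = np.flatnonzero(rng.random(arr.size) < p)
    if idx.size:
        codes = np.zeros(arr.size, dtype=np.int8)
        for c, b in enumerate(b"ACGT"):
            codes[arr == bytes([b])] = c
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASE_ARR[(codes[idx] + shift) % 4]
    return arr.tobytes().decode()


def _build_contig(plan: _LocusPlan, genome: str, rng: np.random.Generator, p: float) -> str:
    gp = plan.genome_plans[genome]
    ins = gp.insert
    if ins is None:
        seq = plan.backbone
    else:
        seq = plant_insertion(plan.backbone, ins.position, ins.alu, ins.tsd_len, ins.tail_len)
    seq = _mutate(seq, rng, p)
    if gp.n_run is not None:
        s, ln = gp.n_run
        seq = seq[:s] + "N" * ln + seq[s + ln :]
    if gp.cut is not None:
        seq = seq[: gp.cut]
    return seq


def _annotations_for(plan: _LocusPlan, genome: str, contig_len: int, div_pct: float) -> list[RepeatAnnotation]:
    gp = plan.genome_plans[genome]
    ins = gp.insert
    if ins is None:
        return []
    out = []
    start = ins.alu_start
    if gp.fragment is None:
        spans = [(start, start + len(ins.alu), 0, len(ins.alu))]
    else:
        a, b = gp.fragment
        spans = [
            (start, start + a, 0, a),
            (start + a, start + a + (ins.full_len - b), b, ins.full_len),
        ]
    for k, (s, e, c_off, c_end) in enumerate(spans):
        if e > contig_len:
            continue  # lost to truncation
        out.append(
            RepeatAnnotation(
                genome_id=genome,
                contig=plan.locus_id,
                start=s,
                end=e,
                strand="+",
                repeat_name=ins.subfamily,
                repeat_class="SINE/Alu",
                consensus_offset=c_off,
                consensus_end=c_end,
                consensus_left=ins.full_len - c_end,
                divergence_pct=round(div_pct, 1),
                sw_score=2000,
                annotation_id=plan.index * 10 + k,
            )
        )
    return out


def _target_pieces(plan: _LocusPlan, genome: str, contig_len: int) -> list[tuple[int, int, int]]:
    """Piecewise backbone -> contig map: (bb_start, bb_end, offset)."""
    gp = plan.genome_plans[genome]
    L = len(plan.backbone)
    ins = gp.insert
    if ins is None:
        pieces = [(0, L, 0)]
    else:
        pieces = [
            (0, ins.position + ins.tsd_len, 0),
            (ins.position, L, ins.tsd_len + ins.block_len),
        ]
    if gp.cut is not None:
        clipped = []
        for bbs, bbe, off in pieces:
            hi = min(bbe, gp.cut - off)
            if hi > bbs:
                clipped.append((bbs, hi, off))
        pieces = clipped
    return pieces


def _query_runs(ins: _Insert, qsize: int) -> list[tuple[str, int, int, int]]:
    """Backbone-derived runs of the extracted query: (side, q_off, bb_start, len)."""
    left = ("left", 0, ins.alu_start - 600, 600)
    right_off = 600 + len(ins.alu) + ins.tail_len
    right = ("right", right_off, ins.position, qsize - right_off)
    return [left, right]


def _map_run(side: str, q_off: int, bbs: int, length: int,
             pieces: list[tuple[int, int, int]], t_ins: Optional[_Insert],
             q_tsd: int) -> list[tuple[int, int, int]]:
    """Map one query backbone run onto a target's piecewise map.

    The TSD exists twice in a carrier but once in a plain backbone, so the
    ambiguous duplicated bases are resolved conservatively: the query's 5'
    flank maps only into the target's left TSD copy, and the query's 3' run
    only past the target insertion point (for a non-carrier target, the
    query's own duplicated ``q_tsd`` bases are left unaligned).
    """
    bbe = bbs + length
    blocks: list[tuple[int, int, int]] = []
    if t_ins is None:
        lo_clip = bbs + q_tsd if side == "right" else bbs
        for pbs, pbe, off in pieces:
            lo, hi = max(lo_clip, pbs), min(bbe, pbe)
            if hi > lo:
                blocks.append((q_off + (lo - bbs), lo + off, hi - lo))
        return blocks
    for idx, (pbs, pbe, off) in enumerate(pieces):
        if idx == 0 and side == "left":
            lo, hi = max(bbs, pbs), min(bbe, pbe, t_ins.position + t_ins.tsd_len)
        elif idx == 1 and side == "right":
            lo, hi = max(bbs, pbs, t_ins.position), min(bbe, pbe)
        else:
            continue
        if hi > lo:
            blocks.append((q_off + (lo - bbs), lo + off, hi - lo))
    return blocks


def _anchor_hit(plan: _LocusPlan, q_genome: str, t_genome: str,
                contigs: Mapping[str, Mapping[str, str]]) -> Optional[AnchorHit]:
    ins = plan.genome_plans[q_genome].insert
    assert ins is not None
    qsize = 1200 + len(ins.alu)
    t_contig = contigs[t_genome][plan.locus_id]
    t_ins = plan.genome_plans[t_genome].insert
    pieces = _target_pieces(plan, t_genome, len(t_contig))
    if not pieces:
        return None
    blocks: list[tuple[int, int, int]] = []
    for side, q_off, bbs, length in _query_runs(ins, qsize):
        blocks.extend(_map_run(side, q_off, bbs, length, pieces, t_ins, ins.tsd_len))
    blocks.sort()
    merged: list[list[int]] = []
    for q, t, ln in blocks:
        if merged and merged[-1][0] + merged[-1][2] == q and merged[-1][1] + merged[-1][2] == t:
            merged[-1][2] += ln
        else:
            merged.append([q, t, ln])
    if not merged:
        return None
    return AnchorHit(
        query_id=f"{plan.locus_id}|{q_genome}",
        target_genome=t_genome,
        target_contig=plan.locus_id,
        query_size=qsize,
        target_size=len(t_contig),
        blocks=tuple(tuple(b) for b in merged),
        matches=sum(b[2] for b in merged),
    )


# ---------------------------------------------------------------------------
# cohort

@dataclass
class CohortData:
    config: Optional[SimulationConfig]
    genomes: dict[str, dict[str, str]]
    annotations: dict[str, list[RepeatAnnotation]]
    anchors: dict[tuple[str, str], list[AnchorHit]]
    truth: list[TruthRecord]

    def write(self, outdir: str | os.PathLike) -> None:
        root = Path(outdir)
        (root / "genomes").mkdir(parents=True, exist_ok=True)
        (root / "annotations").mkdir(exist_ok=True)
        (root / "anchors").mkdir(exist_ok=True)
        for g, contigs in self.genomes.items():
            write_fasta(root / "genomes" / f"{g}.fasta", contigs)
        for g, anns in self.annotations.items():
            write_rmout(root / "annotations" / f"{g}.out", anns)
        grouped: dict[tuple[str, str], list[AnchorHit]] = {}
        for (qname, tgt), hits in sorted(self.anchors.items()):
            q_genome = qname.rsplit("|", 1)[1]
            grouped.setdefault((q_genome, tgt), []).extend(hits)
        for (qg, tg), hits in grouped.items():
            write_psl(root / "anchors" / f"{qg}_vs_{tg}.psl", hits)
        write_truth_table(root / "truth.tsv", self.truth)

    @classmethod
    def read(cls, outdir: str | os.PathLike) -> "CohortData":
        root = Path(outdir)
        genomes = {
            p.stem: read_fasta(p) for p in sorted((root / "genomes").glob("*.fasta"))
        }
        annotations = {
            p.stem: read_rmout(p, genome_id=p.stem)
            for p in sorted((root / "annotations").glob("*.out"))
        }
        anchors: dict[tuple[str, str], list[AnchorHit]] = {}
        for p in sorted((root / "anchors").glob("*.psl")):
            qg, tg = p.stem.split("_vs_")
            for hit in read_psl(p, target_genome=tg):
                anchors.setdefault((hit.query_id, tg), []).append(hit)
        truth_path = root / "truth.tsv"
        truth = read_truth_table(truth_path) if truth_path.exists() else []
        return cls(None, genomes, annotations, anchors, truth)


def simulate_truth(config: SimulationConfig) -> list[TruthRecord]:
    """Truth table only (no sequence materialisation beyond the backbone)."""
    config.validate()
    return [_truth_from_plan(_plan_locus(config, i)) for i in range(config.n_loci)]


def simulate_cohort(config: SimulationConfig, outdir: str | os.PathLike | None = None) -> CohortData:
    """Generate the five genomes, annotations, anchor hits and truth table.

    Deterministic: the same config (including seed) yields byte-identical
    outputs.  If ``outdir`` is given, FASTA / .out / PSL / truth TSV files
    are written there as well.
    """
    config.validate()
    genomes: dict[str, dict[str, str]] = {g: {} for g in (*GENOMES, OUTGROUP)}
    annotations: dict[str, list[RepeatAnnotation]] = {g: [] for g in GENOMES}
    anchors: dict[tuple[str, str], list[AnchorHit]] = {}
    truth: list[TruthRecord] = []
    div_pct = config.per_lineage_divergence * 100
    for i in range(config.n_loci):
        plan = _plan_locus(config, i)
        truth.append(_truth_from_plan(plan))
        for k, g in enumerate((*GENOMES, OUTGROUP)):
            contig = _build_contig(plan, g, _stream(config, i, 4 + k), config.per_lineage_divergence)
            genomes[g][plan.locus_id] = contig
            if g != OUTGROUP:
                annotations[g].extend(_annotations_for(plan, g, len(contig), div_pct))
        # anchor hits for every ascertainable (intact, full-length) insertion
        for g in GENOMES:
            gp = plan.genome_plans[g]
            if gp.insert is None or gp.fragment is not None:
                continue
            if gp.cut is not None and gp.insert.alu_start + len(gp.insert.alu) > gp.cut:
                continue
            qname = f"{plan.locus_id}|{g}"
            for tgt in (*[t for t in GENOMES if t != g], OUTGROUP):
                hit = _anchor_hit(plan, g, tgt, genomes)
                if hit is not None:
                    anchors.setdefault((qname, tgt), []).append(hit)
    cohort = CohortData(config, genomes, annotations, anchors, truth)
    if outdir is not None:
        cohort.write(outdir)
    return cohort


# ---------------------------------------------------------------------------
# truth table I/O

def _join_map(m: Mapping[str, object]) -> str:
    return ";".join(f"{k}:{v}" for k, v in sorted(m.items()))


def write_truth_table(path, truth: Sequence[TruthRecord]) -> None:
    rows = [
        {
            "locus_id": t.locus_id,
            "pattern": "".join("1" if p else "0" for p in t.true_pattern),
            "category": t.true_category,
            "event_type": t.event_type,
            "subfamilies": _join_map(t.planted_subfamily),
            "positions": _join_map(t.insertion_position),
            "tsd_sequence": t.tsd_sequence,
            "corrupt_genome": t.corrupt_genome,
            "np_offset": t.np_offset,
        }
        for t in truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _split_map(s: str) -> dict[str, str]:
    if not s:
        return {}
    return dict(item.split(":", 1) for item in s.split(";"))


def read_truth_table(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            TruthRecord(
                locus_id=row["locus_id"],
                true_pattern=tuple(c == "1" for c in row["pattern"]),  # type: ignore[arg-type]
                true_category=row["category"],
                event_type=row["event_type"],
                planted_subfamily=_split_map(row["subfamilies"]),
                insertion_position={k: int(v) for k, v in _split_map(row["positions"]).items()},
                tsd_sequence=row["tsd_sequence"],
                corrupt_genome=row["corrupt_genome"],
                np_offset=int(row["np_offset"] or 0),
            )
        )
    return out
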