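# Methods

## The problem this package models

Alu elements are ~300 bp primate SINE retrotransposons. An insertion at a
given genomic site is effectively irreversible and identical by descent, so
presence/absence across species is a near-homoplasy-free phylogenetic
character: absence is ancestral, presence derived. During a rapid radiation,
however, insertions that are still polymorphic in the ancestral population
sort independently into descendant lineages (incomplete lineage sorting,
ILS), producing presence/absence patterns that contradict any single species
tree. The package implements the comparative workflow used to read those
patterns out of four New World monkey genomes — capuchin (C), marmoset (M),
owl monkey (O) and squirrel monkey (S) — with a human-like outgroup used
only to establish that a candidate insertion is absent outside the ingroup.

The pipeline stages are:

1. **Ascertainment** (`rmout`, `extract`): parse RepeatMasker `.out`
   annotations; keep *full-length* Alus — at least 267 bp long with the
   match starting no more than 4 bp into the repeat consensus (both bounds
   inclusive, tested on the normalised 0-based consensus offset
   `begin − 1`) — and extract each with 600 bp of 5′ and 3′ flanking
   sequence. Loci that cannot supply a full flank are rejected as
   `edge_locus`, never silently shortened. Minus-strand loci are
   reverse-complemented at extraction so one consensus scorer serves both
   strands.
2. **Lineage-specificity** (`orthologs.check_lineage_specific`): from PSL
   anchor hits of the ~1.5 kb query against the outgroup, the insertion is
   lineage specific when both flanks anchor colinearly to one outgroup
   contig with an unaligned query gap of 250–500 bp (an Alu body plus
   A-tail and TSD) between them. A gap below the minimum means the outgroup
   carries the element; a query whose flanks do not co-anchor is
   `unmappable` — a distinct status, not a negative call.
3. **Ortholog fetching and alignment** (`orthologs`): each other ingroup
   genome contributes the region spanned by the projection of the full
   query through its best anchor hit (maximal summed block length; ties to
   the lowest target coordinate). The 2–4 sequences are aligned by an
   internal star-progressive aligner centred on the ascertainment query,
   using the presence scoring scheme for every pairwise step; an external
   MUSCLE binary can be configured for real-genome runs. Only alignments of
   1500–1600 columns (inclusive) are analysed: 600 + ~300 + 600 is the
   ideal locus, and anything outside that window signals a structural
   problem.
4. **Presence scoring** (`presence`): each row is de-gapped and scored by a
   global pairwise alignment of an AluS consensus against it under the
   18-parameter scheme (match 1.3, mismatch 0; target left/right/internal
   gaps −2/0, −1/0, −5/−3; query left/right/internal gaps −1/−1, −2/0,
   −5/−3). The consensus is the aligner's *target*: the row's flank
   overhangs then cost only the cheap end-gap opens (−3 total), while a row
   that lacks the Alu must pay the −5/−3 internal penalties to engage the
   consensus at all. A row is called present at ≥ 50% of the maximum score
   (1.3 × consensus length). The 4-bit (C,M,O,S) vector maps to one of the
   15 category labels CMOS…S; the all-absent vector is an error.
5. **Inspection** (`inspection`): an automated version of what was
   historically a visual check — see below.
6. **Dedupe and report** (`presence.dedupe_candidates`, `report`): the same
   insertion ascertained from several genomes is collapsed (projection onto
   the earliest carrier genome, 50 bp tolerance; the representative is the
   lowest ascertainment-set number), and per-category totals, unique calls,
   shared/NP/other splits and percentages are tabulated. Displayed
   percentages round half-up at display precision (integer % for
   per-category retention and PCR, one decimal for the pooled
   shared/NP/other fractions); this reproduces every published percentage
   from the published integer counts exactly.

## Operationalising visual inspection

Shared insertions are validated on three pieces of evidence: same position,
matching target-site duplications, and general congruence. The numeric
defaults:

* **Position agreement**: carriers' Alu start positions within 10 bp.
  Positions are measured in *unaligned row coordinates* (all rows share the
  projected-region frame), not alignment columns: because mismatches cost
  nothing under the scoring scheme, the star aligner stacks two
  near-parallel Alus offset by tens of bases into the same columns, hiding
  exactly the offsets this test exists to find. Positions themselves come
  from a separate local "locator" alignment (match 1, mismatch −1, gaps
  −2/−1); the presence scheme's optimum is positionally degenerate (a
  consensus slid into the flank costs nothing), so it is never used for
  locating, only for scoring.
* **TSD detection**: the longest duplicated word (6–25 bp) whose left copy
  ends at the Alu 5′ boundary and whose right copy starts within ±5 bp of
  the estimated A-tail end, allowing up to 2 substitutions between the
  copies (two identical-by-descent copies each decayed ~2% disagree at ~4%
  of sites; an allowance of 1 loses several percent of genuine TSDs).
  Ties: longest, then fewest mismatches, then leftmost. The A-tail end is
  the longest A-run starting within 7 bp of the located consensus end,
  tolerating isolated non-A bases (≤1 per 10, never two in a row). The
  right-copy window extends 5 bp forward of the estimated tail end and up
  to 16 + 5 bp backward into it, because a TSD that begins with adenines is
  indistinguishable from tail to the run estimator and can be absorbed
  whole; the backward reach recovers it at the cost of occasionally
  annotating a slightly different duplication, which cross-carrier
  compatibility then arbitrates.
* **TSD compatibility** across carriers: right-aligned comparison with a
  ±3 bp registration shift, compatible at ≤3 mismatches. Two decayed copies
  of one ancestral TSD pass easily; two unrelated target sites (~75%
  expected mismatch) essentially never do.
* **Verdicts**: `near_parallel` requires a carrier pair whose positions
  differ by more than 10 bp *and* whose TSDs are not compatible — both
  signals, so that positional wobble alone can never demote a genuine
  shared locus. `shared` requires agreement on position, a TSD call for
  every carrier, and pairwise compatibility. Rows with ≥5% Ns are
  `other/has_N`; expected rows that are missing or shorter than 80% of the
  1200 bp flank span are `other/truncated`; a nominally absent row where a
  local alignment of the consensus scores ≥40 (roughly a 40 bp exact
  fragment) is `other/present_in_all` — the case where the element is
  really in all four genomes and the "absence" was a partial deletion.
  Carriers whose TSD evidence is simply irrecoverable give
  `other/tsd_unresolved` rather than a spurious NP call.
* **Subfamily assignment**: best-scoring library consensus under the
  scheme, divergence = mismatches / aligned columns, ties alphabetical,
  `unclassified` below the presence threshold. A validated shared insertion
  whose carriers fall in different subfamily *lineages* (Sc-derived vs
  Ta10-derived, etc.) is flagged as a probable precise parallel insertion;
  same-lineage disagreements are attributed to drift and do not flag.

## The simulator

`simulate_cohort` builds one contig per locus: a random backbone
(default 3000 bp) shared by all five genomes, with the insertion planted at
the midpoint in the genomes named by the locus's category. A shared
insertion is planted *once* — same subfamily consensus, A-tail (10–40 bp),
and exact TSD (8–16 bp) at the same position — and each lineage then decays
independently by site-wise substitution (default 2% per lineage,
approximating ~20 My of drift on both flanks and element). Categories are
drawn from a configurable 16-way distribution (the 15 presence patterns
plus outgroup-private); the default mix follows the relative category
abundances the published study observed for the ten informative categories
(CS richest), with 18% shared-by-all-four, 4% per lineage-specific
singleton and 4% outgroup-private.

Corruption events (one per locus at most, drawn from a single documented
uniform deviate so event counts can be replayed independently):
near-parallel (a different subfamily with its own TSD replaces one
carrier's insertion 10–60 bp away), N-runs (100 bp of Ns in one genome's
flank), truncation (one genome's contig ends 150 bp before the insertion
site; never the first carrier, so the locus remains ascertainable), and
fragmentation (a nominally absent genome keeps a 60–90 bp head and a
15–25 bp tail of the Alu around an internal deletion — large enough to be
unmistakable fragments, far too little to score as presence). The mock
subfamily library is five deterministic 300 bp consensuses differing at a
handful of diagnostic sites, mirroring how real Alu subfamilies differ;
no proprietary consensus sequences are shipped, and real ones can be
supplied as a plain dict. All randomness flows through per-locus numpy
substreams `default_rng([seed, locus, k])` with a documented meaning for
each `k`, making byte-identical re-simulation and independent replay of
any single draw trivial.

What the simulator deliberately does not emulate: indels in the neutral
decay (substitutions only, so clean alignments are exactly 1500 columns),
minus-strand insertions (strand handling is exercised by unit tests on
constructed contigs), nested or adjacent repeats in the flanks,
assembly-scale artefacts beyond N-runs and truncations, and real Alu
sequence composition (A/B boxes, CpG hypermutability). Recovery rates on
simulated cohorts therefore measure the pipeline's logic, not its
performance on real assemblies.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere internally; `.out` (1-based
  inclusive, with the minus-strand `(left) end begin` consensus column
  order) and PSL writers/readers convert at the boundary. The consensus 5′
  offset is normalised to `begin − 1`, so the "≤4 bp from the consensus
  start" filter keeps `begin ≤ 5`.
* The 1500–1600 filter counts alignment columns, bounds inclusive; the
  stated ideal of 1500 bp must itself pass.
* The outgroup gap window (250–500 bp) brackets a full-length Alu (≥267 bp)
  plus A-tail and TSD; both bounds are config keys, as the source workflow
  left them unstated.
* Presence threshold 0.5 × max score: under the scheme a clean Alu row
  scores ≈0.95–1.0 of max, a flank-only row ≈0.33 (mismatch-at-zero lets
  random 25% identity accrue), so 0.5 sits well between the modes. Rows
  retaining large Alu fragments can approach the threshold from below;
  the fragment check in inspection exists precisely for that ambiguity.
* Dedupe tolerance 50 bp; overlap grouping is transitive chaining on
  sorted projected positions, which makes the result order-independent.
* Ascertainment sets are numbered 1–24 in the published layout: the ten
  informative categories in order CM, CO, CS, MO, MS, OS, CMO, CMS, COS,
  MOS, each cycling through its member genomes in C, M, O, S order.
* The star aligner guarantees that the de-gapped content of every row
  equals its input sequence; gap merging is the standard
  once-a-gap-always-a-gap projection onto center coordinates.
* Problem sizes: recovery guarantees are demonstrated on 500-locus cohorts
  (acceptance) and 40–60-locus cohorts (unit fixtures); a 500-locus cohort
  runs the full multi-ascertainment pipeline (~1200 candidate alignments)
  in a few minutes on one CPU.

## Known limitations

* Real-genome mode consumes BLAT PSL and RepeatMasker `.out` files but does
  not wrap those binaries; minus-strand PSL hits are not projected
  (the simulator emits plus-strand hits only).
* The internal star aligner is not a general MSA tool: it is exact for the
  two-to-four-sequence, high-identity regime this pipeline produces, and
  MUSCLE can be swapped in where that assumption breaks.
* `other/tsd_unresolved` is a deliberate extra failure reason with no
  analogue in the published three-way split; in reporting it counts toward
  "other".
* Percent-divergence values reported by `assign_subfamily` are
  alignment-based and will underestimate divergence when the best-scoring
  member is itself diverged from the true progenitor.
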