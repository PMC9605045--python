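"""Synthetic Alu subfamily consensus library.

Real AluS/AluTa consensus sequences are Repbase content and are not bundled.
Instead the package carries a deterministic mock library: a 300 bp base
"AluS" consensus plus five subfamilies that differ from it at a handful of
diagnostic positions, mirroring how the platyrrhine Ta subfamilies differ
from AluSc by only a few bases.  Users running on real genomes drop in their
own consensus FASTA; every function takes the library as an argument.

The 300 bp length is chosen so that a clean locus alignment is exactly
600 + 300 + 600 = 1500 columns, the ideal full-length alignment size.
"""

from __future__ import annotations

import numpy as np

_BASES = np.array(list("ACGT"))

# (subfamily, diagnostic substitution positions) -- positions are applied to
# the base consensus; derived subfamilies stack their parent's diagnostics.
_DIAGNOSTICS = {
    "AluSx": [(11, "T"), (97, "A"), (201, "C"), (277, "G")],
    "AluSc": [(23, "A"), (88, "T"), (150, "G"), (240, "A")],
    "AluTa7": [(23, "A"), (88, "T"), (150, "G"), (240, "A"),
               (45, "C"), (132, "T"), (265, "A")],
    "AluTa10": [(23, "A"), (88, "T"), (150, "G"), (240, "A"),
                (45, "C"), (132, "T"), (265, "A"),
                (60, "G"), (177, "C"), (289, "T")],
    "AluTa15": [(23, "A"), (88, "T"), (150, "G"), (240, "A"),
                (45, "C"), (132, "T"), (265, "A"),
                (70, "T"), (190, "A"), (255, "C")],
}

# Subfamily lineage map used when judging precise parallel insertions:
# same-lineage subfamily differences are compatible with 20 my of decay of a
# single shared insertion; cross-lineage differences are not.
DEFAULT_LINEAGE_MAP = {
    "AluSx": "S",
    "AluSc": "Sc",
    "AluTa7": "Ta7",
    "AluTa10": "Ta10",
    "AluTa15": "Ta15",
}


def _build_library() -> tuple[str, dict[str, str]]:
    rng = np.random.default_rng(164655)
    base = "".join(rng.choice(_BASES, 300))
    lib = {}
    for name, subs in _DIAGNOSTICS.items():
        seq = list(base)
        for pos, alt in subs:
            if seq[pos] == alt:  # force a real difference at diagnostic sites
                alt = "C" if alt != "C" else "G"
            seq[pos] = alt
        lib[name] = "".join(seq)
    return base, lib


#: Generic AluS-lineage consensus used for presence scoring.
ALUS_CONSENSUS: str
#: Mock subfamily consensus library used for planting and classification.
SUBFAMILY_LIBRARY: dict[str, str]
ALUS_CONSENSUS, SUBFAMILY_LIBRARY = _build_library()
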