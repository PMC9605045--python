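"""Small sequence and FASTA helpers shared across modules."""

from __future__ import annotations

import os
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq

Genome = Mapping[str, str]  # contig name -> sequence


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a whole FASTA file into a contig -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(path: str | os.PathLike, records: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def degap(seq: str) -> str:
    return seq.replace("-", "")


def n_fraction(seq: str) -> float:
    s = degap(seq)
    if not s:
        return 0.0
    return s.count("N") / len(s)
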