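"""FASTA helpers (thin wrappers over Bio.SeqIO)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from Bio import SeqIO


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a multi-contig FASTA into a name -> uppercase sequence dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, genome: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
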