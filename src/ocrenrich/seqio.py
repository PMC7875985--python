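"""Sequence and motif-library I/O.

FASTA via Bio.SeqIO. The motif-library text dialect is a row-per-position
probability matrix: a ``>name`` header line followed by one line of four
whitespace-separated probabilities (A C G T order) per motif position.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import IntervalSet
from .motifs import PWM


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def extract_sequences(
    genome: Mapping[str, str], intervals: IntervalSet
) -> dict[str, str]:
    """Peak sequences keyed by interval name (the "getfasta" step)."""
    out: dict[str, str] = {}
    for i, iv in enumerate(intervals):
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome")
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) exceeds {iv.chrom} length"
            )
        name = iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
        out[name] = chrom_seq[iv.start:iv.end]
    return out


def read_motif_library(path) -> list[PWM]:
    """Read PWMs, renormalizing rows (text files round probabilities)."""

    def _finish(name: str, rows: list[list[float]]) -> PWM:
        arr = np.array(rows)
        return PWM(name, arr / arr.sum(axis=1, keepdims=True))

    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(_finish(name, rows))
                name = line[1:].strip()
                rows = []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(
                        f"motif library row must have 4 values, got {line!r}"
                    )
                rows.append(vals)
    if name is not None:
        pwms.append(_finish(name, rows))
    return pwms


def write_motif_library(path, pwms: Sequence[PWM]) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
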