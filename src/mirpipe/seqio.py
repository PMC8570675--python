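"""Sequence and table I/O.

Internal convention: RNA alphabet ``{A, C, G, U, N}``, uppercase. FASTA and
FASTQ files on disk use the sequencer convention (``T``); readers accept
either and writers emit ``T``. All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_RNA_FROM_DNA = str.maketrans("Tt", "Uu")
_DNA_FROM_RNA = str.maketrans("Uu", "Tt")

COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def as_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().translate(_RNA_FROM_DNA)


def as_dna(seq: str) -> str:
    """Uppercase and convert U to T (for file output)."""
    return seq.upper().translate(_DNA_FROM_RNA)


def revcomp(seq: str) -> str:
    return as_rna(seq).translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FastqRecord:
    id: str
    sequence: str          # RNA alphabet internally
    qualities: tuple[int, ...]  # Phred scores

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence and quality lengths differ"
            )


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield FastqRecord(
            id=rec.id,
            sequence=as_rna(str(rec.seq)),
            qualities=tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    # Write through an explicit handle so output is byte-deterministic.
    with open(path, "w", newline="\n") as fh:
        for r in records:
            seqrec = SeqRecord(
                Seq(as_dna(r.sequence)), id=r.id, description=""
            )
            seqrec.letter_annotations["phred_quality"] = list(r.qualities)
            SeqIO.write(seqrec, fh, "fastq")


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str
    description: str = ""


def read_fasta(path: str | Path) -> list[FastaRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(FastaRecord(rec.id, as_rna(str(rec.seq)), desc))
    return out


def write_fasta(records: Iterable[FastaRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for r in records:
            header = r.id if not r.description else f"{r.id} {r.description}"
            fh.write(f">{header}\n{as_dna(r.sequence)}\n")


def read_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True,
                index_label: str | None = None) -> None:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=index, index_label=index_label,
              lineterminator="\n")
    Path(path).write_text(buf.getvalue())
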