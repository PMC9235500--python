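"""Thin FASTA/FASTQ helpers (gzip-transparent, Biopython-backed)."""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path) -> str:
    name = Path(path).name.removesuffix(".gz")
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_sequences(path) -> list[tuple[str, str]]:
    """All records of a FASTA/FASTQ file as (name, uppercase sequence)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sequence file not found: {path}")
    with _open_text(path) as fh:
        records = [(rec.id, str(rec.seq).upper())
                   for rec in SeqIO.parse(fh, _sniff_format(path))]
    if not records:
        raise ValueError(f"no sequence records in {path}")
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def write_fastq(records: list[tuple[str, str]], path, quality: int = 20) -> None:
    """Write reads with a flat placeholder quality (synthetic reads carry no
    per-base quality model)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{chr(33 + quality) * len(seq)}\n")
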