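"""FASTA/FASTQ and table IO, via Biopython and pandas."""

from __future__ import annotations

import os
from collections.abc import Iterable, Iterator
from dataclasses import dataclass

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass(frozen=True)
class FastaRecord:
    id: str
    seq: str


def read_fasta(path: str | os.PathLike) -> list[FastaRecord]:
    """Read a FASTA file; record id is the first whitespace token."""
    records = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            records.append(FastaRecord(id=title.split()[0], seq=seq.upper()))
    if not records:
        raise ValueError(f"empty FASTA: {path}")
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_fastq(path: str | os.PathLike, phred_offset: int = 33) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, seq, quality scores) from a FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            if len(seq) != len(qual):
                raise ValueError(f"seq/qual length mismatch for read {title}")
            yield title.split()[0], seq.upper(), [ord(c) - phred_offset for c in qual]


def write_fastq(
    path: str | os.PathLike,
    reads: Iterable[tuple[str, str, Iterable[int]]],
    phred_offset: int = 33,
) -> None:
    with open(path, "w") as fh:
        for rid, seq, quals in reads:
            qstr = "".join(chr(q + phred_offset) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")


def write_tsv(path: str | os.PathLike, df: pd.DataFrame, header_comment: str | None = None) -> None:
    """Write a TSV table, optionally preceded by '#' comment lines."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
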