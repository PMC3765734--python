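"""File I/O helpers: FASTA/FASTQ (gzip-transparent, via Biopython) and TSV tables."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def open_text(path, mode: str = "rt"):
    """Open a path for text I/O, decompressing transparently if it ends in .gz."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> Iterator[SeqRecord]:
    with open_text(path) as handle:
        yield from SeqIO.parse(handle, "fasta")


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    with open_text(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fastq(path) -> Iterator[SeqRecord]:
    with open_text(path) as handle:
        yield from SeqIO.parse(handle, "fastq")


def write_fastq(reads: Iterable[str], path, prefix: str = "read", quality: int = 30) -> None:
    """Write bare read sequences as FASTQ with a constant Phred quality."""
    def records():
        for i, seq in enumerate(reads):
            rec = SeqRecord(Seq(seq), id=f"{prefix}_{i}", description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(seq)
            yield rec

    with open_text(path, "wt") as handle:
        SeqIO.write(records(), handle, "fastq")


def read_tag_counts(path) -> dict[str, int]:
    """Read a 2-column (tag, count) TSV, with or without a header line."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 1] is not None and not str(df.iloc[0, 1]).isdigit():
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(int)))


def write_tag_counts(counts: dict[str, int], path) -> None:
    """Write a tag->count map as a sorted 2-column TSV (deterministic byte output)."""
    df = pd.DataFrame(sorted(counts.items()), columns=["tag", "count"])
    df.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
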