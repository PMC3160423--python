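"""Sequence primitives shared across the pipeline.

All sequences are stored internally in the DNA alphabet (ACGT, uppercase);
reports render them as RNA (lowercase, U) to match the conventional
presentation of mature miRNA sequences. Genomic coordinates are 1-based
inclusive throughout, matching ``chrom:start:end:strand`` location strings.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")

DNA_BASES = "ACGT"


def to_dna(seq: str) -> str:
    """Normalize a sequence to uppercase DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render a sequence as lowercase RNA (T -> u), as in published tables."""
    return seq.upper().replace("T", "U").lower()


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet (accepts U, returns ACGT)."""
    return to_dna(seq).translate(_COMPLEMENT)[::-1]


def is_valid_seq(seq: str, min_len: int = 1) -> bool:
    s = to_dna(seq)
    return len(s) >= min_len and all(c in DNA_BASES for c in s)


@dataclasses.dataclass(frozen=True, order=True)
class GenomicLocus:
    """A genomic interval, 1-based inclusive, on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}:{self.strand}"

    @classmethod
    def parse(cls, text: str) -> "GenomicLocus":
        """Parse a ``chrom:start:end:strand`` location string."""
        parts = text.rsplit(":", 3)
        if len(parts) != 4:
            raise ValueError(f"malformed location string: {text!r}")
        chrom, start, end, strand = parts
        try:
            return cls(chrom, int(start), int(end), strand)
        except ValueError as exc:
            raise ValueError(f"malformed location string: {text!r}") from exc


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: DNA sequence} dict."""
    from Bio import SeqIO

    return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_reads(path: str | Path) -> Iterator[str]:
    """Yield raw read sequences from a FASTA or FASTQ file (auto-detected)."""
    from Bio import SeqIO

    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield to_dna(str(rec.seq))


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """Write (name, sequence) pairs as FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
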