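"""Exact-match alignment of small-RNA tags to a genome.

A k-mer seed index over the forward strand; full-length exact verification at
each seed hit. Minus-strand hits are found by mapping the reverse complement.
No mismatches, no indels: a tag either occurs verbatim or it does not, which
is the mapping policy appropriate for collapsed sRNA tags.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

from mirdrought.sequtil import GenomicLocus, revcomp, to_dna


@dataclasses.dataclass
class GenomeIndex:
    """k-mer position index of the forward strand of a genome."""

    k: int
    seeds: dict[str, list[tuple[str, int]]]  # kmer -> [(chrom, 0-based pos)]
    sequences: dict[str, str]                # chrom -> forward sequence

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


def build_index(genome: dict[str, str], k: int = 12) -> GenomeIndex:
    """Index every forward-strand k-mer of the genome.

    ``genome`` maps chromosome names to sequences (ACGT/ACGU). Raises on an
    empty genome.
    """
    sequences = {name: to_dna(seq) for name, seq in genome.items()}
    if not sequences or all(len(s) == 0 for s in sequences.values()):
        raise ValueError("empty genome")
    seeds: dict[str, list[tuple[str, int]]] = {}
    for name in sorted(sequences):
        seq = sequences[name]
        for pos in range(len(seq) - k + 1):
            seeds.setdefault(seq[pos : pos + k], []).append((name, pos))
    return GenomeIndex(k=k, seeds=seeds, sequences=sequences)


def _forward_hits(index: GenomeIndex, tag: str) -> list[tuple[str, int]]:
    seed = tag[: index.k]
    hits = []
    for chrom, pos in index.seeds.get(seed, ()):
        if index.sequences[chrom][pos : pos + len(tag)] == tag:
            hits.append((chrom, pos))
    return hits

def map_tag(index: GenomeIndex, tag: str) -> list[GenomicLocus]:
    """All exact full-length occurrences of a tag, both strands.

    Loci are 1-based inclusive; a '-' strand locus means the reverse
    complement of the tag matches the forward genome there. Results are
    sorted by (chrom, start, strand).
    """
    tag = to_dna(tag)
    if len(tag) < index.k:
        raise ValueError(f"tag shorter than seed length {index.k}")
    loci = [
        GenomicLocus(chrom, pos + 1, pos + len(tag), "+")
        for chrom, pos in _forward_hits(index, tag)
    ]
    rc = revcomp(tag)
    for chrom, pos in _forward_hits(index, rc):
        loci.append(GenomicLocus(chrom, pos + 1, pos + len(tag), "-"))
    return sorted(loci, key=lambda g: (g.chrom, g.start, g.strand))


def map_tags(index: GenomeIndex, tags: Iterable[str]) -> dict[str, list[GenomicLocus]]:
    """Map many tags; unmapped tags get an empty locus list."""
    return {to_dna(t): map_tag(index, t) for t in tags}


def naive_scan(genome: dict[str, str], tag: str) -> list[GenomicLocus]:
    """O(nm) reference scan used as the correctness oracle for the index."""
    tag = to_dna(tag)
    loci = []
    for strand, query in (("+", tag), ("-", revcomp(tag))):
        for chrom in sorted(genome):
            seq = to_dna(genome[chrom])
            start = seq.find(query)
            while start != -1:
                loci.append(GenomicLocus(chrom, start + 1, start + len(tag), strand))
                start = seq.find(query, start + 1)
    return sorted(loci, key=lambda g: (g.chrom, g.start, g.strand))


def write_alignments(path, mapped: dict[str, list[GenomicLocus]]) -> None:
    """Write alignments.tsv: seq, chrom, start, end, strand, n_hits."""
    with open(path, "w") as fh:
        fh.write("seq\tchrom\tstart\tend\tstrand\tn_hits\n")
        for seq in sorted(mapped):
            loci = mapped[seq]
            for loc in loci:
                fh.write(f"{seq}\t{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.strand}\t{len(loci)}\n")


def write_sam(path, mapped: dict[str, list[GenomicLocus]], index: GenomeIndex) -> None:
    """Optional SAM export of mapped tags (NM:i:0 on every record)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in sorted(index.sequences):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(index.sequences[chrom])}\n")
        for seq in sorted(mapped):
            for loc in mapped[seq]:
                flag = 16 if loc.strand == "-" else 0
                out_seq = revcomp(seq) if loc.strand == "-" else seq
                fh.write(
                    f"{seq}\t{flag}\t{loc.chrom}\t{loc.start}\t255\t{len(seq)}M\t*\t0\t0\t"
                    f"{out_seq}\t*\tNM:i:0\n"
                )
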