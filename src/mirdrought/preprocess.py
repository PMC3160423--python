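"""Read cleaning, collapsing and library-level statistics.

Raw adapter-ligated reads are trimmed (3' adapter, exact match), filtered on
length (18-30 nt) and polyA content, and collapsed to unique tags with exact
per-library multiplicities. Reads whose 3' adapter cannot be found are
discarded ("null adapter"), as are inserts shorter than 18 nt, longer than
30 nt, or dominated by A (polyA contaminants).
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from typing import Iterable, Sequence

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30


@dataclasses.dataclass(frozen=True)
class CleanTag:
    """A unique clean sequence with raw counts in each library."""

    seq: str
    count_ck: int
    count_ds: int

    @property
    def total(self) -> int:
        return self.count_ck + self.count_ds


@dataclasses.dataclass
class LibraryStats:
    primary_reads: int
    clean_reads: int
    unique_sequences: int
    mapped_reads: int = 0
    mapped_unique: int = 0
    length_histogram: dict[int, int] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def trim_adapter(read: str, adapter3: str, min_overlap: int = 6) -> str | None:
    """Return the insert upstream of the leftmost 3' adapter match, or None.

    A match is an exact occurrence of a prefix of ``adapter3`` starting at
    some position of the read and extending to the read's 3' end (or a full
    internal adapter occurrence), with matched length >= ``min_overlap``.
    None means the adapter was not found and the read is discarded.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    read = read.upper().replace("U", "T")
    adapter3 = adapter3.upper().replace("U", "T")
    for i in range(0, len(read) - min_overlap + 1):
        matched = min(len(adapter3), len(read) - i)
        if matched >= min_overlap and read[i : i + matched] == adapter3[:matched]:
            return read[:i]
    return None


def filter_clean(
    inserts: Iterable[str | None],
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    max_polya_frac: float = 0.8,
) -> list[str]:
    """Keep inserts within [min_len, max_len] whose A-fraction <= threshold."""
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    kept = []
    for ins in inserts:
        if ins is None:
            continue
        if not (min_len <= len(ins) <= max_len):
            continue
        if ins.count("A") / len(ins) > max_polya_frac:
            continue
        kept.append(ins)
    return kept


def clean_reads(
    raw_reads: Iterable[str],
    adapter3: str,
    min_overlap: int = 6,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    max_polya_frac: float = 0.8,
) -> tuple[list[str], int]:
    """Trim + filter a raw library; returns (clean reads, primary read count)."""
    raw = list(raw_reads)
    trimmed = [trim_adapter(r, adapter3, min_overlap) for r in raw]
    return filter_clean(trimmed, min_len, max_len, max_polya_frac), len(raw)


def collapse_tags(clean_ck: Sequence[str], clean_ds: Sequence[str]) -> list[CleanTag]:
    """Collapse two clean-read lists to unique tags with per-library counts."""
    ck = Counter(clean_ck)
    ds = Counter(clean_ds)
    return [
        CleanTag(seq=s, count_ck=ck.get(s, 0), count_ds=ds.get(s, 0))
        for s in sorted(set(ck) | set(ds))
    ]


def length_distribution(tags: Sequence[CleanTag], by: str = "total") -> dict[int, int]:
    """Histogram of tag lengths weighted by read counts or unique sequences."""
    if by not in ("total", "unique"):
        raise ValueError("by must be 'total' or 'unique'")
    hist: Counter[int] = Counter()
    for tag in tags:
        hist[len(tag.seq)] += tag.total if by == "total" else 1
    return dict(sorted(hist.items()))


def library_length_histogram(tags: Sequence[CleanTag], library: str) -> dict[int, int]:
    hist: Counter[int] = Counter()
    for tag in tags:
        n = tag.count_ck if library == "ck" else tag.count_ds
        if n:
            hist[len(tag.seq)] += n
    return dict(sorted(hist.items()))


def common_specific(tags: Sequence[CleanTag]) -> dict[str, dict[str, float]]:
    """Fractions of CK-specific, DS-specific and shared sequences.

    Returned for both weightings: 'total' (read counts) and 'unique'
    (distinct sequences). "DS-specific" means the tag was never seen in CK.
    """
    out: dict[str, dict[str, float]] = {}
    for by in ("total", "unique"):
        ck_only = ds_only = shared = 0
        for tag in tags:
            w = tag.total if by == "total" else 1
            if tag.count_ds == 0:
                ck_only += w
            elif tag.count_ck == 0:
                ds_only += w
            else:
                shared += w
        grand = ck_only + ds_only + shared
        if grand == 0:
            out[by] = {"ck_specific": 0.0, "ds_specific": 0.0, "shared": 0.0}
        else:
            out[by] = {
                "ck_specific": ck_only / grand,
                "ds_specific": ds_only / grand,
                "shared": shared / grand,
            }
    return out


def write_tags(path, tags: Sequence[CleanTag]) -> None:
    with open(path, "w") as fh:
        fh.write("seq\tcount_ck\tcount_ds\n")
        for t in tags:
            fh.write(f"{t.seq}\t{t.count_ck}\t{t.count_ds}\n")


def read_tags(path) -> list[CleanTag]:
    tags = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            seq, ck, ds = line.rstrip("\n").split("\t")
            tags.append(CleanTag(seq=seq, count_ck=int(ck), count_ds=int(ds)))
    return tags


def write_stats(path, stats: dict[str, LibraryStats]) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in stats.items()}, fh, indent=2, default=str)
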