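"""Annotation of mapped tags: ncRNA exclusion and known-miRNA assignment.

Tags matching a user-supplied non-miRNA ncRNA set (rRNA/tRNA/snRNA/snoRNA)
are removed first; the remainder is compared against a known mature miRNA
FASTA (miRBase-style headers, e.g. ``mtr-miR399a``). Matching is exact by
default; a templated-isomiR mode tolerating small 5'/3' end shifts is
available but off by default. Family names are parsed from miRNA ids and
flagged conserved from a packaged, user-editable family list.
"""

from __future__ import annotations

import dataclasses
import re
from importlib import resources
from typing import Iterable, Sequence

from mirdrought.preprocess import CleanTag
from mirdrought.sequtil import to_dna

_FAMILY_RE = re.compile(r"(?:^|-)(miR)(\d+)", re.IGNORECASE)


def parse_family(mirna_id: str) -> str:
    """Family token from an id: ``mtr-miR399a`` -> ``miR399``."""
    m = _FAMILY_RE.search(mirna_id)
    if not m:
        return mirna_id
    return f"miR{m.group(2)}"


@dataclasses.dataclass
class KnownMiRNARecord:
    mirna_id: str
    family: str
    mature_seq: str
    count_ck: int
    count_ds: int
    conserved: bool


def load_conserved_families(path=None) -> set[str]:
    if path is None:
        path = resources.files("mirdrought.data") / "conserved_families.tsv"
    families = set()
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line == "family":
                continue
            families.add(line)
    return families


def exclude_ncrna(
    tags: Sequence[CleanTag],
    ncrna_seqs: dict[str, str] | Iterable[str],
    mode: str = "substring",
) -> tuple[list[CleanTag], list[CleanTag]]:
    """Partition tags into (excluded, retained) against an ncRNA reference.

    A tag is excluded iff it equals an ncRNA sequence or (default mode
    'substring') occurs verbatim inside one — sRNA tags are typically
    fragments of the parent ncRNA. The partition is disjoint and complete.
    """
    if mode not in ("substring", "equality"):
        raise ValueError("mode must be 'substring' or 'equality'")
    seqs = list(ncrna_seqs.values()) if isinstance(ncrna_seqs, dict) else list(ncrna_seqs)
    seqs = [to_dna(s) for s in seqs]
    if mode == "equality":
        ref = set(seqs)
        is_hit = ref.__contains__
    else:
        haystack = "#".join(seqs)
        is_hit = lambda t: t in haystack  # noqa: E731
    excluded, retained = [], []
    for tag in tags:
        (excluded if is_hit(tag.seq) else retained).append(tag)
    return excluded, retained


def _end_shift_match(tag: str, mature: str, max_shift: int, max_mismatch: int) -> int | None:
    """Score a tag against a mature allowing templated end offsets.

    Returns a penalty (offset magnitude + mismatches) for the best admissible
    alignment, or None. Offset 0 with 0 mismatches (exact) scores 0.
    """
    best: int | None = None
    for off in range(-max_shift, max_shift + 1):
        # off: start of tag relative to start of mature
        overlap_len = min(len(mature) - max(off, 0), len(tag) - max(-off, 0))
        if overlap_len < min(len(tag), len(mature)) - max_shift:
            continue
        if abs(len(tag) - len(mature)) > 2 * max_shift:
            continue
        t0, m0 = max(-off, 0), max(off, 0)
        mism = sum(1 for a, b in zip(tag[t0 : t0 + overlap_len], mature[m0 : m0 + overlap_len]) if a != b)
        hang = (len(tag) - overlap_len) + (len(mature) - overlap_len)
        if mism <= max_mismatch and hang <= 2 * max_shift:
            score = mism + abs(off) + hang
            if best is None or score < best:
                best = score
    return best


def match_known_mirna(
    tags: Sequence[CleanTag],
    known_matures: dict[str, str],
    max_shift: int = 0,
    max_mismatch: int = 0,
    conserved_families: set[str] | None = None,
) -> tuple[list[KnownMiRNARecord], list[CleanTag]]:
    """Assign tags to known miRNAs; returns (records, unassigned tags).

    Each tag goes to at most one miRNA: the best-scoring match, ties broken
    lexicographically by miRNA id. With the defaults (max_shift=0,
    max_mismatch=0) only exact full-sequence matches are assigned.
    """
    if conserved_families is None:
        conserved_families = load_conserved_families()
    matures = {mid: to_dna(seq) for mid, seq in known_matures.items()}
    exact: dict[str, str] = {}
    for mid in sorted(matures):
        exact.setdefault(matures[mid], mid)

    counts: dict[str, list[int]] = {mid: [0, 0] for mid in matures}
    unassigned: list[CleanTag] = []
    for tag in tags:
        chosen: str | None = None
        if max_shift == 0 and max_mismatch == 0:
            chosen = exact.get(tag.seq)
        else:
            best_score: int | None = None
            for mid in sorted(matures):
                score = _end_shift_match(tag.seq, matures[mid], max_shift, max_mismatch)
                if score is not None and (best_score is None or score < best_score):
                    best_score, chosen = score, mid
        if chosen is None:
            unassigned.append(tag)
        else:
            counts[chosen][0] += tag.count_ck
            counts[chosen][1] += tag.count_ds
    records = [
        KnownMiRNARecord(
            mirna_id=mid,
            family=parse_family(mid),
            mature_seq=matures[mid],
            count_ck=counts[mid][0],
            count_ds=counts[mid][1],
            conserved=parse_family(mid) in conserved_families,
        )
        for mid in sorted(matures)
        if sum(counts[mid]) > 0
    ]
    return records, unassigned


@dataclasses.dataclass
class FamilySummary:
    family: str
    n_members: int
    count_ck: int
    count_ds: int
    conserved: bool


def summarize_families(
    records: Sequence[KnownMiRNARecord],
    conserved_families: set[str] | None = None,
) -> list[FamilySummary]:
    """Group records by family; ranked by total summed counts, descending."""
    if conserved_families is None:
        conserved_families = load_conserved_families()
    by_family: dict[str, list[KnownMiRNARecord]] = {}
    for rec in records:
        by_family.setdefault(rec.family, []).append(rec)
    out = [
        FamilySummary(
            family=fam,
            n_members=len(members),
            count_ck=sum(r.count_ck for r in members),
            count_ds=sum(r.count_ds for r in members),
            conserved=fam in conserved_families,
        )
        for fam, members in by_family.items()
    ]
    out.sort(key=lambda f: (-(f.count_ck + f.count_ds), f.family))
    return out


def write_known(path, records: Sequence[KnownMiRNARecord]) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tfamily\tmature_seq\tcount_ck\tcount_ds\tconserved\n")
        for r in records:
            fh.write(
                f"{r.mirna_id}\t{r.family}\t{r.mature_seq}\t{r.count_ck}\t{r.count_ds}\t{r.conserved}\n"
            )


def write_families(path, families: Sequence[FamilySummary]) -> None:
    with open(path, "w") as fh:
        fh.write("family\tn_members\tcount_ck\tcount_ds\tconserved\n")
        for f in families:
            fh.write(f"{f.family}\t{f.n_members}\t{f.count_ck}\t{f.count_ds}\t{f.conserved}\n")
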