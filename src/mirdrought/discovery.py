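"""Novel miRNA discovery from unannotated mapped tags.

For each mapped tag of mature length (20-22 nt by default) candidate genomic
windows are excised around the tag (a plan of window lengths with the tag
near either end), folded, and assessed against plant miRNA annotation
criteria: the fold around the mature must be a single stem-loop, the mature
must sit on one arm without spanning the terminal loop, at most a few mature
bases may be unpaired, and the hairpin free energy must clear a stability
threshold. The reported precursor is the hairpin component that encloses the
mature within the folded window (side structure in the excised flanks is
ignored), which mirrors how stem-loops are reported from fold-and-inspect
pipelines. Candidates gain miRNA* support when sequenced tags match the
duplex partner interval predicted from the structure with 2-nt 3' overhangs.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import pandas as pd

from mirdrought.energy import EnergyModel, default_model, encode, structure_energy_deci
from mirdrought.folding import SecondaryStructure, fold_mfe, hairpin_metrics
from mirdrought.mapping import GenomeIndex
from mirdrought.preprocess import CleanTag
from mirdrought.sequtil import GenomicLocus, revcomp, to_dna, to_rna


@dataclasses.dataclass
class DiscoveryConfig:
    mature_len_range: tuple[int, int] = (20, 22)
    min_count: int = 3                 # summed raw counts for candidacy
    precursor_len_range: tuple[int, int] = (80, 320)
    window_lengths: tuple[int, ...] = tuple(range(80, 321, 20))
    end_flank: int = 10                # flank on the tag-proximal window side
    mfe_threshold: float = -30.0       # kcal/mol, internal energy scale
    max_unpaired: int = 4              # unpaired mature bases in the duplex
    star_shift: int = 2                # +/- nt tolerance for star tag matching
    family_dist: int = 3               # mismatches to call a known family


@dataclasses.dataclass
class HairpinEvaluation:
    """Verdict of the annotation criteria for one candidate window."""

    passed: bool
    reason: str
    structure: SecondaryStructure | None = None
    precursor_interval: tuple[int, int] | None = None  # 1-based on window
    mfe: float | None = None
    arm: str | None = None
    mature_unpaired: int | None = None
    star_interval: tuple[int, int] | None = None       # 1-based on window


@dataclasses.dataclass
class NovelMiRNACandidate:
    name: str
    mature_seq: str
    count_ck: int
    count_ds: int
    star_seq: str | None
    star_count_ck: int
    star_count_ds: int
    locus: GenomicLocus          # precursor locus
    arm: str
    precursor_len: int
    mfe: float
    has_star_support: bool
    classification: str          # new_miRNA | new_member_of_known_family
    family: str | None = None


def precursor_length_from_location(location: str) -> int:
    """Length in nt of a ``chrom:start:end:strand`` string (1-based incl.)."""
    return GenomicLocus.parse(location).length


def load_reference_novel_mirnas() -> pd.DataFrame:
    """Packaged worked-example table of 29 star-supported novel miRNAs."""
    path = resources.files("mirdrought.data") / "novel_mirna_reference.tsv"
    return pd.read_csv(str(path), sep="\t", comment="#")


def plan_windows(
    locus: GenomicLocus, chrom_len: int, config: DiscoveryConfig
) -> list[tuple[int, int, bool]]:
    """Genomic windows (1-based start/end, clipped flag) for one tag locus.

    For each planned total length the tag is placed near the transcript 5'
    end, near the transcript 3' end, and centrally (a hairpin partner can lie
    downstream, upstream, or the tag can sit mid-precursor); windows beyond
    chromosome bounds are clipped and flagged.
    """
    out = []
    seen = set()
    for total in config.window_lengths:
        spare = total - locus.length
        for up in (config.end_flank, spare - config.end_flank, spare // 2):
            down = spare - up
            if up < 0 or down < 0:
                continue
            if locus.strand == "+":
                gs, ge = locus.start - up, locus.end + down
            else:
                gs, ge = locus.start - down, locus.end + up
            clipped = gs < 1 or ge > chrom_len
            gs, ge = max(1, gs), min(chrom_len, ge)
            if (gs, ge) not in seen:
                seen.add((gs, ge))
                out.append((gs, ge, clipped))
    return out


def _enclosing_component(
    structure: SecondaryStructure, mature: tuple[int, int]
) -> tuple[tuple[int, int], list[tuple[int, int]]] | None:
    """Outermost pair enclosing the mature and all pairs inside it.

    Returns ((i0, j0), component pairs), 1-based, or None when no pair
    encloses the mature interval.
    """
    s, e = mature
    enclosing = [(i, j) for i, j in structure.pairs if i <= s and j >= e]
    if not enclosing:
        return None
    i0, j0 = min(enclosing)
    comp = [(i, j) for i, j in structure.pairs if i0 <= i and j <= j0]
    return (i0, j0), sorted(comp)


def evaluate_candidate(
    window_seq: str,
    mature_interval: tuple[int, int],
    config: DiscoveryConfig | None = None,
    model: EnergyModel | None = None,
) -> HairpinEvaluation:
    """Fold a candidate window and apply the annotation criteria.

    ``mature_interval`` is 1-based inclusive on ``window_seq``. The criteria
    are applied to the hairpin component enclosing the mature: (a) a single
    stem-loop, (b) mature on one arm, not spanning the loop, (c) at most
    ``max_unpaired`` unpaired mature bases, (d) component free energy at or
    below ``mfe_threshold``.
    """
    config = config or DiscoveryConfig()
    model = model or default_model()
    structure = fold_mfe(window_seq, model)
    comp = _enclosing_component(structure, mature_interval)
    if comp is None:
        return HairpinEvaluation(False, "mature not enclosed by any pair", structure)
    (i0, j0), comp_pairs = comp
    plo, phi = config.precursor_len_range
    if not plo <= (j0 - i0 + 1) <= phi:
        return HairpinEvaluation(False, f"precursor length {j0 - i0 + 1} outside bounds", structure)
    sub_seq = window_seq[i0 - 1 : j0]
    sub_pairs = tuple((i - i0 + 1, j - i0 + 1) for i, j in comp_pairs)
    sub = SecondaryStructure(
        seq=sub_seq,
        pairs=sub_pairs,
        dotbracket="",
        mfe=structure_energy_deci(encode(sub_seq), tuple((a - 1, b - 1) for a, b in sub_pairs), model) / 10.0,
    )
    sub_mature = (mature_interval[0] - i0 + 1, mature_interval[1] - i0 + 1)
    metrics = hairpin_metrics(sub, sub_mature)
    if not metrics.is_single_hairpin:
        return HairpinEvaluation(False, "branched structure around mature", structure)
    if metrics.arm is None:
        return HairpinEvaluation(False, "mature spans the terminal loop", structure)
    if metrics.mature_unpaired_count > config.max_unpaired:
        return HairpinEvaluation(
            False, f"{metrics.mature_unpaired_count} unpaired mature bases", structure
        )
    if sub.mfe > config.mfe_threshold:
        return HairpinEvaluation(False, f"MFE {sub.mfe:.1f} above threshold", structure)
    star_sub = find_star(sub, sub_mature, config.max_unpaired)
    star = None
    if star_sub is not None:
        star = (star_sub[0] + i0 - 1, star_sub[1] + i0 - 1)
    return HairpinEvaluation(
        passed=True,
        reason="ok",
        structure=structure,
        precursor_interval=(i0, j0),
        mfe=sub.mfe,
        arm=metrics.arm,
        mature_unpaired=metrics.mature_unpaired_count,
        star_interval=star,
    )


def find_star(
    structure: SecondaryStructure,
    mature: tuple[int, int],
    max_unpaired: int = 4,
) -> tuple[int, int] | None:
    """Predicted miRNA* interval for a mature on one arm of a hairpin.

    The duplex part of the mature is the mature minus its 2-nt 3' overhang;
    the star spans the pairing partners of that part, extended by 2 nt at the
    star's own 3' end (the complementary Dicer overhang). Returns a 1-based
    interval in precursor coordinates, or None when the mature arm is too
    unpaired for a duplex to be located. On a perfect duplex the construction
    is an involution: the star of the star is the mature.
    """
    s, e = mature
    m_len = e - s + 1
    partner = structure.partner
    duplex = [p for p in range(s, e - 1) if p in partner]
    if len(duplex) < (e - 2 - s + 1) - max_unpaired or not duplex:
        return None
    # a few mature bases can pair spuriously outside the duplex (e.g. with
    # terminal-loop bases); keep the densest partner cluster spanning at most
    # one mature length, which is the duplex proper
    partners = sorted(partner[p] for p in duplex)
    best_i, best_j = 0, 0
    i = 0
    for j in range(len(partners)):
        while partners[j] - partners[i] > m_len + 1:
            i += 1
        if j - i > best_j - best_i:
            best_i, best_j = i, j
    cluster = partners[best_i : best_j + 1]
    return (cluster[0], cluster[-1] + 2)


def _precursor_contains_known(precursor_seq: str, known_set: set[str]) -> bool:
    """True when the precursor carries a known mature on either strand: the
    candidate then sits on an annotated miRNA hairpin (typically it is the
    known miRNA's star arm) and is not a novel discovery."""
    return any(
        mature in precursor_seq or revcomp(mature) in precursor_seq
        for mature in known_set
    )


def attach_star_support(
    window_seq: str,
    star_interval: tuple[int, int],
    tags_by_seq: dict[str, CleanTag],
    star_shift: int = 2,
) -> tuple[str | None, int, int]:
    """Find sequenced tags matching the predicted star interval (+/- shift).

    Returns (best star sequence or None, summed CK count, summed DS count).
    Each interval end may deviate up to ``star_shift`` nt from the predicted
    interval (isomiR-style end variation); every distinct matching tag is
    counted once, and the most abundant one is reported as the star.
    """
    lo, hi = star_interval
    found: dict[str, CleanTag] = {}
    for ss in range(-star_shift, star_shift + 1):
        for es in range(-star_shift, star_shift + 1):
            a, b = lo + ss, hi + es
            if a < 1 or b > len(window_seq) or b - a + 1 < 15:
                continue
            seq = window_seq[a - 1 : b]
            tag = tags_by_seq.get(seq)
            if tag is not None and tag.total > 0:
                found[seq] = tag
    if not found:
        return None, 0, 0
    best_seq = max(found, key=lambda s: (found[s].total, s))
    ck = sum(t.count_ck for t in found.values())
    ds = sum(t.count_ds for t in found.values())
    return best_seq, ck, ds


def classify_novel(
    mature_seq: str,
    known_matures: dict[str, str],
    family_dist: int = 3,
) -> tuple[str, str | None]:
    """new_member_of_known_family if within ``family_dist`` mismatches of a
    known mature (inclusive), else new_miRNA. Length differences are scored
    as mismatches at the best overlap alignment."""
    from mirdrought.annotation import parse_family

    mature = to_dna(mature_seq)
    best: tuple[int, str] | None = None
    for mid in sorted(known_matures):
        ref = to_dna(known_matures[mid])
        short, long_ = (mature, ref) if len(mature) <= len(ref) else (ref, mature)
        diff = len(long_) - len(short)
        dist = min(
            sum(1 for a, b in zip(short, long_[off : off + len(short)]) if a != b) + diff
            for off in range(diff + 1)
        )
        if best is None or dist < best[0]:
            best = (dist, mid)
    if best is not None and best[0] <= family_dist:
        return "new_member_of_known_family", parse_family(best[1])
    return "new_miRNA", None


def _window_to_genomic(gs: int, ge: int, strand: str, interval: tuple[int, int], chrom: str) -> GenomicLocus:
    a, b = interval
    if strand == "+":
        return GenomicLocus(chrom, gs + a - 1, gs + b - 1, "+")
    return GenomicLocus(chrom, ge - b + 1, ge - a + 1, "-")


def discover(
    tags: list[CleanTag],
    mapped: dict[str, list[GenomicLocus]],
    index: GenomeIndex,
    known_matures: dict[str, str] | None = None,
    config: DiscoveryConfig | None = None,
    model: EnergyModel | None = None,
) -> list[NovelMiRNACandidate]:
    """Run candidate extraction, hairpin evaluation and star attachment.

    ``tags`` are the unannotated tags (post ncRNA/known-miRNA removal);
    ``mapped`` maps tag sequences to their genomic loci. One candidate is
    retained per locus (lowest hairpin MFE, ties to the shorter precursor);
    overlapping precursors from different tags collapse to the most abundant
    mature.
    """
    config = config or DiscoveryConfig()
    model = model or default_model()
    known_matures = known_matures or {}
    known_set = {to_dna(s) for s in known_matures.values()}
    tags_by_seq = {t.seq: t for t in tags}
    lo, hi = config.mature_len_range

    eligible = [
        t for t in tags if lo <= len(t.seq) <= hi and t.total >= config.min_count
    ]
    # most abundant first: any later tag whose locus falls inside an accepted
    # precursor would be collapsed against it anyway, so it is skipped before
    # the (expensive) folding step
    eligible.sort(key=lambda t: (-t.total, t.seq))

    def _overlaps_accepted(locus: GenomicLocus) -> bool:
        return any(
            locus.chrom == p.chrom and locus.start <= p.end and p.start <= locus.end
            for p in (c.locus for c in raw)
        )

    raw: list[NovelMiRNACandidate] = []
    for tag in eligible:
        tag_cands: list[NovelMiRNACandidate] = []
        for locus in mapped.get(tag.seq, []):
            if _overlaps_accepted(locus):
                continue
            chrom_len = index.chrom_length(locus.chrom)
            best: tuple[float, int, tuple, HairpinEvaluation, str, tuple[int, int]] | None = None
            for gs, ge, _clipped in plan_windows(locus, chrom_len, config):
                gwin = index.sequences[locus.chrom][gs - 1 : ge]
                if locus.strand == "+":
                    window = gwin
                    m_start = locus.start - gs + 1
                else:
                    window = revcomp(gwin)
                    m_start = ge - locus.end + 1
                m_iv = (m_start, m_start + locus.length - 1)
                if len(window) < 10:
                    continue
                ev = evaluate_candidate(window, m_iv, config, model)
                if not ev.passed:
                    continue
                i0, j0 = ev.precursor_interval
                key = (ev.mfe, j0 - i0 + 1, (gs, ge))
                if best is None or key < best[:3]:
                    best = key + (ev, window, m_iv)
            if best is None:
                continue
            ev, window, m_iv = best[3], best[4], best[5]
            gs, ge = best[2]
            i0, j0 = ev.precursor_interval
            if _precursor_contains_known(window[i0 - 1 : j0], known_set):
                continue
            star_seq, star_ck, star_ds = (None, 0, 0)
            if ev.star_interval is not None:
                star_seq, star_ck, star_ds = attach_star_support(
                    window, ev.star_interval, tags_by_seq, config.star_shift
                )
            prec_locus = _window_to_genomic(gs, ge, locus.strand, ev.precursor_interval, locus.chrom)
            classification, family = classify_novel(tag.seq, known_matures, config.family_dist)
            tag_cands.append(
                NovelMiRNACandidate(
                    name="",
                    mature_seq=tag.seq,
                    count_ck=tag.count_ck,
                    count_ds=tag.count_ds,
                    star_seq=star_seq,
                    star_count_ck=star_ck,
                    star_count_ds=star_ds,
                    locus=prec_locus,
                    arm=ev.arm,
                    precursor_len=prec_locus.length,
                    mfe=ev.mfe,
                    has_star_support=(star_ck + star_ds) >= 1,
                    classification=classification,
                    family=family,
                )
            )
        # a palindromic stem hits both strands of one interval; among a
        # tag's own overlapping candidates, the orientation with sequenced
        # star support wins (then the more stable, shorter hairpin)
        tag_cands.sort(key=lambda c: (not c.has_star_support, c.mfe, c.precursor_len, c.locus))
        for cand in tag_cands:
            if not any(
                cand.locus.chrom == o.locus.chrom
                and cand.locus.start <= o.locus.end
                and o.locus.start <= cand.locus.end
                for o in raw
            ):
                raw.append(cand)

    # collapse overlapping precursors: keep the most abundant mature arm.
    # Strand is ignored: a palindromic stem maps its tags on both strands of
    # the same interval and must not yield two records.
    raw.sort(key=lambda c: (-(c.count_ck + c.count_ds), c.locus))
    kept: list[NovelMiRNACandidate] = []
    for cand in raw:
        clash = False
        for other in kept:
            if (
                cand.locus.chrom == other.locus.chrom
                and cand.locus.start <= other.locus.end
                and other.locus.start <= cand.locus.end
            ):
                clash = True
                break
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: (c.locus.chrom, c.locus.start, c.locus.strand))
    return [dataclasses.replace(c, name=f"cand-{i + 1:03d}") for i, c in enumerate(kept)]


def write_novel(path, candidates: list[NovelMiRNACandidate]) -> None:
    """Write the novel-miRNA table in the published column layout."""
    with open(path, "w") as fh:
        fh.write(
            "name\tsequence\tlength_nt\tcounts\tlocation\tarm\tprecursor_len\tmfe_kcal_mol\t"
            "classification\thas_star_support\n"
        )
        for c in candidates:
            counts = f"{c.count_ck + c.count_ds}/{c.star_count_ck + c.star_count_ds}"
            arm = "5'" if c.arm == "5p" else "3'"
            fh.write(
                f"{c.name}\t{to_rna(c.mature_seq)}\t{len(c.mature_seq)}\t{counts}\t{c.locus}\t"
                f"{arm}\t{c.precursor_len}\t{c.mfe:.1f}\t{c.classification}\t{c.has_star_support}\n"
            )
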