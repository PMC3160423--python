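import numpy as np
import pytest

from mirdrought.discovery import (
    DiscoveryConfig,
    attach_star_support,
    classify_novel,
    evaluate_candidate,
    find_star,
    load_reference_novel_mirnas,
    plan_windows,
    precursor_length_from_location,
)
from mirdrought.folding import SecondaryStructure, fold_mfe
from mirdrought.preprocess import CleanTag
from mirdrought.sequtil import GenomicLocus
from mirdrought.synthetic import build_hairpin

MATURE = "UGAGGUAGUAGGUUGUAUAGU"


@pytest.mark.parametrize(
    "location,length",
    [
        ("MtChr2:16737666:16737796:+", 131),
        ("MtChr5:6026167:6026481:+", 315),
        ("c:10:10:+", 1),
    ],
)
def test_precursor_length_from_location(location, length):
    assert precursor_length_from_location(location) == length


def test_precursor_length_rejects_malformed():
    with pytest.raises(ValueError):
        precursor_length_from_location("MtChr2:16737796:16737666:+")
    with pytest.raises(ValueError):
        precursor_length_from_location("MtChr2;1;2;+")


def test_reference_table_fixture_shape():
    df = load_reference_novel_mirnas()
    assert len(df) == 29
    assert set(df["group"]) == {"new_miRNA", "new_member"}


class TestEvaluateCandidate:
    def test_planted_hairpin_passes(self):
        frag = build_hairpin(MATURE, loop_len=8, n_imperfections=0, seed=1, flank_len=25)
        s = frag.mature_offset + 1
        ev = evaluate_candidate(frag.precursor_seq, (s, s + len(frag.mature_seq) - 1))
        assert ev.passed
        assert ev.arm == "5p"
        assert ev.mfe <= -30.0

    def test_mature_across_loop_fails(self):
        frag = build_hairpin(MATURE, loop_len=8, n_imperfections=0, seed=1, flank_len=25)
        # place the "mature" over the terminal loop region
        loop_start = frag.mature_offset + len(frag.mature_seq) + 1
        ev = evaluate_candidate(frag.precursor_seq, (loop_start - 5, loop_start + 15))
        assert not ev.passed

    def test_dinucleotide_shuffle_mostly_fails(self):
        """Shuffled precursors retain composition but lose the planted duplex;
        the hairpin/MFE criteria reject nearly all of them."""
        rng = np.random.default_rng(21)
        frag = build_hairpin(MATURE, loop_len=8, n_imperfections=0, seed=1, flank_len=30)
        seq = frag.precursor_seq
        m = len(frag.mature_seq)
        fails = 0
        n_shuffles = 60
        for _ in range(n_shuffles):
            dinucs = [seq[i : i + 2] for i in range(0, len(seq) - 1, 2)]
            order = rng.permutation(len(dinucs))
            shuffled = "".join(dinucs[i] for i in order)
            ev = evaluate_candidate(shuffled, (5, 5 + m - 1))
            fails += not ev.passed
        assert fails / n_shuffles >= 0.95

    def test_mfe_threshold_monotonicity(self):
        """Relaxing the MFE threshold never rejects a previously passing
        candidate."""
        strict = DiscoveryConfig(mfe_threshold=-40.0)
        relaxed = DiscoveryConfig(mfe_threshold=-25.0)
        n_pass = 0
        for seed in range(6):
            frag = build_hairpin(MATURE, loop_len=6, n_imperfections=2, seed=seed, flank_len=20)
            s = frag.mature_offset + 1
            iv = (s, s + len(frag.mature_seq) - 1)
            if evaluate_candidate(frag.precursor_seq, iv, strict).passed:
                n_pass += 1
                assert evaluate_candidate(frag.precursor_seq, iv, relaxed).passed
        assert n_pass > 0  # the check must not be vacuous


class TestFindStar:
    def _frag_structure(self, arm="5p", seed=1):
        frag = build_hairpin(MATURE, loop_len=8, n_imperfections=0, seed=seed, arm=arm)
        return frag, fold_mfe(frag.precursor_seq)

    @pytest.mark.parametrize("arm", ["5p", "3p"])
    def test_predicted_star_matches_construction(self, arm):
        frag, st = self._frag_structure(arm)
        s = frag.mature_offset + 1
        star = find_star(st, (s, s + len(frag.mature_seq) - 1))
        assert star == (frag.star_offset + 1, frag.star_offset + len(frag.star_seq))

    def test_star_of_star_is_mature(self):
        frag, st = self._frag_structure()
        s = frag.mature_offset + 1
        star = find_star(st, (s, s + len(frag.mature_seq) - 1))
        back = find_star(st, star)
        assert back == (s, s + len(frag.mature_seq) - 1)

    def test_unpaired_mature_gives_none(self):
        st = SecondaryStructure(seq="A" * 40, pairs=(), dotbracket="." * 40, mfe=0.0)
        assert find_star(st, (5, 25)) is None


class TestStarSupport:
    def test_no_tags_no_support(self):
        frag = build_hairpin(MATURE, loop_len=8, n_imperfections=0, seed=1)
        star_iv = (frag.star_offset + 1, frag.star_offset + len(frag.star_seq))
        seq, ck, ds = attach_star_support(frag.precursor_seq, star_iv, {})
        assert seq is None and ck == 0 and ds == 0

    def test_single_star_read_counts(self):
        frag = build_hairpin(MATURE, loop_len=8, n_imperfections=0, seed=1)
        star_iv = (frag.star_offset + 1, frag.star_offset + len(frag.star_seq))
        tag = CleanTag(seq=frag.star_seq, count_ck=1, count_ds=0)
        seq, ck, ds = attach_star_support(frag.precursor_seq, star_iv, {tag.seq: tag})
        assert seq == frag.star_seq and (ck, ds) == (1, 0)

    def test_shifted_star_tag_still_found(self):
        frag = build_hairpin(MATURE, loop_len=8, n_imperfections=0, seed=1)
        lo, hi = frag.star_offset + 1, frag.star_offset + len(frag.star_seq)
        shifted = frag.precursor_seq[lo : hi + 1]  # +1 shift
        tag = CleanTag(seq=shifted, count_ck=0, count_ds=2)
        seq, ck, ds = attach_star_support(frag.precursor_seq, (lo, hi), {shifted: tag})
        assert seq == shifted and ds == 2


class TestClassifyNovel:
    KNOWN = {"mtr-miR172a": "AGAATCTTGATGATGCTGCAT"}

    def test_identical_mature_is_new_member(self):
        cls, fam = classify_novel("AGAATCTTGATGATGCTGCAT", self.KNOWN)
        assert cls == "new_member_of_known_family" and fam == "miR172"

    def test_distance_at_threshold_is_inclusive(self):
        mutated = "TGAATCTTGATGATGCTGCTA"  # 3 mismatches
        cls, _ = classify_novel(mutated, self.KNOWN, family_dist=3)
        assert cls == "new_member_of_known_family"

    def test_unrelated_is_new_mirna(self):
        cls, fam = classify_novel("TTTTGGGGCCCCAAAATTTTT", self.KNOWN)
        assert cls == "new_miRNA" and fam is None

    def test_no_known_set(self):
        assert classify_novel("AGAATCTTGATGATGCTGCAT", {})[0] == "new_miRNA"


def test_plan_windows_covers_published_precursor_range():
    cfg = DiscoveryConfig()
    locus = GenomicLocus("chr1", 5_000, 5_020, "+")
    lengths = {ge - gs + 1 for gs, ge, _ in plan_windows(locus, 100_000, cfg)}
    assert min(lengths) == 80 and max(lengths) == 320  # spans 86..315 with margin


def test_plan_windows_clips_at_chromosome_start():
    cfg = DiscoveryConfig()
    locus = GenomicLocus("chr1", 5, 25, "+")
    wins = plan_windows(locus, 100_000, cfg)
    assert all(gs >= 1 for gs, _, _ in wins)
    assert any(clipped for _, _, clipped in wins)
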