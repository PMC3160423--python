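import filecmp

import numpy as np
import pytest

from mirdrought.folding import fold_mfe, hairpin_metrics
from mirdrought.mapping import build_index, map_tag
from mirdrought.preprocess import clean_reads, collapse_tags
from mirdrought.sequtil import revcomp, to_dna
from mirdrought.synthetic import (
    PlantedMiRNA,
    SimConfig,
    build_hairpin,
    generate_genome,
    simulate,
    simulate_libraries,
)

MATURE = "UGAGGUAGUAGGUUGUAUAGU"  # 21 nt


class TestBuildHairpin:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_hairpin(MATURE, loop_len=2)
        with pytest.raises(ValueError):
            build_hairpin("ACGU" * 4, loop_len=8)  # 16 nt mature

    def test_perfect_complement_star(self):
        frag = build_hairpin(MATURE, loop_len=8, n_imperfections=0, seed=1)
        mature = to_dna(MATURE)
        # star pairs the mature shifted 2 nt: its first m-2 bases are the
        # reverse complement of the mature minus its last two bases
        assert frag.star_seq[:-2] == revcomp(mature[:-2])
        assert mature in frag.precursor_seq
        assert frag.star_seq in frag.precursor_seq

    def test_perfect_construct_pairs_every_mature_base(self):
        frag = build_hairpin(MATURE, loop_len=8, n_imperfections=0, seed=1)
        st = fold_mfe(frag.precursor_seq)
        s = frag.mature_offset + 1
        metrics = hairpin_metrics(st, (s, s + len(frag.mature_seq) - 1))
        assert metrics.is_single_hairpin
        assert metrics.mature_paired_fraction == 1.0
        assert metrics.arm == "5p"

    def test_three_prime_arm_construct(self):
        frag = build_hairpin(MATURE, loop_len=6, n_imperfections=1, seed=3, arm="3p")
        st = fold_mfe(frag.precursor_seq)
        s = frag.mature_offset + 1
        metrics = hairpin_metrics(st, (s, s + len(frag.mature_seq) - 1))
        assert metrics.arm == "3p"
        assert metrics.mature_unpaired_count <= 1

    def test_deterministic_under_seed(self):
        a = build_hairpin(MATURE, 8, 2, seed=7)
        b = build_hairpin(MATURE, 8, 2, seed=7)
        assert a == b


class TestGenerateGenome:
    def test_no_planted_gives_empty_truth(self):
        cfg = SimConfig(genome_length=5_000, n_planted=0, n_up=0, n_down=0,
                        n_known_mirnas=0, n_ncrna=0, seed=1)
        genome, planted, extras = generate_genome(cfg)
        assert planted == [] and extras["known"] == {}
        assert len(genome[cfg.chrom_name]) == 5_000

    def test_planted_precursors_at_recorded_loci(self):
        cfg = SimConfig(genome_length=40_000, n_planted=5, n_up=1, n_down=1,
                        n_known_mirnas=2, n_ncrna=1, seed=2)
        genome, planted, extras = generate_genome(cfg)
        assert len(planted) == 5
        for rec in planted + list(extras["known"].values()):
            sub = genome[rec.locus.chrom][rec.locus.start - 1 : rec.locus.end]
            expected = rec.precursor_seq if rec.locus.strand == "+" else revcomp(rec.precursor_seq)
            assert sub == expected
            assert rec.mature_seq in rec.precursor_seq
            assert rec.star_seq in rec.precursor_seq

    def test_deterministic(self):
        cfg = SimConfig(genome_length=30_000, n_planted=3, n_up=0, n_down=0, seed=5,
                        n_known_mirnas=1, n_ncrna=1)
        g1, p1, _ = generate_genome(cfg)
        g2, p2, _ = generate_genome(cfg)
        assert g1 == g2 and p1 == p2

    def test_overcrowded_genome_rejected(self):
        cfg = SimConfig(genome_length=2_000, n_planted=20, n_up=0, n_down=0, seed=1)
        with pytest.raises(ValueError):
            generate_genome(cfg)

    def test_true_log2fc(self):
        cfg = SimConfig(genome_length=60_000, n_planted=6, n_up=2, n_down=1,
                        de_log2fc=2.0, n_known_mirnas=0, n_ncrna=0, seed=3)
        _, planted, _ = generate_genome(cfg)
        fcs = sorted(round(p.true_log2fc, 6) for p in planted)
        assert fcs == [-2.0, 0.0, 0.0, 0.0, 2.0, 2.0]


class TestSimulateLibraries:
    def test_zero_depth_gives_empty_libraries(self):
        cfg = SimConfig(genome_length=30_000, n_planted=2, n_up=0, n_down=0,
                        library_depths=(0, 0), seed=4, n_known_mirnas=0, n_ncrna=0)
        genome, planted, _ = generate_genome(cfg)
        ck, ds = simulate_libraries(genome, planted, cfg)
        assert ck == [] and ds == []

    def test_poisson_counts_recovered_through_preprocessing(self):
        """With clean adapters, mature counts recovered after trimming,
        collapsing and mapping stay within 4 SD of the Poisson mean."""
        rate = 400.0
        cfg = SimConfig(genome_length=20_000, n_planted=1, n_up=0, n_down=0,
                        base_rate_low=rate, base_rate_high=rate,
                        library_depths=(3_000, 3_000), noise_read_fraction=0.0,
                        n_known_mirnas=0, n_ncrna=0, seed=8)
        genome, planted, _ = generate_genome(cfg)
        ck, ds = simulate_libraries(genome, planted, cfg)
        mirna = planted[0]
        index = build_index(genome)
        for lib in (ck, ds):
            clean, _ = clean_reads(lib, cfg.adapter3)
            tags = {t.seq: t for t in collapse_tags(clean, [])}
            assert mirna.mature_seq in tags
            count = tags[mirna.mature_seq].count_ck
            assert abs(count - rate) <= 4 * np.sqrt(rate)
            assert map_tag(index, mirna.mature_seq), "mature must map back"

    def test_truth_conservation_reads_map_to_locus(self):
        cfg = SimConfig(genome_length=30_000, n_planted=3, n_up=0, n_down=0,
                        library_depths=(1_000, 1_000), noise_read_fraction=0.0,
                        n_known_mirnas=0, n_ncrna=0, seed=9)
        genome, planted, _ = generate_genome(cfg)
        index = build_index(genome)
        for rec in planted:
            hits = map_tag(index, rec.mature_seq)
            assert any(
                h.chrom == rec.locus.chrom
                and rec.locus.start <= h.start <= h.end <= rec.locus.end
                for h in hits
            )


def test_simulate_outputs_are_byte_identical_across_runs(tmp_path):
    cfg = SimConfig(genome_length=30_000, n_planted=3, n_up=1, n_down=0,
                    library_depths=(800, 800), seed=13, n_known_mirnas=1, n_ncrna=1)
    p1 = simulate(cfg, tmp_path / "a")
    p2 = simulate(cfg, tmp_path / "b")
    for key in p1:
        assert filecmp.cmp(p1[key], p2[key], shallow=False), key


def test_simconfig_validation():
    with pytest.raises(ValueError):
        SimConfig(length_dist={21: 0.5}).validate()
    with pytest.raises(ValueError):
        SimConfig(noise_read_fraction=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(n_planted=2, n_up=2, n_down=1).validate()
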