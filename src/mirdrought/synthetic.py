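"""Synthetic small-RNA study generator with ground truth.

Builds a toy genome with planted miRNA hairpin precursors and simulates two
adapter-ligated libraries (control CK, drought DS) with Poisson read counts
and configurable fold changes, plus background reads drawn from the genome
with a length distribution peaked at 24 nt then 21 nt. Every planted locus,
rate and fold change is recorded in a truth table so the pipeline's
sensitivity and differential-expression calls can be scored exactly.

The generator emulates library construction only to the depth the pipeline
can see: adapter ligation of 18-30 nt inserts, null-adapter noise, and
sampling depth. There is no sequencing-error or quality model.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

from mirdrought.sequtil import GenomicLocus, revcomp, to_dna, write_fasta, write_fastq

#: classic Solexa small-RNA 3' adapter
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"

#: background insert-length distribution: 24-nt mode, 21-nt secondary mode
DEFAULT_LENGTH_DIST = {
    18: 0.02, 19: 0.03, 20: 0.05, 21: 0.20, 22: 0.07, 23: 0.08, 24: 0.30,
    25: 0.08, 26: 0.05, 27: 0.04, 28: 0.03, 29: 0.02, 30: 0.03,
}

_BASES = np.array(list("ACGT"))
_NONPAIRING = {  # bases that pair neither Watson-Crick nor wobble with key
    "A": "CG", "C": "AU", "G": "AG", "U": "CU", "T": "CU",
}


@dataclasses.dataclass(frozen=True)
class HairpinFragment:
    """A constructed precursor with mature/star placement (0-based offsets)."""

    precursor_seq: str
    mature_offset: int
    star_offset: int
    mature_seq: str
    star_seq: str
    arm: str


@dataclasses.dataclass(frozen=True)
class PlantedMiRNA:
    name: str
    mature_seq: str
    star_seq: str
    precursor_seq: str
    locus: GenomicLocus
    arm: str
    rate_ck: float
    rate_ds: float

    @property
    def true_log2fc(self) -> float:
        if self.rate_ck <= 0 or self.rate_ds <= 0:
            return math.inf if self.rate_ds > self.rate_ck else -math.inf
        return math.log2(self.rate_ds / self.rate_ck)


@dataclasses.dataclass
class SimConfig:
    genome_length: int = 100_000
    chrom_name: str = "chr1"
    n_planted: int = 30
    n_up: int = 5
    n_down: int = 5
    de_log2fc: float = 2.0
    base_rate_low: float = 50.0
    base_rate_high: float = 1000.0
    star_ratio: float = 50.0
    mature_len_range: tuple[int, int] = (20, 22)
    adapter3: str = DEFAULT_ADAPTER3
    read_length: int = 36
    noise_read_fraction: float = 0.05
    library_depths: tuple[int, int] = (50_000, 50_000)
    length_dist: dict[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    n_known_mirnas: int = 5
    n_ncrna: int = 2
    ncrna_read_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.length_dist.values()) - 1.0) > 1e-9:
            raise ValueError("length_dist must sum to 1")
        if any(d < 0 for d in self.library_depths):
            raise ValueError("library depths must be >= 0")
        if not 0 <= self.noise_read_fraction <= 1:
            raise ValueError("noise_read_fraction must be in [0, 1]")
        if self.n_up + self.n_down > self.n_planted:
            raise ValueError("n_up + n_down exceeds n_planted")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def build_hairpin(
    mature: str,
    loop_len: int = 8,
    n_imperfections: int = 0,
    seed: int | np.random.Generator = 0,
    flank_len: int = 20,
    arm: str = "5p",
) -> HairpinFragment:
    """Construct a precursor whose stem carries the mature/star duplex.

    The precursor is flank5 + (mature arm) + loop + (star arm) + flank3 with
    flank3 the reverse complement of flank5, so the minimum-energy fold is a
    single hairpin pairing every mature base. The star arm is the reverse
    complement of the mature with ``n_imperfections`` point changes to
    non-pairing bases; the mature/star duplex carries the 2-nt 3' overhangs
    of a Dicer product on both ends.
    """
    mature = to_dna(mature)
    m = len(mature)
    if not 20 <= m <= 22:
        raise ValueError(f"mature length {m} outside 20..22")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
    if flank_len < 4:
        raise ValueError("flank_len must be >= 4")
    if not 0 <= n_imperfections <= (m - 4):
        raise ValueError("n_imperfections out of range")
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _attempt in range(40):
        flank5 = _random_seq(rng, flank_len)
        loop = _random_seq(rng, loop_len)
        pair_arm = list(revcomp(mature))
        # point imperfections in the star arm, away from the duplex ends so
        # the terminal loop and the duplex 3' overhangs stay intact
        positions = rng.choice(np.arange(2, m - 2), size=n_imperfections, replace=False)
        for pos in positions:
            partner_base = mature[m - 1 - pos]  # base this position would pair
            pair_arm[pos] = rng.choice(list(_NONPAIRING[partner_base]))
        pair_arm_seq = to_dna("".join(pair_arm))
        flank3 = revcomp(flank5)
        if arm == "5p":
            precursor = flank5 + mature + loop + pair_arm_seq + flank3
            mature_offset = flank_len
            star_offset = flank_len + m + loop_len + 2
        else:
            precursor = flank5 + pair_arm_seq + loop + mature + flank3
            mature_offset = flank_len + m + loop_len
            star_offset = flank_len + 2
        star_seq = precursor[star_offset : star_offset + m]
        frag = HairpinFragment(
            precursor_seq=precursor,
            mature_offset=mature_offset,
            star_offset=star_offset,
            mature_seq=mature,
            star_seq=star_seq,
            arm=arm,
        )
        if _folds_as_designed(frag, n_imperfections):
            return frag
    raise ValueError("could not build a hairpin folding as designed for this mature")


def _folds_as_designed(frag: HairpinFragment, n_imperfections: int) -> bool:
    """Fold-validate a construct: random loops/flanks can occasionally create
    alternative structures that unpair the mature; those draws are rejected."""
    from mirdrought.folding import fold_mfe, hairpin_metrics

    structure = fold_mfe(frag.precursor_seq)
    s = frag.mature_offset + 1
    e = frag.mature_offset + len(frag.mature_seq)
    enclosing = [(i, j) for i, j in structure.pairs if i <= s and j >= e]
    if not enclosing:
        return False
    i0, j0 = min(enclosing)
    comp = [(i, j) for i, j in structure.pairs if i0 <= i and j <= j0]
    sub = dataclasses.replace(
        structure,
        pairs=tuple((i - i0 + 1, j - i0 + 1) for i, j in sorted(comp)),
        seq=frag.precursor_seq[i0 - 1 : j0],
    )
    metrics = hairpin_metrics(sub, (s - i0 + 1, e - i0 + 1))
    return (
        metrics.is_single_hairpin
        and metrics.arm == frag.arm
        and metrics.mature_unpaired_count <= n_imperfections
    )


def generate_genome(config: SimConfig) -> tuple[dict[str, str], list[PlantedMiRNA], dict]:
    """Random genome with planted hairpins at recorded non-overlapping loci.

    Returns (genome, planted novel miRNAs, extras) where extras holds the
    planted "known" miRNAs and ncRNA reference sequences used to exercise
    annotation. Plus- and minus-strand placements alternate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_total = config.n_planted + config.n_known_mirnas
    genome_arr = np.array(list(_random_seq(rng, config.genome_length)))

    # non-overlap by construction: one even slot per inserted element
    n_slots = n_total + config.n_ncrna
    fragments: list[tuple[str, HairpinFragment | str]] = []
    matures_seen: set[str] = set()
    for i in range(n_total):
        while True:
            m_len = int(rng.integers(config.mature_len_range[0], config.mature_len_range[1] + 1))
            mature = _random_seq(rng, m_len)
            if mature not in matures_seen:
                matures_seen.add(mature)
                break
        loop_len = int(rng.integers(4, 13))
        flank_len = int(rng.integers(10, 60))
        n_imp = int(rng.integers(0, 4))
        arm = "5p" if rng.random() < 0.5 else "3p"
        name = f"syn-miR{i + 1:03d}" if i < config.n_planted else f"mtr-miRsim{i - config.n_planted + 1:03d}"
        fragments.append((name, build_hairpin(mature, loop_len, n_imp, rng, flank_len, arm)))
    ncrna_seqs: dict[str, str] = {}
    for i in range(config.n_ncrna):
        ncrna_seqs[f"ncRNA{i + 1:02d}"] = _random_seq(rng, 120)

    slot = config.genome_length // n_slots if n_slots else config.genome_length
    sizes = [len(f.precursor_seq) for _, f in fragments] + [len(s) for s in ncrna_seqs.values()]
    if sizes and slot < max(sizes) + 50:
        raise ValueError("genome too short to place planted elements without overlap")

    planted: list[PlantedMiRNA] = []
    known_records: dict[str, PlantedMiRNA] = {}
    de_labels = ["up"] * config.n_up + ["down"] * config.n_down
    de_labels += ["flat"] * (config.n_planted - len(de_labels))
    insert_items = fragments + [(name, seq) for name, seq in ncrna_seqs.items()]
    for idx, (name, frag) in enumerate(insert_items):
        seq = frag.precursor_seq if isinstance(frag, HairpinFragment) else frag
        lo = idx * slot
        start0 = lo + int(rng.integers(0, slot - len(seq) - 10))
        if isinstance(frag, HairpinFragment):
            strand = "+" if rng.random() < 0.5 else "-"
        else:
            strand = "+"
        inserted = seq if strand == "+" else revcomp(seq)
        genome_arr[start0 : start0 + len(seq)] = list(inserted)
        locus = GenomicLocus(config.chrom_name, start0 + 1, start0 + len(seq), strand)
        if not isinstance(frag, HairpinFragment):
            continue  # ncRNA: sequence recorded in ncrna_seqs, locus implicit
        rate_ck = float(np.exp(rng.uniform(np.log(config.base_rate_low), np.log(config.base_rate_high))))
        if name.startswith("syn-"):
            label = de_labels[len(planted)]
        else:
            label = "flat"
        if label == "up":
            rate_ds = rate_ck * 2.0 ** config.de_log2fc
        elif label == "down":
            rate_ds = rate_ck / 2.0 ** config.de_log2fc
        else:
            rate_ds = rate_ck
        rec = PlantedMiRNA(
            name=name,
            mature_seq=frag.mature_seq,
            star_seq=frag.star_seq,
            precursor_seq=frag.precursor_seq,
            locus=locus,
            arm=frag.arm,
            rate_ck=rate_ck,
            rate_ds=rate_ds,
        )
        if name.startswith("syn-"):
            planted.append(rec)
        else:
            known_records[name] = rec
    genome = {config.chrom_name: "".join(genome_arr)}
    extras = {"known": known_records, "ncrna": ncrna_seqs}
    return genome, planted, extras


def _emit_read(insert: str, config: SimConfig, rng: np.random.Generator, corrupt: bool) -> str:
    adapter = config.adapter3
    if corrupt:
        adapter = _random_seq(rng, len(adapter))
    return (insert + adapter)[: config.read_length]


def simulate_libraries(
    genome: dict[str, str],
    planted: list[PlantedMiRNA],
    config: SimConfig,
    known: dict[str, PlantedMiRNA] | None = None,
    ncrna: dict[str, str] | None = None,
) -> tuple[list[str], list[str]]:
    """Simulate CK and DS read lists (adapter-ligated, fixed read length).

    Mature counts are Poisson(rate); star counts Poisson(rate/star_ratio).
    Background reads are genome-derived fragments with the configured length
    distribution; a ``noise_read_fraction`` of all reads get corrupted
    adapters and are expected to fail the null-adapter filter. Library depths
    are total read counts; a depth of 0 gives an empty library.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    chrom = config.chrom_name
    gseq = genome[chrom]
    lengths = np.array(sorted(config.length_dist))
    probs = np.array([config.length_dist[int(l)] for l in lengths])
    all_mirnas = list(planted) + sorted((known or {}).values(), key=lambda p: p.name)
    ncrna_list = sorted((ncrna or {}).items())

    libraries: list[list[str]] = []
    for lib_idx, depth in enumerate(config.library_depths):
        reads: list[str] = []
        if depth > 0:
            for rec in all_mirnas:
                rate = rec.rate_ck if lib_idx == 0 else rec.rate_ds
                for seq, r in ((rec.mature_seq, rate), (rec.star_seq, rate / config.star_ratio)):
                    for _ in range(rng.poisson(r)):
                        reads.append(seq)
            n_background = max(0, depth - len(reads))
            n_nc = int(round(n_background * config.ncrna_read_fraction)) if ncrna_list else 0
            for _ in range(n_nc):
                _, nseq = ncrna_list[int(rng.integers(len(ncrna_list)))]
                ln = int(rng.choice(lengths, p=probs))
                if ln >= len(nseq):
                    ln = len(nseq) - 1
                pos = int(rng.integers(0, len(nseq) - ln + 1))
                reads.append(nseq[pos : pos + ln])
            for _ in range(n_background - n_nc):
                ln = int(rng.choice(lengths, p=probs))
                pos = int(rng.integers(0, len(gseq) - ln + 1))
                frag = gseq[pos : pos + ln]
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                reads.append(frag)
            rng.shuffle(reads)
        corrupt = rng.random(len(reads)) < config.noise_read_fraction
        libraries.append(
            [_emit_read(insert, config, rng, bool(c)) for insert, c in zip(reads, corrupt)]
        )
    return libraries[0], libraries[1]


def write_truth(path, planted: list[PlantedMiRNA]) -> None:
    with open(path, "w") as fh:
        fh.write("name\tlocus\tarm\tmature_seq\tstar_seq\trate_ck\trate_ds\ttrue_log2fc\n")
        for p in planted:
            fh.write(
                f"{p.name}\t{p.locus}\t{p.arm}\t{p.mature_seq}\t{p.star_seq}\t"
                f"{p.rate_ck:.4f}\t{p.rate_ds:.4f}\t{p.true_log2fc:.4f}\n"
            )


def simulate(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full simulation and write genome, libraries, truth and refs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, planted, extras = generate_genome(config)
    ck, ds = simulate_libraries(genome, planted, config, extras["known"], extras["ncrna"])
    paths = {
        "genome": outdir / "genome.fa",
        "ck": outdir / "lib_CK.fastq",
        "ds": outdir / "lib_DS.fastq",
        "truth": outdir / "truth.tsv",
        "known": outdir / "known_mirnas.fa",
        "ncrna": outdir / "ncrna.fa",
    }
    write_fasta(paths["genome"], sorted(genome.items()))
    write_fastq(paths["ck"], ((f"ck_{i:07d}", r) for i, r in enumerate(ck)))
    write_fastq(paths["ds"], ((f"ds_{i:07d}", r) for i, r in enumerate(ds)))
    write_truth(paths["truth"], planted)
    write_fasta(paths["known"], [(name, rec.mature_seq) for name, rec in sorted(extras["known"].items())])
    write_fasta(paths["ncrna"], sorted(extras["ncrna"].items()))
    return paths
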