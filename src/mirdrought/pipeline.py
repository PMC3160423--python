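"""End-to-end pipeline: reads -> clean tags -> mapping -> annotation ->
novel miRNA discovery -> differential expression -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from mirdrought import annotation, diffexpr, discovery, mapping, preprocess
from mirdrought.sequtil import read_fasta, read_reads

log = logging.getLogger("mirdrought")


@dataclasses.dataclass
class PipelineConfig:
    reads_ck: str = ""
    reads_ds: str = ""
    genome: str = ""
    known_mirnas: str = ""        # FASTA of known matures; optional
    ncrna: str = ""               # FASTA of rRNA/tRNA/snRNA/snoRNA; optional
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    min_overlap: int = 6
    min_len: int = 18
    max_len: int = 30
    max_polya_frac: float = 0.8
    mapper_k: int = 12
    isomir_max_shift: int = 0
    isomir_max_mismatch: int = 0
    mature_len_range: tuple[int, int] = (20, 22)
    discovery_min_count: int = 3
    mfe_threshold: float = -30.0
    max_unpaired: int = 4
    family_dist: int = 3
    min_cpm: float = 1.0
    fold_ratio_threshold: float = 1.5
    alpha: float = 0.05
    alpha_strong: float = 0.01
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if not (0 < self.alpha_strong <= self.alpha <= 1):
            raise ValueError("alphas must satisfy 0 < alpha_strong <= alpha <= 1")
        if self.fold_ratio_threshold < 1:
            raise ValueError("fold_ratio_threshold must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["mature_len_range"] = list(self.mature_len_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mature_len_range" in data:
            data["mature_len_range"] = tuple(data["mature_len_range"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the result bundle into ``config.outdir``.

    Returns a dict with in-memory results (tags, stats, candidates, the DE
    table) and the paths written. Reruns with identical inputs and config
    produce identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- preprocess -------------------------------------------------------
    clean_ck, primary_ck = preprocess.clean_reads(
        read_reads(config.reads_ck), config.adapter3, config.min_overlap,
        config.min_len, config.max_len, config.max_polya_frac,
    )
    clean_ds, primary_ds = preprocess.clean_reads(
        read_reads(config.reads_ds), config.adapter3, config.min_overlap,
        config.min_len, config.max_len, config.max_polya_frac,
    )
    tags = preprocess.collapse_tags(clean_ck, clean_ds)
    stats = {
        "CK": preprocess.LibraryStats(
            primary_reads=primary_ck,
            clean_reads=len(clean_ck),
            unique_sequences=sum(1 for t in tags if t.count_ck),
            length_histogram=preprocess.library_length_histogram(tags, "ck"),
        ),
        "DS": preprocess.LibraryStats(
            primary_reads=primary_ds,
            clean_reads=len(clean_ds),
            unique_sequences=sum(1 for t in tags if t.count_ds),
            length_histogram=preprocess.library_length_histogram(tags, "ds"),
        ),
    }
    log.info("preprocess: %d/%d primary -> %d/%d clean reads, %d unique tags",
             primary_ck, primary_ds, len(clean_ck), len(clean_ds), len(tags))

    # --- mapping ----------------------------------------------------------
    genome = read_fasta(config.genome)
    index = mapping.build_index(genome, k=config.mapper_k)
    mapped_all = mapping.map_tags(index, [t.seq for t in tags])
    mapped_tags = [t for t in tags if mapped_all[t.seq]]
    for lib, attr in (("CK", "count_ck"), ("DS", "count_ds")):
        stats[lib].mapped_reads = sum(getattr(t, attr) for t in mapped_tags)
        stats[lib].mapped_unique = sum(1 for t in mapped_tags if getattr(t, attr))
    log.info("mapping: %d/%d unique tags mapped", len(mapped_tags), len(tags))

    # --- annotation -------------------------------------------------------
    ncrna_seqs = read_fasta(config.ncrna) if config.ncrna else {}
    excluded, retained = annotation.exclude_ncrna(mapped_tags, ncrna_seqs)
    known_matures = read_fasta(config.known_mirnas) if config.known_mirnas else {}
    known_records, unannotated = annotation.match_known_mirna(
        retained, known_matures, config.isomir_max_shift, config.isomir_max_mismatch
    )
    families = annotation.summarize_families(known_records)
    log.info("annotation: %d ncRNA-excluded, %d known-miRNA records, %d unannotated tags",
             len(excluded), len(known_records), len(unannotated))

    # --- discovery --------------------------------------------------------
    disc_cfg = discovery.DiscoveryConfig(
        mature_len_range=config.mature_len_range,
        min_count=config.discovery_min_count,
        mfe_threshold=config.mfe_threshold,
        max_unpaired=config.max_unpaired,
        family_dist=config.family_dist,
    )
    candidates = discovery.discover(
        unannotated, mapped_all, index, known_matures, disc_cfg
    )
    log.info("discovery: %d candidates (%d with miRNA* support)",
             len(candidates), sum(c.has_star_support for c in candidates))

    # --- differential expression -----------------------------------------
    rows = [
        {"id": r.mirna_id, "kind": "known", "count_ck": r.count_ck, "count_ds": r.count_ds}
        for r in known_records
    ] + [
        {"id": c.name, "kind": "novel", "count_ck": c.count_ck, "count_ds": c.count_ds}
        for c in candidates
    ]
    counts = pd.DataFrame(rows, columns=["id", "kind", "count_ck", "count_ds"])
    n1 = max(len(clean_ck), 1)  # zero-depth degenerate libraries still run
    n2 = max(len(clean_ds), 1)
    if len(counts):
        de = diffexpr.classify_de(
            counts, n1, n2, config.min_cpm, config.fold_ratio_threshold,
            config.alpha, config.alpha_strong,
        )
    else:
        de = counts.assign(norm_ck=[], norm_ds=[], log2fc=[], regularized=[],
                           p=[], p_adj=[], regulation=[], tier=[])
    log.info("diffexpr: %d analyzed, %d up, %d down",
             len(de), int((de["regulation"] == "up").sum()), int((de["regulation"] == "down").sum()))

    # --- outputs ----------------------------------------------------------
    paths = {k: outdir / v for k, v in {
        "tags": "tags.tsv", "stats": "stats.json", "lengths": "lengths.tsv",
        "alignments": "alignments.tsv", "known": "known_mirnas.tsv",
        "families": "families.tsv", "novel": "novel_mirnas.tsv",
        "de": "de_results.tsv", "report": "report.txt", "manifest": "manifest.json",
    }.items()}
    preprocess.write_tags(paths["tags"], tags)
    preprocess.write_stats(paths["stats"], stats)
    with open(paths["lengths"], "w") as fh:
        fh.write("length\ttotal_reads\tunique_sequences\n")
        total = preprocess.length_distribution(tags, "total")
        uniq = preprocess.length_distribution(tags, "unique")
        for ln in sorted(total):
            fh.write(f"{ln}\t{total[ln]}\t{uniq.get(ln, 0)}\n")
    mapping.write_alignments(paths["alignments"], {t.seq: mapped_all[t.seq] for t in mapped_tags})
    annotation.write_known(paths["known"], known_records)
    annotation.write_families(paths["families"], families)
    discovery.write_novel(paths["novel"], candidates)
    diffexpr.write_de(paths["de"], de)
    novel_df = pd.read_csv(paths["novel"], sep="\t")
    with open(paths["report"], "w") as fh:
        fh.write(report_tables(stats, novel_df))
    with open(paths["manifest"], "w") as fh:
        from mirdrought import __version__

        json.dump({"version": __version__, "config_hash": config.config_hash(),
                   "seed": config.seed,
                   "records": {"tags": len(tags), "known": len(known_records),
                                "candidates": len(candidates), "de": len(de)}},
                  fh, indent=2)

    return {
        "tags": tags, "stats": stats, "known": known_records, "families": families,
        "candidates": candidates, "de": de, "paths": paths,
        "clean_totals": (len(clean_ck), len(clean_ds)),
    }


def report_tables(stats: dict[str, preprocess.LibraryStats], novel_df: pd.DataFrame) -> str:
    """Library-statistics and novel-miRNA summaries as aligned text tables."""
    lines = ["Statistics of sRNA sequences", ""]
    lines.append("\t".join(["library", "primary_reads", "clean_reads",
                            "unique_sequences", "mapped_reads", "mapped_unique"]))
    for lib, st in stats.items():
        lines.append("\t".join(str(v) for v in [
            lib, st.primary_reads, st.clean_reads, st.unique_sequences,
            st.mapped_reads, st.mapped_unique]))
    lines += ["", "Novel miRNAs / new members of known families", ""]
    if len(novel_df):
        lines.append("\t".join(str(c) for c in novel_df.columns))
        for _, row in novel_df.iterrows():
            lines.append("\t".join("" if pd.isna(v) else str(v) for v in row))
    else:
        lines.append("(none)")
    return "\n".join(lines) + "\n"
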