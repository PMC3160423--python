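import pandas as pd
import pytest

from mirdrought.pipeline import PipelineConfig, run_pipeline
from mirdrought.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic study plus one full pipeline run, shared read-only."""
    root = tmp_path_factory.mktemp("small_study")
    sim_cfg = SimConfig(
        genome_length=60_000,
        n_planted=6,
        n_up=1,
        n_down=1,
        base_rate_low=150,
        base_rate_high=600,
        library_depths=(6_000, 6_000),
        n_known_mirnas=3,
        n_ncrna=2,
        seed=42,
    )
    paths = simulate(sim_cfg, root / "sim")
    pipe_cfg = PipelineConfig(
        reads_ck=str(paths["ck"]),
        reads_ds=str(paths["ds"]),
        genome=str(paths["genome"]),
        known_mirnas=str(paths["known"]),
        ncrna=str(paths["ncrna"]),
        outdir=str(root / "results"),
        seed=42,
    )
    bundle = run_pipeline(pipe_cfg)
    truth = pd.read_csv(paths["truth"], sep="\t")
    return {
        "sim_cfg": sim_cfg,
        "paths": paths,
        "pipe_cfg": pipe_cfg,
        "bundle": bundle,
        "truth": truth,
    }
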