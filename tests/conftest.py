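import json
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

import tagcascade as tc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_mock(tmp_path_factory):
    """An 8-taxon even mock (3 samples x 800 pairs) with written files."""
    cfg = tc.MockConfig(n_taxa=8, n_reads=800, n_samples=3, seed=7)
    run = tc.simulate_reads(cfg)
    outdir = tmp_path_factory.mktemp("mock")
    paths = run.write(outdir)
    return cfg, run, paths


def make_pipeline_config(cfg, paths, workdir, seed=3):
    return tc.PipelineConfig(
        workdir=workdir,
        read_mode="paired",
        r1=paths["r1"],
        r2=paths["r2"],
        reference_fasta=paths["references"],
        tree=paths["tree"],
        primer_fwd=cfg.primer_fwd,
        primer_rev=cfg.primer_rev,
        rarefaction_depth=300,
        rarefaction_reps=50,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_pipeline(small_mock, tmp_path_factory):
    """The small mock processed end to end; yields (config, report, run)."""
    cfg, run, paths = small_mock
    workdir = tmp_path_factory.mktemp("work")
    pcfg = make_pipeline_config(cfg, paths, workdir)
    report = tc.run_pipeline(pcfg)
    assert not report.failed and not report.blocked
    return pcfg, report, run


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
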