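"""Shared fixtures: a small planted replicon and one pipeline run over it."""

from __future__ import annotations

import pytest

from ncscribe.pipeline import PipelineConfig, run_pipeline
from ncscribe.synthetic import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """20 kb replicon with 4 planted transcripts (one per category cycle)."""
    return make_fixture(FixtureSpec(genome_length=20000, n_planted=4, seed=7))


@pytest.fixture(scope="session")
def fixture_dir(small_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return small_fixture.write(outdir)


@pytest.fixture(scope="session")
def pipeline_run(fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    config = PipelineConfig(genome=str(fixture_dir["fasta"]),
                            genes=str(fixture_dir["ptt"]),
                            loci=str(fixture_dir["loci"]),
                            output_dir=str(out),
                            sidd_window=2000, sidd_step=1000)
    return config, run_pipeline(config)
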