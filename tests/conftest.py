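"""Shared fixtures: a small simulated study bundle and its pipeline run."""

from __future__ import annotations

import json

import pandas as pd
import pytest

from msidyn.pipeline import RunConfig, run_all
from msidyn.simulate import small_config, simulate_all

SIM_SEED = 11


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Small synthetic bundle (1 Mb, 6+6 cells) with ground truth."""
    out = tmp_path_factory.mktemp("sim")
    cfg = small_config(SIM_SEED)
    truth = simulate_all(cfg, out)
    return cfg, out, truth


@pytest.fixture(scope="session")
def pipeline_run(sim_bundle, tmp_path_factory):
    """Full pipeline executed on the small bundle."""
    cfg, sim_dir, truth = sim_bundle
    out = tmp_path_factory.mktemp("run")
    rc = RunConfig(
        fasta=str(sim_dir / "genome.fa"),
        regions=str(sim_dir / "regions.bed"),
        samples=str(sim_dir / "cells" / "samples.tsv"),
        genes_gtf=str(sim_dir / "genes.gtf"),
        pol2_bed=str(sim_dir / "pol2.bed"),
        repliseq_tsv=str(sim_dir / "repliseq.tsv"),
        out_dir=str(out),
    )
    summary = run_all(rc)
    return rc, out, summary


@pytest.fixture(scope="session")
def truth_events(sim_bundle) -> pd.DataFrame:
    _, _, truth = sim_bundle
    return pd.DataFrame(truth["events"])


@pytest.fixture(scope="session")
def run_events(pipeline_run) -> pd.DataFrame:
    _, out, _ = pipeline_run
    return pd.read_csv(out / "events.tsv", sep="\t")
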