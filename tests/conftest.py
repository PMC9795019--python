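"""Shared fixtures: one full synthetic pipeline run per session."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pytest

from peonymir import pipeline
from peonymir.smallrna_catalog import GenomeIndex
from peonymir.synthetic_data import (
    SimulationConfig,
    read_fasta,
    truth_from_json,
)

SESSION_SEED = 1


@pytest.fixture(scope="session")
def run_dir(tmp_path_factory) -> Path:
    """Full end-to-end pipeline run on the default synthetic dataset."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    cfg = pipeline.load_config(seed=SESSION_SEED)
    pipeline.run(cfg, outdir)
    return outdir


@pytest.fixture(scope="session")
def truth(run_dir):
    return truth_from_json(json.loads((run_dir / "truth.json").read_text()))


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def genome(run_dir) -> dict[str, str]:
    return read_fasta(run_dir / "genome.fasta")


@pytest.fixture(scope="session")
def genome_index(genome) -> GenomeIndex:
    return GenomeIndex(genome)


@pytest.fixture(scope="session")
def mature_ref(run_dir) -> dict[str, str]:
    return read_fasta(run_dir / "mature_ref.fasta")


@pytest.fixture(scope="session")
def precursor_ref(run_dir) -> dict[str, str]:
    return read_fasta(run_dir / "precursor_ref.fasta")


@pytest.fixture(scope="session")
def transcripts(run_dir) -> dict[str, str]:
    return read_fasta(run_dir / "transcripts.fasta")


@pytest.fixture(scope="session")
def catalog(run_dir) -> pd.DataFrame:
    return pd.read_csv(run_dir / "catalog.tsv", sep="\t", index_col="sequence")


@pytest.fixture(scope="session")
def mirna_records(run_dir) -> pd.DataFrame:
    return pd.read_csv(run_dir / "mirna_records.tsv", sep="\t")


@pytest.fixture(scope="session")
def validated(run_dir) -> pd.DataFrame:
    return pd.read_csv(run_dir / "validated_cleavages.tsv", sep="\t")


@pytest.fixture(scope="session")
def modules(run_dir) -> pd.DataFrame:
    return pd.read_csv(run_dir / "modules.tsv", sep="\t")
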