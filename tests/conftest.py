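"""Shared fixtures: one small simulated study reused across the suite."""

from pathlib import Path

import pandas as pd
import pytest

from ovamir import (
    SimulationConfig,
    build_reference,
    clean_and_collapse,
    quantify_mirnas,
    simulate_counts,
    simulate_reads,
    simulate_truth,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_mirnas=30, library_sizes=(20_000, 20_000), seed=7)


@pytest.fixture(scope="session")
def bundle(small_config):
    return build_reference(small_config)


@pytest.fixture(scope="session")
def truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def counts(small_config, truth):
    return simulate_counts(small_config, truth)


@pytest.fixture(scope="session")
def fastq_paths(small_config, bundle, counts, tmp_path_factory):
    out = tmp_path_factory.mktemp("reads")
    return simulate_reads(small_config, bundle, counts, out)


@pytest.fixture(scope="session")
def clean_libs(small_config, fastq_paths):
    return {
        name: clean_and_collapse(path, adapter=small_config.adapter, name=name)
        for name, path in fastq_paths.items()
    }


@pytest.fixture(scope="session")
def annotation(clean_libs, bundle):
    a, b = clean_libs.values()
    return quantify_mirnas(a, b, bundle)


@pytest.fixture(scope="session")
def printed_de_table():
    """The published >4-fold DE miRNA table (fold magnitudes with directions)."""
    return pd.read_csv(DATA_DIR / "ovary_de_table_printed.tsv", sep="\t", index_col=0)
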