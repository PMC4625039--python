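import numpy as np
import pandas as pd
import pytest

from polyherit import CohortData, GeneModel, SimulationConfig
from polyherit import synthetic as syn


def make_snp_table(positions, chrom="1", freq=0.3):
    positions = np.asarray(positions)
    freq = np.broadcast_to(np.asarray(freq, dtype=float), positions.shape)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "a1": "A",
            "a2": "G",
            "freq": freq,
            "info": 1.0,
        }
    )


def make_cohort(dosages, positions=None, chrom="1", phenotype=None):
    dosages = np.asarray(dosages, dtype=float)
    if positions is None:
        positions = np.arange(1, dosages.shape[1] + 1) * 1000
    freq = dosages.mean(axis=0) / 2.0
    table = make_snp_table(positions, chrom=chrom, freq=freq)
    return CohortData(dosages=dosages, snp_table=table, phenotype=phenotype)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_individuals=500, n_snps=400, within_block_rho=0.5, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    return syn.simulate_study(small_config, n_genes=3)


@pytest.fixture
def toy_genes():
    return [
        GeneModel("geneA", "1", 10_000, 20_000, "+", coding=[(12_000, 14_000)]),
        GeneModel("geneB", "1", 60_000, 80_000, "-", coding=[(65_000, 70_000)]),
    ]
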