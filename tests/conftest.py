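"""Shared fixtures: small synthetic cohorts, genomes and tables.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk except files the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from panelforge import synthetic_data as sd


@pytest.fixture(scope="session")
def small_panel() -> sd.GenotypePanel:
    """Two populations, 10 samples each, 200 loci, F = 0.1."""
    model = sd.PopulationModel(
        n_pops=2, n_per_pop=10, fst=0.1, n_snps_per_chrom=200, seed=101
    )
    return sd.simulate_populations(model)


@pytest.fixture(scope="session")
def three_pop_panel() -> sd.GenotypePanel:
    """Three populations for pairwise-union AIM selection tests."""
    model = sd.PopulationModel(
        n_pops=3, n_per_pop=20, fst=0.05, n_snps_per_chrom=300,
        chrom_names=("chr1", "chr2"), seed=202,
    )
    return sd.simulate_populations(model)


@pytest.fixture(scope="session")
def clean_genome() -> tuple[dict[str, str], dict]:
    """Pure random 60 kb genome, no planted repeats or decoys."""
    spec = sd.GenomeSpec(chrom_lengths={"chr1": 60_000}, seed=301)
    return sd.simulate_reference(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
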