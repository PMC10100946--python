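import numpy as np
import pandas as pd
import pytest

from oralgut import (
    GeneAbundanceTable,
    MSPAbundanceTable,
    SimulationConfig,
    build_catalogue_pair,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A miniature but fully featured scenario (runs in well under a second)."""
    return SimulationConfig(
        n_gut_only=20,
        n_oral_only=12,
        n_shared=4,
        markers_per_msp=20,
        genes_per_msp=30,
        sequencing_depth=20_000,
        seed=7,
    )


@pytest.fixture
def small_catalogue(small_config):
    return build_catalogue_pair(small_config)


def random_msp_table(rng, n_msps=6, n_samples=4, normalized=False, zero_fraction=0.3):
    values = rng.gamma(1.0, 2.0, size=(n_msps, n_samples))
    values[rng.random(values.shape) < zero_fraction] = 0.0
    # keep every column detectable
    for j in range(n_samples):
        if values[:, j].sum() == 0:
            values[rng.integers(n_msps), j] = 1.0
    if normalized:
        values = values / values.sum(axis=0)
    return MSPAbundanceTable(
        abundance=pd.DataFrame(
            values,
            index=[f"msp_{i:03d}" for i in range(n_msps)],
            columns=[f"s{j}" for j in range(n_samples)],
        ),
        normalized=normalized,
    )


def random_gene_table(rng, n_genes=50, n_samples=3, with_unassigned=True, max_count=40):
    counts = rng.integers(0, max_count, size=(n_genes, n_samples)).astype(float)
    unassigned = (
        pd.Series(
            rng.integers(0, max_count, size=n_samples).astype(float),
            index=[f"s{j}" for j in range(n_samples)],
        )
        if with_unassigned
        else None
    )
    return GeneAbundanceTable(
        counts=pd.DataFrame(
            counts,
            index=[f"g{i:04d}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        ),
        unassigned=unassigned,
    )
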