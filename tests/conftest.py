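import numpy as np
import pytest
from hypothesis import settings

from plasticitome.io_formats import ExpressionMatrix
from plasticitome.pipeline import tpm_matrix
from plasticitome.rank_norm import rank_matrix
from plasticitome.plasticity import gene_stats_table, merge_platforms
from plasticitome.synthetic_data import (
    SyntheticConfig,
    generate_bulk,
    generate_singlecell,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def bulk_data(config):
    """(array matrix, count matrix, lengths, truth) from one fixed seed."""
    return generate_bulk(config)


@pytest.fixture(scope="session")
def rnaseq_ranks(bulk_data):
    _, rna, lengths, _ = bulk_data
    return rank_matrix(tpm_matrix(rna, lengths))


@pytest.fixture(scope="session")
def array_ranks(bulk_data):
    arr, *_ = bulk_data
    return rank_matrix(arr)


@pytest.fixture(scope="session")
def merged_stats(array_ranks, rnaseq_ranks):
    merged, pearson = merge_platforms(
        gene_stats_table(array_ranks), gene_stats_table(rnaseq_ranks)
    )
    return merged, pearson


@pytest.fixture(scope="session")
def sc_matrix(config, bulk_data) -> ExpressionMatrix:
    *_, truth = bulk_data
    return generate_singlecell(config, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
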