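import numpy as np
import pytest

from ribotradeoff import (
    SyntheticSpec,
    generate_genome,
    packaged_time_table,
    uniform_time_table,
)
from ribotradeoff.sequence_io import trim_genome


@pytest.fixture(scope="session")
def ecoli_table():
    return packaged_time_table("synthetic_ecoli")


@pytest.fixture(scope="session")
def uniform_table():
    return uniform_time_table()


@pytest.fixture(scope="session")
def pars_genome(ecoli_table):
    """Small PARS-channel synthetic genome with a strong planted coupling."""
    spec = SyntheticSpec(
        n_genes=30,
        gene_len_codons=120,
        block_len_nt=60,
        beta=0.75,
        time_table=ecoli_table,
        seed=42,
    )
    return generate_genome(spec)


@pytest.fixture(scope="session")
def pars_trimmed(pars_genome):
    return trim_genome(pars_genome.genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
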