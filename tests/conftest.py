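import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """3 samples x 2 SNPs with classes (0, 1, 1)."""
    from seei import GenotypeDataset

    return GenotypeDataset(
        genotypes=np.array([[0, 1], [2, 0], [1, 1]]),
        phenotype=np.array([0, 1, 1]),
        snp_ids=["rs1", "rs2"],
    )


@pytest.fixture(scope="session")
def xor_dataset():
    """200-sample panel from the XOR fixture with an embedded pair."""
    from seei import SimulationConfig, generate_dataset, parity_model

    model = parity_model(2, 0.1, label="xor")
    sim = SimulationConfig(n_cases=100, n_controls=100, n_snps=30, seed=7)
    ds, truth = generate_dataset(model, sim)
    return ds, truth


def random_tables(n, rng, max_rows=9, max_count=50):
    """Random small I x 2 count tables (at least one sample each)."""
    tables = []
    while len(tables) < n:
        rows = rng.integers(1, max_rows + 1)
        counts = rng.integers(0, max_count, size=(rows, 2))
        if counts.sum() > 0:
            tables.append(counts)
    return tables
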