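import numpy as np
import pytest

from exsitu import (
    ArchipelagoConfig,
    GenotypeDataset,
    compute_allele_frequencies,
    generate_reference_panel,
)


@pytest.fixture(scope="session")
def small_panel():
    """4 populations x 6 loci, complete data — fast fixture for unit tests."""
    cfg = ArchipelagoConfig(
        n_populations=4,
        n_loci=6,
        alleles_per_locus=6,
        ref_sample_size=25,
        missing_rate=0.0,
        seed=11,
    )
    return generate_reference_panel(cfg)


@pytest.fixture(scope="session")
def small_table(small_panel):
    return compute_allele_frequencies(small_panel.dataset)


@pytest.fixture(scope="session")
def panel17():
    """Default study-scale panel: 17 populations x 9 loci x 30 individuals."""
    return generate_reference_panel(ArchipelagoConfig(seed=1))


def random_dataset(seed: int, n_pops=3, n_loci=4, n_per_pop=6, missing_rate=0.1):
    """Small random dataset built through the public simulator."""
    cfg = ArchipelagoConfig(
        n_populations=n_pops,
        n_loci=n_loci,
        alleles_per_locus=5,
        ref_sample_size=n_per_pop,
        missing_rate=missing_rate,
        seed=seed,
    )
    return generate_reference_panel(cfg).dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)
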