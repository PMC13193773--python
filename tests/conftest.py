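import numpy as np
import pytest

from caprigen import (
    SimulationConfig,
    pedigree_from_records,
    simulate_dataset,
    simulate_pedigree,
)


@pytest.fixture(scope="session")
def trio():
    return pedigree_from_records(
        [("A", None, None), ("B", None, None), ("C", "A", "B")]
    )


@pytest.fixture(scope="session")
def small_config():
    """Small herd: ~60 terminal-generation does carry records."""
    return SimulationConfig(
        n_founder_sires=5, n_founder_dams=60, n_generations=3, seed=42
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def random_pedigrees():
    """A batch of random multi-generation pedigrees with inbreeding."""
    peds = []
    for seed in range(6):
        cfg = SimulationConfig(
            n_founder_sires=3, n_founder_dams=20, n_generations=3, seed=seed
        )
        peds.append(simulate_pedigree(cfg))
    return peds


def founders_only(n, prefix="A"):
    return pedigree_from_records([(f"{prefix}{i}", None, None) for i in range(n)])
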