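import numpy as np
import pytest

from spdeg import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A compact planted cohort: one 30-patient subgroup in 100 cases."""
    return SimulationConfig(
        n_controls=60,
        n_patients=100,
        n_genes=300,
        n_snps=150,
        n_subgroups=1,
        subgroup_size=30,
        n_signature_genes=25,
        log2_effect=1.5,
        maf_range=(0.2, 0.3),
        subgroup_or=3.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
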