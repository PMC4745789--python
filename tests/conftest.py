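import pytest
from hypothesis import HealthCheck, settings

from sescreen import SyntheticConfig, simulate_dataset

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# A reduced landscape for fast unit tests; recovery statistics are always
# measured on the default configuration (see test_acceptance.py).
SMALL_LANDSCAPE = dict(
    n_chromosomes=2,
    chrom_length=1_000_000,
    n_typical=40,
    n_super=3,
    n_genes=60,
    n_screen_genes=50,
    n_lines=12,
    n_target_lines=4,
    n_selective_genes=2,
    n_driver_genes=1,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=11, **SMALL_LANDSCAPE)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, with_sequence=True)
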