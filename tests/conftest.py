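import pytest

from msiscan import SimulationConfig, simulate_study

# compact study used across tests: 2 scaffolds, 24 planted repeats of which
# 18 carry variants, a modest SNP background, and a few filter-failing sites
SMALL_CONFIG = SimulationConfig(
    n_scaffolds=2,
    scaffold_length=30_000,
    n_planted_msats=24,
    n_dose_dependent=6,
    n_non_dose=6,
    n_shared=6,
    n_neutral_snps=40,
    n_low_mq=3,
    n_low_dp=3,
    mean_depth=120.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)
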