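import pytest
from hypothesis import settings

from ipqc.synthetic_data import (
    SyntheticConfig,
    fit_predictor,
    generate_proteome,
    generate_run,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

SEED = 7


@pytest.fixture(scope="session")
def config():
    """Default study conditions: two disjoint-anchor alleles, 15% noise,
    9mer-peaked lengths, 1000 peptides per run."""
    return SyntheticConfig(seed=SEED)


@pytest.fixture(scope="session")
def proteome(config):
    return generate_proteome(config)


@pytest.fixture(scope="session")
def predictor(config):
    """PSSM predictor fitted on the default synthetic alleles (10k-peptide
    rank calibration keeps the suite fast)."""
    return fit_predictor(config, n_background=10_000)


@pytest.fixture(scope="session")
def run_and_truth(config, proteome):
    return generate_run(config, proteome)
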