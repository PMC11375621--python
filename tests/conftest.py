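import warnings

import pytest

from ntsprio.features import ExperimentDesign, run_cascade
from ntsprio.synthetic import SyntheticConfig, simulate_experiment


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Default (noise-free) synthetic experiment, shared across tests."""
    return simulate_experiment(SyntheticConfig(seed=7), seed=7)


@pytest.fixture(scope="session")
def cascade_result(noise_free_bundle):
    b = noise_free_bundle
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_cascade(b.features, b.design, spectra=b.spectra, eics=b.eics)


@pytest.fixture
def triplicate_design():
    return ExperimentDesign(
        samples={"S1": ["S1_r1", "S1_r2", "S1_r3"], "S2": ["S2_r1", "S2_r2", "S2_r3"]},
        blanks=["B1", "B2"],
    )
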