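import pytest

from sodium_cra.scenarios import Inputs
from sodium_cra.synthetic import SynthConfig


@pytest.fixture(scope="session")
def synth_config() -> SynthConfig:
    """Small but fully populated study: 24 strata, 12 categories, 10 companies."""
    return SynthConfig(
        seed=7, n_persons=300, n_products_per_category=15, n_companies=10
    )


@pytest.fixture(scope="session")
def inputs(synth_config) -> Inputs:
    return Inputs.synthetic(synth_config)
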