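import pytest

from saplingniche import (
    GeneratorConfig,
    gen_provenance_dataset,
    reference_annual_model,
)


@pytest.fixture(scope="session")
def truth_model():
    return reference_annual_model()


@pytest.fixture(scope="session")
def default_dataset():
    """One realization of the default provenance-trial generator."""
    return gen_provenance_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def noise_free_dataset():
    return gen_provenance_dataset(
        GeneratorConfig(noise_sd=0.0, specialist_extra_sd=0.0, seed=2)
    )
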