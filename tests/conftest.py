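import pytest

from troutrisk.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def survey_dataset():
    """Default synthetic dataset at the survey design (432 records)."""
    return generate(GeneratorConfig(seed=7))
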