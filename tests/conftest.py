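import pytest

from hgrisk import calibrate_defaults, generate_survey


@pytest.fixture(scope="session")
def default_config():
    """Packaged default generator calibration (deterministic to solve)."""
    return calibrate_defaults()


@pytest.fixture(scope="session")
def default_survey(default_config):
    """One default 49-specimen synthetic survey with a fixed seed."""
    return generate_survey(default_config, seed=11)
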