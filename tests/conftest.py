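import numpy as np
import pytest

from telodyn.synthetic import StudyConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One study drawn at the default (study-scale) configuration."""
    return generate_study(StudyConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_study():
    """Zero replicate noise, no year/drought structure: exact round trips."""
    cfg = StudyConfig(seed=12, qpcr_noise_sd=0.0, sigma_year=0.0, drought_rtl_effect=0.0)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
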