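import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

from bivalbind import presets
from bivalbind.fitting import PARAM_NAMES, normalize_dataset
from bivalbind.synthetic import NoiseModel, default_design, generate


@pytest.fixture(scope="session")
def best_fit():
    return presets.best_fit_params()


@pytest.fixture(scope="session")
def truth_log10(best_fit):
    return np.log10([getattr(best_fit, name) for name in PARAM_NAMES])


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def clean_dataset(design, best_fit):
    """Noise-free 77-point dataset generated from the best-fit parameters."""
    return generate(
        design, best_fit, NoiseModel(kind="none", sigma=0.0), scale=1e3, seed=0
    )


@pytest.fixture(scope="session")
def clean_normalized(clean_dataset):
    return normalize_dataset(clean_dataset.frame)
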