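import numpy as np
import pytest

from oncocea.cli_io import load_config
from oncocea.survival_models import ParametricSurvival

#: Published best-fit log-normal (meanlog, sdlog) per (arm, endpoint).
TABLE1 = {
    ("combo", "PFS"): (1.660, 0.850),
    ("combo", "OS"): (2.398, 0.808),
    ("mono", "PFS"): (1.110, 0.644),
    ("mono", "OS"): (2.030, 0.793),
}


@pytest.fixture(scope="session")
def default_config():
    return load_config()


@pytest.fixture(scope="session")
def base_case(default_config):
    return default_config.case


@pytest.fixture(scope="session")
def table1_models():
    return {k: ParametricSurvival("lognormal", mu, sd) for k, (mu, sd) in TABLE1.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
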