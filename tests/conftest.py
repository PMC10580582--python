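import numpy as np
import pytest

from psmcea.config import default_config

# Table-style base-case curve parameters used across tests
CURVES = {
    ("NI", "PFS"): ("log_normal", 1.93843, 1.26135),
    ("C", "PFS"): ("log_logistic", 7.53780, 2.29427),
    ("NI", "A"): ("weibull_ph", 0.0241553, 1.1284343),
    ("NI", "E"): ("log_logistic", 19.01452, 1.51241),
    ("NI", "N"): ("exponential", 0.0412831, None),
    ("C", "A"): ("log_logistic", 14.25065, 1.76236),
    ("C", "E"): ("log_logistic", 16.70245, 1.70694),
    ("C", "N"): ("log_logistic", 9.03382, 2.17796),
}


@pytest.fixture
def base_cfg():
    return default_config()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230743)
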