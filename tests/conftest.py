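import numpy as np
import pytest

from mbwsim.petal_pattern import DomainLayout, default_params
from mbwsim.rd_core import NetworkParams
from mbwsim.transcriptome import build_panel


@pytest.fixture(scope="session")
def symmetric_params() -> NetworkParams:
    """sigma = 0, kappa = 0, all rates 1, n = 2: steady state (1, 1)."""
    return NetworkParams()


@pytest.fixture(scope="session")
def stable_symmetric_params() -> NetworkParams:
    """Same (1, 1) steady state but asymptotically stable (mu_i > mu_a)."""
    return NetworkParams(mu_i=2.0, rho_i=2.0)


@pytest.fixture(scope="session")
def pattern_params() -> NetworkParams:
    """The shipped Turing-capable petal-patterning kinetics."""
    return default_params()


@pytest.fixture(scope="session")
def petal_layout() -> DomainLayout:
    return DomainLayout.default()


@pytest.fixture(scope="session")
def fig5c_panel():
    return build_panel()


def draw_valid_params(rng: np.random.Generator, **overrides) -> NetworkParams:
    """A random valid parameter set spanning the documented ranges."""
    raw = dict(
        sigma_a=rng.uniform(0, 0.5),
        sigma_i=rng.uniform(0, 0.5),
        rho_a=rng.uniform(0.2, 5.0),
        rho_i=rng.uniform(0.2, 5.0),
        mu_a=rng.uniform(0.2, 5.0),
        mu_i=rng.uniform(0.2, 5.0),
        kappa=rng.uniform(0, 0.5),
        n_coop=rng.uniform(1.0, 3.0),
    )
    raw.update(overrides)
    return NetworkParams(**raw)
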