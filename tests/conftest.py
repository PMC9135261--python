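"""Shared fixtures: the three reference parameter regimes used throughout.

* symmetric deep double well (F=0, J=10, N=100): modes pinned at m = +-1;
* asymmetric deep well (F=0.1, J=5, N=50): lock-in with an exponentially
  suppressed sub-optimal mode;
* shallow bimodal (F=0.025, J=1.5, N=50): both modes carry mass and the
  relaxation time is numerically resolvable — the calibration regime.
"""

import numpy as np
import pytest

from lockin import ModelParams, RateTable, propensities


@pytest.fixture(scope="session")
def symmetric_deep_params() -> ModelParams:
    return ModelParams(F=0.0, J=10.0, alpha=0.0, beta=1.0, gamma=1.0, N=100)


@pytest.fixture(scope="session")
def asymmetric_deep_params() -> ModelParams:
    return ModelParams(F=0.1, J=5.0, alpha=0.0, beta=1.0, gamma=1.0, N=50)


@pytest.fixture(scope="session")
def shallow_bimodal_params() -> ModelParams:
    return ModelParams(F=0.025, J=1.5, alpha=0.0, beta=1.0, gamma=1.0, N=50)


@pytest.fixture(scope="session")
def symmetric_deep_rates(symmetric_deep_params) -> RateTable:
    return propensities(symmetric_deep_params)


@pytest.fixture(scope="session")
def asymmetric_deep_rates(asymmetric_deep_params) -> RateTable:
    return propensities(asymmetric_deep_params)


@pytest.fixture(scope="session")
def shallow_bimodal_rates(shallow_bimodal_params) -> RateTable:
    return propensities(shallow_bimodal_params)


def random_rate_table(rng: np.random.Generator, n_max: int = 20) -> RateTable:
    """A random strictly positive (irreducible) birth-death chain."""
    N = int(rng.integers(3, n_max + 1))
    birth = np.concatenate([rng.uniform(0.1, 3.0, N), [0.0]])
    death = np.concatenate([[0.0], rng.uniform(0.1, 3.0, N)])
    return RateTable(birth=birth, death=death)
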