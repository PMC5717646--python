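import logging

import numpy as np
import pytest

from tcrkp import ModelParams

logging.getLogger("tcrkp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tristable_params() -> ModelParams:
    """Agonist-only N=3 instance with three positive steady states."""
    return ModelParams(alpha=1.0, beta=1.0, gamma=1.0, phi=1.0, b=0.0,
                       kappa=2e-4, nu1=1e-4, nu2=1.0, L1=1.0, L2=0.0,
                       R=1.0, ST=10.0, N=3)


@pytest.fixture(scope="session")
def dose_response_params() -> ModelParams:
    """Instance whose dose-response curve shows all four regimes."""
    return ModelParams(alpha=1.0, ST=6e5, beta=5e2, kappa=1e-4, R=3e4,
                       b=4e-2, gamma=1.2e-6, phi=9e-2, nu1=1e-2, nu2=1.0,
                       L1=1.0, L2=0.0, N=3)


@pytest.fixture(scope="session")
def optimal_nu1_params() -> ModelParams:
    """Instance with an interior optimum of C3 over nu1."""
    return ModelParams(alpha=1e-1, ST=1e7, beta=10.0, kappa=1e-6, R=1e5,
                       b=1e-2, gamma=1e-4, phi=1e-2, nu1=1e-2, nu2=1.0,
                       L1=1e3, L2=0.0, N=3)


def random_params(rng: np.random.Generator, N: int | None = None,
                  b_zero: bool = False, L2: float = 0.0) -> ModelParams:
    """Moderate log-uniform parameter draw for property tests."""
    u = lambda lo, hi: 10 ** rng.uniform(np.log10(lo), np.log10(hi))
    return ModelParams(
        alpha=u(1e-2, 1e2), beta=u(1e-2, 1e2), gamma=u(1e-2, 1e2),
        phi=u(1e-2, 1e2), b=0.0 if b_zero else u(1e-3, 1e1),
        kappa=u(1e-4, 1e0), nu1=u(1e-4, 1e1), nu2=u(1e-4, 1e1),
        L1=u(1e-1, 1e2), L2=L2, R=u(1e-1, 1e2), ST=u(1e-1, 1e3),
        N=int(N if N is not None else rng.integers(1, 5)))
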