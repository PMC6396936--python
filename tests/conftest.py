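import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from resistmc import (
    ModelParameters,
    detection_distribution_approx,
    detection_distribution_exact,
    division_death_table,
    mutation_rate_table,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# (lambda, alpha) pairs A-D used throughout the accuracy comparisons,
# always with mu = beta = 1 and gamma = 1e-5.
RATE_PAIRS = {"A": (2.0, 2.0), "B": (4.0, 4.0), "C": (2.0, 3.0), "D": (3.0, 5.0)}


def pair_params(lam: float, alpha: float, gamma: float = 1e-5) -> ModelParameters:
    return ModelParameters(lam, 1.0, alpha, 1.0, gamma)


def random_valid_params(rng: np.random.Generator) -> ModelParameters:
    return ModelParameters(
        lambda_div=rng.uniform(0.5, 4.0),
        mu_death=rng.uniform(0.0, 2.0),
        alpha_div=rng.uniform(0.5, 4.0),
        beta_death=rng.uniform(0.0, 2.0),
        gamma_mut=rng.uniform(0.0, 0.3),
    )


@pytest.fixture(scope="session")
def division_death_frame():
    """3x3 resistance-probability table over rate ratios (nominal M = 10^4)."""
    return division_death_table()


@pytest.fixture(scope="session")
def mutation_rate_frame():
    """4x3 resistance-probability table over mutation rates (nominal M = 10^4)."""
    return mutation_rate_table()


@pytest.fixture(scope="session")
def exact_m500():
    """Exact resistance probabilities at M = 500 for the four rate pairs."""
    import warnings

    values = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for name, (lam, alpha) in RATE_PAIRS.items():
            values[name] = detection_distribution_exact(pair_params(lam, alpha), 500).p_resistance
    return values


@pytest.fixture(scope="session")
def approx_m500():
    """Aggregated (m = 100) resistance probabilities at M = 500, pairs A-D."""
    return {
        name: detection_distribution_approx(pair_params(lam, alpha), 500, 100).p_resistance
        for name, (lam, alpha) in RATE_PAIRS.items()
    }
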