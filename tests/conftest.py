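import numpy as np
import pytest

from qpcropt import (
    DEFAULT_FACTORS,
    default_spec,
    fit_quadratic,
    generate_ccd,
    simulate_response,
)

FACTOR_NAMES = ["A", "B", "C", "D", "E"]


@pytest.fixture(scope="session")
def factors5():
    return list(DEFAULT_FACTORS)


@pytest.fixture(scope="session")
def design50(factors5):
    """The canonical five-factor rotatable CCD with 8 center replicates."""
    return generate_ccd(factors5, n_center=8, alpha="rotatable")


@pytest.fixture(scope="session")
def rsv_model():
    """Reduced RSV surface used as ground truth throughout."""
    return default_spec("RSV").true_model


@pytest.fixture(scope="session")
def noisy_fit(design50):
    """A representative noisy RSV fit shared by read-only tests."""
    spec = default_spec("RSV", noise_sd=0.1, seed=11)
    responses = simulate_response(design50, spec)
    y = responses["ct_mean"].to_numpy()
    return fit_quadratic(design50, y), y


def random_quadratic(rng, names=FACTOR_NAMES, lin_sd=1.0, quad_sd=0.5, inter_sd=0.3):
    """A random full quadratic surface for oracle-equivalence checks."""
    from qpcropt import QuadraticModel

    coeffs = {"intercept": 20.0}
    for n in names:
        coeffs[n] = rng.normal(0, lin_sd)
    for n in names:
        coeffs[f"{n}^2"] = rng.normal(0, quad_sd)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            coeffs[names[i] + names[j]] = rng.normal(0, inter_sd)
    return QuadraticModel.from_coefficients(list(names), coeffs)
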