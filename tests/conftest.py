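import numpy as np
import pytest

from gaitcost import EfficiencyParams, SyntheticConfig, generate_cohort, reference


@pytest.fixture(scope="session")
def eff():
    return EfficiencyParams()


@pytest.fixture(scope="session")
def none_v1():
    """No-amputation coefficients with the reference changing-speed and
    turning costs."""
    return reference.coefficients("none", version=1)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero-noise cohort at the version-1 reference coefficients: every
    trial speed is exactly the model-optimal speed for its condition."""
    return generate_cohort(
        SyntheticConfig(sigma_subject=0.0, sigma_trial=0.0, seed=20240102)
    )


@pytest.fixture(scope="session")
def noiseless_v2_cohort():
    """Zero-noise cohort generated at the version-2 (a2 refit) reference
    coefficients."""
    coeffs = {g: reference.coefficients(g, version=2)
              for g in ("above_knee", "below_knee")}
    return generate_cohort(
        SyntheticConfig(coeffs=coeffs, sigma_subject=0.0, sigma_trial=0.0,
                        seed=20240102)
    )


@pytest.fixture(scope="session")
def noisy_cohort():
    return generate_cohort(
        SyntheticConfig(sigma_subject=0.08, sigma_trial=0.04, seed=20240102)
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Constant target speed in every condition: no distance or radius
    dependence, only lognormal noise."""
    return generate_cohort(
        SyntheticConfig(constant_speed=1.0, sigma_subject=0.08,
                        sigma_trial=0.05, seed=20240102)
    )
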