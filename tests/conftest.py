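import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aucsas

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def solvent():
    return aucsas.SolventConditions()


@pytest.fixture(scope="session")
def bsa_dataset(solvent):
    """One noisy BSA-like synthetic experiment (r_a = 0.20, seed 1)."""
    import warnings

    scenario = aucsas.bsa_like_scenario(seed=1)
    profile, distribution, truth = aucsas.make_dataset(scenario)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        distribution = aucsas.assign_association_numbers(distribution, solvent)
    return scenario, profile, distribution, truth


@pytest.fixture(scope="session")
def clean_monomer_profile():
    """Noise-free absolute-scale profile of a lone BSA-like monomer."""
    scenario = aucsas.bsa_like_scenario(ra=0.0, noise_level=0.0, seed=0)
    curve = aucsas.monomer_curve(scenario)
    intensity = scenario.concentration * curve.intensity
    sigma = 0.005 * intensity.max() * (1.0 + curve.q / curve.q.max())
    return aucsas.ScatteringProfile(
        q=curve.q.copy(),
        intensity=intensity,
        sigma=sigma,
        concentration=scenario.concentration,
    ), scenario
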