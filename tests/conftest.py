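"""Shared fixtures: small simulated harvest tables under known regimes."""

import pytest

from droughtmix import (
    NO_NOISE,
    NoiseModel,
    SpeciesParams,
    default_species_params,
    resilience_design,
    resistance_design,
    simulate_experiment,
)


def identical_species(alpha: float = 1.0, s_event: float = 0.5) -> dict:
    """Two species with identical parameters: the exact-null configuration.

    With competition coefficient 1 a 12+12 mixture behaves exactly like a
    24-plant monoculture split in half, so LER = 1 and AME = 0 downstream.
    """
    base = dict(r_max=0.18, K=12.0, alpha_inter=alpha, h_water=0.05,
                s_event=s_event, tau_recovery=6.0, c_comp=1.3, b0=0.01)
    return {
        "AC": SpeciesParams("AC", **base),
        "BM": SpeciesParams("BM", **base),
    }


@pytest.fixture(scope="session")
def null_resilience_obs():
    """Noise-free resilience run under the exact mixture null."""
    return simulate_experiment(resilience_design(), identical_species(),
                               NO_NOISE, seed=11)


@pytest.fixture(scope="session")
def null_resistance_obs():
    """Noise-free resistance run under the exact mixture null."""
    return simulate_experiment(resistance_design(), identical_species(),
                               NO_NOISE, seed=11)


@pytest.fixture(scope="session")
def noise_free_resilience_obs():
    """Default-parameter resilience run without noise."""
    return simulate_experiment(resilience_design(), default_species_params(),
                               NO_NOISE, seed=3)


@pytest.fixture(scope="session")
def noise_free_resistance_obs():
    """Default-parameter resistance run without noise."""
    return simulate_experiment(resistance_design(), default_species_params(),
                               NO_NOISE, seed=3)


@pytest.fixture(scope="session")
def noisy_resilience_obs():
    """Default-parameter resilience run with default noise."""
    return simulate_experiment(resilience_design(), default_species_params(),
                               NoiseModel(), seed=7)
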