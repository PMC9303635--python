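"""Shared fixtures: strain parameter sets and the headline diel simulations.

The four 10-day flat-panel simulations (three measured strains plus the fast
Picochlorum celeri variant) are expensive, so they are computed once per
session and shared by every test that inspects them.
"""

from __future__ import annotations

import pytest

from phycokin import (
    DielLight,
    OperatingSchedule,
    ReactorConfig,
    SpectralDistribution,
    STRAINS,
    simulate_chemostat,
    species_params,
)

HEADLINE_KEYS = ("picochlorum", "neochloris", "nannochloropsis", "celeri")


@pytest.fixture(scope="session")
def diel_light() -> DielLight:
    return DielLight()


@pytest.fixture(scope="session")
def solar_shape() -> SpectralDistribution:
    return SpectralDistribution.daylight()


@pytest.fixture(scope="session")
def reactor() -> ReactorConfig:
    return ReactorConfig()


@pytest.fixture(scope="session")
def headline_sims(diel_light, solar_shape, reactor):
    """Day-10 results of the four default scenarios, keyed by strain."""
    out = {}
    for key in HEADLINE_KEYS:
        strain = STRAINS[key]
        sp = species_params(key)
        sched = OperatingSchedule(
            daily_dilution=strain.best_daily_dilution,
            initial_biomass=strain.initial_biomass,
        )
        out[key] = simulate_chemostat(sp, reactor, sched, diel_light, solar_shape)
    return out
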