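"""Shared fixtures: generator configurations and cached ensembles."""

import math

import numpy as np
import pytest

from smbjdna import (
    GeneratorConfig,
    MixtureSpec,
    ScreeningConfig,
    SpeciesModel,
    default_mixture,
    simulate_ensemble,
)


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def noiseless_config() -> GeneratorConfig:
    return GeneratorConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def duplex_species() -> SpeciesModel:
    return SpeciesModel(name="duplex-test", mu=math.log10(3.03e-4), topology="duplex")


@pytest.fixture(scope="session")
def tunneling_mixture(duplex_species) -> MixtureSpec:
    """A mixture that never forms junctions (p_junction = 0)."""
    return MixtureSpec(components=((duplex_species, 1e-6),), p_junction=0.0)


@pytest.fixture(scope="session")
def default_ensemble_5000(gen_config):
    """The package-default 5000-trace ensemble at one fixed seed."""
    return simulate_ensemble(5000, default_mixture(), gen_config, seed=11)


@pytest.fixture(scope="session")
def screening_config() -> ScreeningConfig:
    return ScreeningConfig()
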