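"""Shared fixtures: small synthetic scenes generated at test time."""

import numpy as np
import pytest

from orgscreen.synthetic_data import (
    AcquisitionModel,
    OrganoidPhenotype,
    generate_organoid_stack,
)


@pytest.fixture(scope="session")
def small_organoid():
    """A small organoid stack with zone markers, filament texture and
    ground truth; shared read-only across tests."""
    phenotype = OrganoidPhenotype(
        radius_um=60.0,
        n_nuclei=300,
        zone_fractions={"Sox2": (0.8, 0.45, 0.15)},
        filament_density={"Map2": 60.0},
    )
    stack, gt = generate_organoid_stack(
        phenotype, AcquisitionModel(), seed=42, grid_shape=(160, 160), n_planes=4
    )
    return stack, gt


@pytest.fixture(scope="session")
def clean_acquisition():
    """Noise- and haze-free acquisition for exactness checks."""
    return AcquisitionModel(
        attenuation_per_um=0.0, haze_amplitude=0.0, noise_sd=0.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
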