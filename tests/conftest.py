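import math

import numpy as np
import pytest

from rootcap import (
    CapacitanceReading,
    PlantCalibrationSeries,
    SimConfig,
    Species,
    species_calibration,
)


@pytest.fixture
def maize_printed():
    return species_calibration(Species.MAIZE, "printed")


@pytest.fixture
def soybean_printed():
    return species_calibration(Species.SOYBEAN, "printed")


@pytest.fixture
def maize_derived():
    return species_calibration(Species.MAIZE, "derived")


def make_series(
    plant_id="P1",
    species=Species.MAIZE,
    a=None,
    b=2.0,
    c_star=10.0,
    theta=None,
    age=30,
    rdm=None,
):
    """Noise-free pot series from c_r = c_star * a * exp(b * theta).

    With the default a = exp(-b) the series is self-consistent: the
    saturated reading equals c_star and the ln-linear fit recovers (a, b)
    exactly.
    """
    if a is None:
        a = math.exp(-b)
    if theta is None:
        theta = np.linspace(0.2, 1.0, 10)
    readings = [
        CapacitanceReading(
            plant_id=plant_id,
            species=species,
            theta_rel=float(t),
            c_r=float(c_star * a * math.exp(b * t)),
        )
        for t in theta
    ]
    return PlantCalibrationSeries(
        plant_id=plant_id,
        species=species,
        readings=readings,
        plant_age_days=age,
        rdm=rdm,
    )


@pytest.fixture
def pot_maize_default():
    """One seeded default-noise maize pot batch (15 plants x 10 levels)."""
    from rootcap import simulate_pot

    return simulate_pot(SimConfig(seed=7, species=Species.MAIZE))
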