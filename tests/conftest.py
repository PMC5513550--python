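import numpy as np
import pytest

from ecoclim.climate_io import LocationClimate
from ecoclim.params import preset


@pytest.fixture
def current():
    return preset("current")


@pytest.fixture
def spradbery():
    return preset("spradbery_maywald")


def constant_climate(tavg: float, monthly_precip: float, rh: float = 0.6,
                     lat: float = -35.0, dtr: float = 10.0,
                     site_id: str = "const") -> LocationClimate:
    """A seasonless climate: the same normals every month."""
    ones = np.ones(12)
    return LocationClimate(
        site_id=site_id, lat=lat, lon=0.0,
        tmin=(tavg - dtr / 2) * ones, tmax=(tavg + dtr / 2) * ones,
        precip=monthly_precip * ones,
        rh09=np.clip(rh + 0.05, 0, 1) * ones, rh15=np.clip(rh - 0.05, 0, 1) * ones,
    )


def random_climate(rng: np.random.Generator, site_id: str = "rand") -> LocationClimate:
    """A random but always-valid monthly climate (for bound/invariant checks)."""
    m = np.arange(12)
    tmean = rng.uniform(-5, 30)
    tamp = rng.uniform(0, 15)
    phase = rng.uniform(0, 12)
    tavg = tmean + tamp * np.cos(2 * np.pi * (m - phase) / 12)
    dtr = rng.uniform(4, 16)
    annual_p = rng.uniform(0, 3000)
    w = 1 + rng.uniform(0, 0.9) * np.cos(2 * np.pi * (m - rng.uniform(0, 12)) / 12)
    w = np.maximum(w, 0)
    precip = annual_p * w / max(w.sum(), 1e-9)
    rh = np.clip(rng.uniform(0.2, 0.9) + rng.uniform(-0.1, 0.1, size=12), 0, 0.95)
    return LocationClimate(
        site_id=site_id, lat=float(rng.uniform(-60, 60)), lon=float(rng.uniform(-180, 180)),
        tmin=tavg - dtr / 2, tmax=tavg + dtr / 2, precip=precip,
        rh09=np.clip(rh + 0.05, 0, 1), rh15=np.clip(rh - 0.05, 0, 1),
    )
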