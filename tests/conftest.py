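import numpy as np
import pytest

from cropsuit.engine import ClimateStack, EngineConfig
from cropsuit.geo import GridGeometry
from cropsuit.registry import CropParameters, load_registry
from cropsuit.synth import WorldSpec, make_world


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def simple_params():
    """A hand-made crop with easy round numbers."""
    return CropParameters(
        crop_code="toy", crop_class="Cereals", gmin=90, gmax=120,
        ktmp=0, tmin=10, topmin=15, topmax=25, tmax=30,
        rmin=200, ropmin=300, ropmax=600, rmax=900,
        phmin=4.0, phopmin=5.0, phopmax=7.0, phmax=8.5)


@pytest.fixture
def engine_config():
    return EngineConfig()


def random_stack(rng, ny=5, nx=5, with_tminm=True):
    """A random but physically consistent small climate stack."""
    geom = GridGeometry.from_bounds(0.0, ny * 0.5, 0.0, nx * 0.5, 0.5)
    tmean = rng.uniform(5, 35, size=(12, ny, nx))
    prec = rng.uniform(0, 250, size=(12, ny, nx))
    tminm = tmean - rng.uniform(2, 10, size=(12, ny, nx)) if with_tminm else None
    return ClimateStack(geom, tmean, prec, tminm=tminm)


def random_params(rng):
    t = np.sort(rng.uniform(0, 40, size=4))
    r = np.sort(rng.uniform(0, 1500, size=4))
    p = np.sort(rng.uniform(3, 10, size=4))
    gmin = rng.uniform(30, 200)
    return CropParameters(
        crop_code="rnd", crop_class="Cereals",
        gmin=gmin, gmax=rng.uniform(gmin, 365),
        ktmp=t[0] - rng.uniform(0, 10),
        tmin=t[0], topmin=t[1], topmax=t[2], tmax=t[3],
        rmin=r[0], ropmin=r[1], ropmax=r[2], rmax=r[3],
        phmin=p[0], phopmin=p[1], phopmax=p[2], phmax=p[3])


@pytest.fixture
def small_world():
    spec = WorldSpec(lat_min=-10, lat_max=10, lon_min=0, lon_max=10,
                     resolution=1.0, seed=42, n_countries=4)
    return make_world(spec)


# --- tuned parameter-recovery scenario -------------------------------------
#
# The seasonal rainfall totals concentrate in a narrow band around the
# crop's (degenerate, step-like) lower rainfall bound, so each 10 mm
# decrement crosses a large share of cells, and the upper temperature
# bound sits just above the hottest growing windows, so a -2 degC niche
# shift zeroes most of the map while -1 zeroes about half.  This makes
# the two-stage calibration identifiable: accuracy stays below the 0.7
# target until the rainfall minima are back near truth and the niche is
# within one degree of truth.

RECOVERY_RAIN_STEP = 10.0
RECOVERY_TEMP_STEP = 1.0


def recovery_world_spec(seed):
    return WorldSpec(lat_min=-16, lat_max=16, lon_min=0, lon_max=20,
                     resolution=0.5, seed=seed,
                     equatorial_mean=29.5, lapse_per_degree=0.15,
                     seasonal_amplitude=2.0, temp_noise_sd=0.2,
                     wet_peak=155.0, precip_noise_sd=0.015, dry_floor=5.0,
                     n_countries=9)


def recovery_true_params():
    return CropParameters(
        crop_code="testcrop", crop_class="Cereals", gmin=90, gmax=140,
        ktmp=5, tmin=15, topmin=20, topmax=31.15, tmax=31.45,
        rmin=445.5, ropmin=445.5, ropmax=900, rmax=2000,
        phmin=3.5, phopmin=4.0, phopmax=9.0, phmax=9.5)


def degrade_params(p_true, rain_offset=30.0, niche_offset=-2.0):
    return p_true.replace(
        rmin=p_true.rmin + rain_offset, ropmin=p_true.ropmin + rain_offset,
        tmin=p_true.tmin + niche_offset, topmin=p_true.topmin + niche_offset,
        topmax=p_true.topmax + niche_offset, tmax=p_true.tmax + niche_offset)
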