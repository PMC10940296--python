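"""Seeded synthetic worlds for exercising the full pipeline offline.

The generated fields carry the qualitative structure the pipeline
assumes — a latitudinal temperature gradient with hemisphere-phased
seasonality, a wet-season precipitation cycle, a smooth soil-pH surface,
a rectangular country mosaic — without pretending to climatic realism.
All randomness flows from a single seed through spawned generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .engine import ClimateStack, EngineConfig, SuitabilityMap, map_suitability
from .geo import GridGeometry, RegionMosaic, cell_area_grid, suitable_area_by_region
from .registry import CropParameters
from .validate import OccurrenceSet

__all__ = ["WorldSpec", "SyntheticWorld", "make_world", "make_truth",
           "sample_occurrences", "make_harvest_table", "make_yield_grid"]

MONTHS = np.arange(1, 13)


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a synthetic world (Africa-like defaults)."""

    lat_min: float = -40.0
    lat_max: float = 40.0
    lon_min: float = -20.0
    lon_max: float = 55.0
    resolution: float = 0.5
    seed: int = 0
    # temperature model
    equatorial_mean: float = 27.0
    lapse_per_degree: float = 0.25      # °C cooling per degree of |lat|
    seasonal_amplitude: float = 4.0
    north_phase: int = 7                # month of thermal maximum, northern cells
    south_phase: int = 1
    temp_noise_sd: float = 0.3
    diurnal_offset: float = 8.0         # tminm = tmean − offset
    # precipitation model
    wet_peak: float = 180.0             # mm/month at the heart of the wet season
    wet_peak_gradient: float = 0.0      # fractional drying per degree of |lat|
    season_halfwidth: float = 3.0       # months from peak to zero weight
    dry_floor: float = 5.0
    precip_noise_sd: float = 0.2        # lognormal sigma
    # soil pH model
    ph_range: tuple[float, float] = (4.8, 8.2)
    ph_correlation_cells: float = 5.0
    n_countries: int = 12

    def __post_init__(self):
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("invalid extent")
        for name in ("temp_noise_sd", "precip_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def geometry(self) -> GridGeometry:
        return GridGeometry.from_bounds(self.lat_min, self.lat_max,
                                        self.lon_min, self.lon_max,
                                        self.resolution)


@dataclass
class SyntheticWorld:
    spec: WorldSpec
    stack: ClimateStack
    ph: np.ndarray
    mosaic: RegionMosaic

    @property
    def geom(self) -> GridGeometry:
        return self.stack.geom


def _phase_by_latitude(spec: WorldSpec, lat: np.ndarray) -> np.ndarray:
    return np.where(lat >= 0, spec.north_phase, spec.south_phase)


def seasonal_temperature(spec: WorldSpec, lat: np.ndarray, month: int) -> np.ndarray:
    """Closed-form noise-free monthly mean temperature by latitude."""
    phase = _phase_by_latitude(spec, lat)
    return (spec.equatorial_mean
            - spec.lapse_per_degree * np.abs(lat)
            + spec.seasonal_amplitude * np.cos(2 * np.pi * (month - phase) / 12.0))


def seasonal_precip_weight(spec: WorldSpec, lat: np.ndarray, month: int) -> np.ndarray:
    """Wet-season weight in [0, 1]: cosine bump around the hemisphere phase."""
    phase = _phase_by_latitude(spec, lat)
    dm = np.abs((month - phase + 6) % 12 - 6)  # circular month distance
    w = np.cos(np.pi * np.minimum(dm, spec.season_halfwidth) / (2 * spec.season_halfwidth))
    return np.clip(w, 0.0, 1.0) ** 2


def make_world(spec: WorldSpec) -> SyntheticWorld:
    """Generate the (climate stack, soil pH, country mosaic) triple."""
    geom = spec.geometry()
    ny, nx = geom.shape
    rng = np.random.default_rng(spec.seed)
    r_temp, r_prec, r_ph = rng.spawn(3)

    lat2d = np.broadcast_to(geom.lat[:, None], (ny, nx))
    tmean = np.empty((12, ny, nx))
    prec = np.empty((12, ny, nx))
    for m in MONTHS:
        base_t = seasonal_temperature(spec, lat2d, m)
        noise = r_temp.normal(0.0, spec.temp_noise_sd, size=(ny, nx)) if spec.temp_noise_sd else 0.0
        tmean[m - 1] = base_t + noise
        w = seasonal_precip_weight(spec, lat2d, m)
        w = w * np.clip(1.0 - spec.wet_peak_gradient * np.abs(lat2d), 0.0, None)
        mult = (np.exp(r_prec.normal(0.0, spec.precip_noise_sd, size=(ny, nx)))
                if spec.precip_noise_sd else 1.0)
        prec[m - 1] = spec.dry_floor + spec.wet_peak * w * mult
    tminm = tmean - spec.diurnal_offset

    raw = r_ph.normal(size=(ny, nx))
    smooth = ndimage.gaussian_filter(raw, sigma=spec.ph_correlation_cells)
    lo, hi = smooth.min(), smooth.max()
    span = hi - lo if hi > lo else 1.0
    ph = spec.ph_range[0] + (smooth - lo) / span * (spec.ph_range[1] - spec.ph_range[0])

    mosaic = _rectangular_mosaic(geom, spec.n_countries)
    stack = ClimateStack(geom, tmean, prec, tminm=tminm)
    return SyntheticWorld(spec, stack, ph, mosaic)


def _rectangular_mosaic(geom: GridGeometry, n_countries: int) -> RegionMosaic:
    ny, nx = geom.shape
    n_cols = int(np.ceil(np.sqrt(n_countries)))
    n_rows = int(np.ceil(n_countries / n_cols))
    labels = np.zeros((ny, nx), dtype=int)
    row_edges = np.linspace(0, ny, n_rows + 1).astype(int)
    col_edges = np.linspace(0, nx, n_cols + 1).astype(int)
    rid = 0
    names = {}
    for i in range(n_rows):
        for j in range(n_cols):
            if rid >= n_countries:
                break
            rid += 1
            labels[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = rid
            names[rid] = f"country_{rid:02d}"
    return RegionMosaic(labels=labels, names=names)


def make_truth(world: SyntheticWorld, p_true: CropParameters,
               cfg: EngineConfig | None = None) -> SuitabilityMap:
    """Ground-truth suitability: the engine run under the true parameters."""
    return map_suitability(world.stack, world.ph, p_true, cfg or EngineConfig())


def sample_occurrences(truth: SuitabilityMap, n: int, background_rate: float,
                       seed: int) -> OccurrenceSet:
    """Presence points at cell centers, sampled ∝ suitability, plus a
    uniform background fraction over land.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    values = np.nan_to_num(truth.values, nan=0.0).ravel()
    land = np.isfinite(truth.values).ravel()
    total = values.sum()
    if total <= 0 and background_rate <= 0:
        raise ValueError("all-zero truth with no background: nothing to sample")

    flat: list[np.ndarray] = []
    if total > 0:
        flat.append(rng.choice(values.size, size=n, p=values / total))
    n_bg = int(round(background_rate * n))
    if n_bg > 0:
        land_idx = np.flatnonzero(land)
        flat.append(rng.choice(land_idx, size=n_bg))
    idx = np.concatenate(flat)
    row, col = np.unravel_index(idx, truth.values.shape)
    return OccurrenceSet(lon=truth.geom.lon[col], lat=truth.geom.lat[row],
                         provenance="synthetic")


def make_harvest_table(truth: SuitabilityMap, mosaic: RegionMosaic,
                       noise_sd: float, zero_fraction: float, seed: int,
                       harvest_ratio: float = 0.3) -> pd.DataFrame:
    """Country table with harvested area ∝ true suitable area plus
    lognormal noise; a ``zero_fraction`` of countries is set non-producing.
    """
    if not 0.0 <= zero_fraction <= 1.0:
        raise ValueError("zero_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    binary = np.where(np.isfinite(truth.values), (truth.values > 0).astype(float), np.nan)
    suitable = suitable_area_by_region(binary, mosaic, truth.geom)
    ids = suitable.index.to_numpy()
    noise = np.exp(rng.normal(0.0, noise_sd, size=ids.size)) if noise_sd > 0 else np.ones(ids.size)
    harvested = harvest_ratio * suitable.to_numpy() * noise
    n_zero = int(round(zero_fraction * ids.size))
    if n_zero:
        off = rng.choice(ids.size, size=n_zero, replace=False)
        harvested[off] = 0.0
    return pd.DataFrame({
        "region_id": ids,
        "produced": harvested > 0,
        "harvested_km2": harvested,
        "suitable_km2": suitable.to_numpy(),
    })


def make_yield_grid(truth: SuitabilityMap, noise_sd: float, seed: int) -> np.ndarray:
    """Yield surface ∝ true suitability with multiplicative gaussian noise,
    clipped at zero; exactly zero where truth is zero, NaN off-land.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    values = truth.values
    noise = rng.normal(0.0, noise_sd, size=values.shape) if noise_sd > 0 else 0.0
    with np.errstate(invalid="ignore"):
        y = np.maximum(0.0, values * (1.0 + noise))
        y = np.where(values == 0, 0.0, y)
    y[np.isnan(values)] = np.nan
    return y
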