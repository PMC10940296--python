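"""Gridded I/O and geometry utilities.

Grids are geographic (WGS84), cell-center registered, stored north-to-south
by row.  Layers are exchanged as single-band GeoTIFF files or 12-month
NetCDF stacks; missing data is NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "GridGeometry",
    "PeriodSpec",
    "RegionMosaic",
    "GeometryError",
    "aggregate_to_monthly",
    "climatology",
    "resample_bilinear",
    "cell_area_km2",
    "cell_area_grid",
    "suitable_area_by_region",
    "archive_name",
    "read_geotiff",
    "write_geotiff",
    "read_netcdf_stack",
    "write_netcdf_stack",
    "PERIODS",
    "FUTURE_PERIODS",
    "GCM_CODES",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0

PERIODS = ("curr", "s126", "s370", "s585")
FUTURE_PERIODS = ("s126", "s370", "s585")
#: Archive tokens of the ten climate models, plus "mn" for the ensemble mean.
GCM_CODES = (
    "cane", "cnrc", "cnrm", "erth", "gfdl",
    "ipsl", "miro", "mpie", "mrie", "uksm",
)
MODEL_TOKENS = GCM_CODES + ("mn",)
DATA_TYPES = ("suit", "suit_cl")
CROP_CLASS_TOKENS = ("Banana", "Cereals", "Pulses", "Roots")

HISTORICAL_YEARS = (1984, 2014)
FUTURE_YEARS = (2035, 2065)


class GeometryError(ValueError):
    """Raised when layer geometries do not match or are invalid."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular lat/lon grid of cell centers; latitude descends row-wise."""

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self):
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        if lat.size > 1 and not np.all(np.diff(lat) < 0):
            raise GeometryError("latitudes must descend north to south")
        if lon.size > 1 and not np.all(np.diff(lon) > 0):
            raise GeometryError("longitudes must ascend west to east")

    @classmethod
    def from_bounds(cls, lat_min: float, lat_max: float,
                    lon_min: float, lon_max: float,
                    resolution: float = 0.5) -> "GridGeometry":
        ny = round((lat_max - lat_min) / resolution)
        nx = round((lon_max - lon_min) / resolution)
        if ny < 1 or nx < 1:
            raise GeometryError("extent smaller than one cell")
        lat = lat_max - resolution * (np.arange(ny) + 0.5)
        lon = lon_min + resolution * (np.arange(nx) + 0.5)
        return cls(lat, lon)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    @property
    def resolution(self) -> float:
        if self.lat.size > 1:
            return float(-np.diff(self.lat).mean())
        return float(np.diff(self.lon).mean())

    def matches(self, other: "GridGeometry", atol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.lat, other.lat, atol=atol)
                and np.allclose(self.lon, other.lon, atol=atol))

    def require_matches(self, other: "GridGeometry") -> None:
        if not self.matches(other):
            raise GeometryError("grid geometries do not match")

    def cell_index(self, lon_pts, lat_pts) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col); third return flags points inside the grid."""
        res = self.resolution
        north = self.lat[0] + res / 2
        west = self.lon[0] - res / 2
        lon_pts = np.asarray(lon_pts, dtype=float)
        lat_pts = np.asarray(lat_pts, dtype=float)
        row = np.floor((north - lat_pts) / res).astype(int)
        col = np.floor((lon_pts - west) / res).astype(int)
        ny, nx = self.shape
        inside = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
        return row, col, inside


@dataclass(frozen=True)
class PeriodSpec:
    """A climate period: historical baseline or one future scenario run."""

    label: str
    model: str = ""

    def __post_init__(self):
        if self.label not in PERIODS:
            raise ValueError(f"unknown period label {self.label!r}; expected one of {PERIODS}")
        if self.label == "curr" and self.model:
            raise ValueError("historical period 'curr' takes no model token")
        if self.label != "curr":
            if not self.model:
                raise ValueError(f"future period {self.label!r} requires a model token")
            if self.model not in MODEL_TOKENS:
                raise ValueError(f"unknown model token {self.model!r}; expected one of {MODEL_TOKENS}")

    @property
    def years(self) -> tuple[int, int]:
        return HISTORICAL_YEARS if self.label == "curr" else FUTURE_YEARS


@dataclass
class RegionMosaic:
    """Integer-labelled grid assigning land cells to regions (countries).

    Cells outside any region carry the fill value 0.
    """

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


# ---------------------------------------------------------------------------
# temporal aggregation

def aggregate_to_monthly(daily: xr.DataArray, kind: str,
                         strict: bool = True) -> xr.DataArray:
    """Collapse a daily series into per-year monthly layers.

    Precipitation is summed (mm), temperature averaged (°C).  In strict
    mode a month with any missing day comes out NaN; otherwise available
    days are used.
    """
    if kind not in ("precipitation", "temperature"):
        raise ValueError(f"unknown variable kind {kind!r}")
    time = pd.DatetimeIndex(daily["time"].values)
    key = xr.DataArray((time.year * 100 + time.month).to_numpy(),
                       dims="time", name="yearmonth")
    grouped = daily.groupby(key)
    agg = grouped.sum(skipna=not strict) if kind == "precipitation" else grouped.mean(skipna=not strict)
    if strict:
        # a month is complete only when every calendar day is present & finite
        counts = daily.notnull().groupby(key).sum()
        ym = agg["yearmonth"].values
        expected = np.array([
            pd.Period(f"{v // 100}-{v % 100:02d}").days_in_month for v in ym
        ])
        shape = [1] * agg.ndim
        shape[agg.get_axis_num("yearmonth")] = expected.size
        complete = counts.values == expected.reshape(shape)
        agg = agg.where(xr.DataArray(complete, dims=agg.dims, coords=agg.coords))
    years = agg["yearmonth"].values // 100
    months = agg["yearmonth"].values % 100
    agg = agg.assign_coords(year=("yearmonth", years), month=("yearmonth", months))
    return agg.set_index(yearmonth=["year", "month"]).unstack("yearmonth")


def climatology(monthly: xr.DataArray, period: PeriodSpec) -> xr.DataArray:
    """Per-calendar-month mean over the period's years.

    ``monthly`` must carry ``year`` and ``month`` dimensions.  Missing
    years raise an error listing them.
    """
    y0, y1 = period.years
    wanted = set(range(y0, y1 + 1))
    have = set(int(y) for y in monthly["year"].values)
    absent = sorted(wanted - have)
    if absent:
        raise ValueError(f"period {period.label!r} missing year(s): {absent}")
    subset = monthly.sel(year=sorted(wanted))
    return subset.mean("year").sortby("month")


# ---------------------------------------------------------------------------
# spatial operations

def resample_bilinear(src_geom: GridGeometry, values: np.ndarray,
                      dst_geom: GridGeometry) -> np.ndarray:
    """Bilinear resampling between cell-center lattices.

    Destination points outside the source center lattice clamp to the
    nearest edge value.
    """
    if values.shape != src_geom.shape:
        raise GeometryError("source values do not match source geometry")
    lat_asc = src_geom.lat[::-1]
    vals_asc = values[::-1, :]
    interp = RegularGridInterpolator(
        (lat_asc, src_geom.lon), vals_asc, method="linear",
        bounds_error=False, fill_value=None,
    )
    dlat = np.clip(dst_geom.lat, lat_asc[0], lat_asc[-1])
    dlon = np.clip(dst_geom.lon, src_geom.lon[0], src_geom.lon[-1])
    glat, glon = np.meshgrid(dlat, dlon, indexing="ij")
    if glat.size == 0:
        raise GeometryError("empty destination grid")
    out = interp(np.column_stack([glat.ravel(), glon.ravel()]))
    return out.reshape(dst_geom.shape)


def cell_area_km2(lat_center, resolution: float = 0.5):
    """Spherical area of a grid cell centered at ``lat_center`` degrees."""
    lat = np.asarray(lat_center, dtype=float)
    half = resolution / 2.0
    if np.any(np.abs(lat) + half > 90.0 + 1e-12):
        raise ValueError("cell extends beyond the poles")
    top = np.radians(lat + half)
    bottom = np.radians(lat - half)
    dlon = np.radians(resolution)
    area = EARTH_RADIUS_KM ** 2 * dlon * (np.sin(top) - np.sin(bottom))
    return float(area) if np.isscalar(lat_center) else area


def cell_area_grid(geom: GridGeometry) -> np.ndarray:
    """Per-cell areas (km²) broadcast over the grid."""
    areas = cell_area_km2(geom.lat, geom.resolution)
    return np.broadcast_to(areas[:, None], geom.shape).copy()


def suitable_area_by_region(binary: np.ndarray, mosaic: RegionMosaic,
                            geom: GridGeometry) -> pd.Series:
    """Total area (km²) of suitable cells per region.

    ``binary`` is boolean/0-1 with NaN where undefined; undefined cells
    contribute nothing.  Regions without a suitable cell report 0.
    """
    if binary.shape != geom.shape or mosaic.labels.shape != geom.shape:
        raise GeometryError("binary map, mosaic and geometry must share shape")
    areas = cell_area_grid(geom)
    b = np.nan_to_num(np.asarray(binary, dtype=float), nan=0.0)
    weights = (b > 0) * areas
    ids = mosaic.region_ids()
    totals = {int(r): float(weights[mosaic.labels == r].sum()) for r in ids}
    return pd.Series(totals, name="suitable_km2").sort_index()


# ---------------------------------------------------------------------------
# archive naming

def archive_name(crop_class: str, crop_code: str, data_type: str,
                 period: str, model: str | None = None,
                 ext: str = ".tif") -> str:
    """Build the archive filename ``<class>_<crop>_<datatype>_<period>[_<model>]``."""
    if crop_class not in CROP_CLASS_TOKENS:
        raise ValueError(f"invalid crop class token {crop_class!r}")
    if not crop_code or not crop_code.isidentifier():
        raise ValueError(f"invalid crop code token {crop_code!r}")
    if data_type not in DATA_TYPES:
        raise ValueError(f"invalid data type token {data_type!r}")
    if period not in PERIODS:
        raise ValueError(f"invalid period token {period!r}")
    if period == "curr":
        if model:
            raise ValueError("period 'curr' takes no model token")
        return f"{crop_class}_{crop_code}_{data_type}_{period}{ext}"
    if not model or model not in MODEL_TOKENS:
        raise ValueError(f"invalid model token {model!r}")
    return f"{crop_class}_{crop_code}_{data_type}_{period}_{model}{ext}"


# ---------------------------------------------------------------------------
# raster I/O
#
# GeoTIFF is written directly through tifffile with the standard
# ModelPixelScale / ModelTiepoint / GeoKeyDirectory tags (WGS84
# geographic, pixel-is-area with the tiepoint at the NW outer corner).

_GEOTIFF_PIXELSCALE = 33550
_GEOTIFF_TIEPOINT = 33922
_GEOTIFF_KEYDIR = 34735

# GTModelType=Geographic(2), GTRasterType=PixelIsArea(1), GeographicType=WGS84(4326)
_WGS84_KEYS = (1, 1, 0, 3,
               1024, 0, 1, 2,
               1025, 0, 1, 1,
               2048, 0, 1, 4326)


def write_geotiff(path: str | Path, values: np.ndarray, geom: GridGeometry) -> None:
    """Write one float32 layer as a WGS84 GeoTIFF (NaN = missing)."""
    if values.shape != geom.shape:
        raise GeometryError("values do not match geometry")
    res = geom.resolution
    north = float(geom.lat[0] + res / 2)
    west = float(geom.lon[0] - res / 2)
    extratags = [
        (_GEOTIFF_PIXELSCALE, "d", 3, (res, res, 0.0)),
        (_GEOTIFF_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, west, north, 0.0)),
        (_GEOTIFF_KEYDIR, "H", len(_WGS84_KEYS), _WGS84_KEYS),
    ]
    tifffile.imwrite(path, values.astype(np.float32), extratags=extratags)


def read_geotiff(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        try:
            scale = tags[_GEOTIFF_PIXELSCALE].value
            tie = tags[_GEOTIFF_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: not a GeoTIFF (missing geo tags)") from exc
    res_x, res_y = float(scale[0]), float(scale[1])
    west, north = float(tie[3]), float(tie[4])
    ny, nx = values.shape
    lat = north - res_y * (np.arange(ny) + 0.5)
    lon = west + res_x * (np.arange(nx) + 0.5)
    return values, GridGeometry(lat, lon)


def write_netcdf_stack(path: str | Path, layers: dict[str, np.ndarray],
                       geom: GridGeometry) -> None:
    """Write 12-month stacks (and optional 2-D layers) to NetCDF.

    3-D variables get dimensions (month, lat, lon); 2-D get (lat, lon).
    """
    data = {}
    for name, arr in layers.items():
        if arr is None:
            continue
        if arr.ndim == 3:
            if arr.shape != (12, *geom.shape):
                raise GeometryError(f"layer {name!r} does not match (12, lat, lon)")
            data[name] = (("month", "lat", "lon"), arr.astype(np.float32))
        elif arr.ndim == 2:
            if arr.shape != geom.shape:
                raise GeometryError(f"layer {name!r} does not match (lat, lon)")
            data[name] = (("lat", "lon"), arr.astype(np.float32))
        else:
            raise GeometryError(f"layer {name!r} must be 2-D or 3-D")
    ds = xr.Dataset(
        data,
        coords={"month": np.arange(1, 13), "lat": geom.lat, "lon": geom.lon},
    )
    ds.to_netcdf(path, engine="scipy")


def read_netcdf_stack(path: str | Path) -> tuple[dict[str, np.ndarray], GridGeometry]:
    with xr.open_dataset(path, engine="scipy") as ds:
        geom = GridGeometry(ds["lat"].values.copy(), ds["lon"].values.copy())
        layers = {name: ds[name].values.copy() for name in ds.data_vars}
    return layers, geom
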