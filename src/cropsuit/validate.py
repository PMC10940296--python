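"""Six-metric evaluation framework and threshold-exceedance profiles.

Metrics per crop: occurrence detection rate (GBIF-style points),
country-level detection accuracy, harvested-vs-suitable area correlation
and exceedance (FAOSTAT-style), and the same correlation/exceedance pair
against a gridded-allocation reference (MAPSPAM-style, gated on
availability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geo import GridGeometry
from .registry import CropRegistry

__all__ = [
    "OccurrenceSet",
    "MetricReport",
    "METRIC_NAMES",
    "PROFILE_THRESHOLDS",
    "thin_to_grid",
    "occurrence_detection_rate",
    "country_detection_accuracy",
    "area_correlation",
    "area_exceedance",
    "threshold_profile",
    "class_mean_profile",
]

METRIC_NAMES = (
    "gbif_detection",
    "faostat_detection",
    "faostat_correlation",
    "faostat_exceedance",
    "mapspam_correlation",
    "mapspam_exceedance",
)

PROFILE_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class OccurrenceSet:
    """Presence points: (lon, lat) pairs with optional observation years."""

    lon: np.ndarray
    lat: np.ndarray
    year: np.ndarray | None = None
    provenance: str = ""
    n_dropped: int = 0

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.year is not None:
            self.year = np.asarray(self.year)

    def __len__(self) -> int:
        return self.lon.size

    def filter_years(self, min_year: int = 2000) -> "OccurrenceSet":
        """Keep points observed from ``min_year`` on (no-op without years)."""
        if self.year is None:
            return self
        keep = self.year >= min_year
        return OccurrenceSet(self.lon[keep], self.lat[keep], self.year[keep],
                             self.provenance, self.n_dropped)

    def to_frame(self) -> pd.DataFrame:
        data = {"lon": self.lon, "lat": self.lat}
        if self.year is not None:
            data["year"] = self.year
        return pd.DataFrame(data)


def thin_to_grid(points: OccurrenceSet, geom: GridGeometry,
                 seed: int) -> OccurrenceSet:
    """Randomly keep at most one point per grid cell (seeded); points
    outside the grid are dropped and counted.
    """
    if len(points) == 0:
        return OccurrenceSet(np.empty(0), np.empty(0), provenance=points.provenance)
    rng = np.random.default_rng(seed)
    row, col, inside = geom.cell_index(points.lon, points.lat)
    dropped = int(np.count_nonzero(~inside))
    idx = np.flatnonzero(inside)
    cells: dict[tuple[int, int], list[int]] = {}
    for i in idx:
        cells.setdefault((int(row[i]), int(col[i])), []).append(int(i))
    chosen = sorted(int(rng.choice(members)) for members in cells.values())
    year = points.year[chosen] if points.year is not None else None
    return OccurrenceSet(points.lon[chosen], points.lat[chosen], year,
                         points.provenance, n_dropped=dropped)


def occurrence_detection_rate(points: OccurrenceSet, binary: np.ndarray,
                              geom: GridGeometry,
                              return_details: bool = False):
    """Proportion of points falling in suitable cells, over all points.

    Points landing in missing (NaN) cells stay in the denominator; their
    count is available via ``return_details``.
    """
    if len(points) == 0:
        raise ValueError("no occurrence points")
    row, col, inside = geom.cell_index(points.lon, points.lat)
    values = np.full(len(points), np.nan)
    values[inside] = binary[row[inside], col[inside]]
    hits = np.count_nonzero(values > 0)
    n_missing = int(np.count_nonzero(np.isnan(values)))
    rate = hits / len(points)
    if return_details:
        return rate, {"n_points": len(points), "n_missing_cells": n_missing}
    return rate


def country_detection_accuracy(table: pd.DataFrame,
                               one_cell_area_km2: float) -> float:
    """Proportion of countries consistent with the production record.

    A country mismatches only when it produces the crop but the modelled
    suitable area does not exceed one grid cell; non-producing countries
    always match (a crop may be suitable where it is not grown).
    ``table`` needs columns ``produced`` and ``suitable_km2``.
    """
    if table.empty:
        raise ValueError("empty country table")
    produced = table["produced"].astype(bool).to_numpy()
    suitable = table["suitable_km2"].to_numpy(dtype=float)
    mismatch = produced & (suitable <= one_cell_area_km2)
    return float(1.0 - mismatch.sum() / len(table))


def area_correlation(table: pd.DataFrame, source: str = "faostat",
                     log_areas: bool = False) -> float | None:
    """Pearson correlation of harvested vs modelled suitable area across
    countries; ``None`` when fewer than 3 complete pairs or either side
    has zero variance.
    """
    col = _harvested_column(table, source)
    pairs = table[[col, "suitable_km2"]].dropna()
    if len(pairs) < 3:
        return None
    x = pairs[col].to_numpy(dtype=float)
    y = pairs["suitable_km2"].to_numpy(dtype=float)
    if log_areas:
        x, y = np.log1p(x), np.log1p(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def area_exceedance(table: pd.DataFrame, source: str = "faostat") -> float:
    """Proportion of countries whose modelled suitable area strictly
    exceeds the reported harvested area.
    """
    col = _harvested_column(table, source)
    pairs = table[[col, "suitable_km2"]].dropna()
    if pairs.empty:
        raise ValueError("no country with both harvested and suitable area")
    exceed = pairs["suitable_km2"].to_numpy(dtype=float) > pairs[col].to_numpy(dtype=float)
    return float(exceed.sum() / len(pairs))


def _harvested_column(table: pd.DataFrame, source: str) -> str:
    col = f"harvested_km2_{source}"
    if col in table.columns:
        return col
    if "harvested_km2" in table.columns:
        return "harvested_km2"
    raise KeyError(f"no harvested-area column for source {source!r}")


def threshold_profile(metrics: dict[str, float | None],
                      thresholds: tuple[float, ...] = PROFILE_THRESHOLDS) -> dict[float, int]:
    """For each threshold, how many defined metrics lie strictly above it."""
    values = [v for v in metrics.values() if v is not None and np.isfinite(v)]
    return {t: sum(v > t for v in values) for t in thresholds}


def class_mean_profile(profiles: dict[str, dict[float, int]],
                       registry: CropRegistry) -> pd.DataFrame:
    """Mean exceedance counts per crop class and threshold.

    Rows: crop classes; columns: thresholds.
    """
    by_class: dict[str, list[dict[float, int]]] = {}
    for crop, profile in profiles.items():
        if crop not in registry:
            raise KeyError(f"unknown crop {crop!r}")
        by_class.setdefault(registry[crop].crop_class, []).append(profile)
    rows = {}
    for cls, plist in by_class.items():
        thresholds = sorted({t for p in plist for t in p})
        rows[cls] = {t: float(np.mean([p[t] for p in plist])) for t in thresholds}
    return pd.DataFrame(rows).T.sort_index()


@dataclass
class MetricReport:
    """Per-crop six-metric table mirroring the evaluation framework."""

    metrics: dict[str, dict[str, float | None]] = field(default_factory=dict)
    notes: dict[str, list[str]] = field(default_factory=dict)

    def add(self, crop: str, **values) -> None:
        unknown = set(values) - set(METRIC_NAMES)
        if unknown:
            raise KeyError(f"unknown metric(s): {sorted(unknown)}")
        slot = {name: None for name in METRIC_NAMES}
        slot.update(values)
        self.metrics[crop] = slot

    def note(self, crop: str, message: str) -> None:
        self.notes.setdefault(crop, []).append(message)

    def profile(self, crop: str) -> dict[float, int]:
        return threshold_profile(self.metrics[crop])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame.from_dict(self.metrics, orient="index")
        return frame.reindex(columns=list(METRIC_NAMES))

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("crop_code").to_csv(path)
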