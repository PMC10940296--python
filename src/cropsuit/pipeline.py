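"""Run orchestration: crop × scenario × GCM enumeration, per-run layer
production, ensemble means, area summaries, and the run manifest."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import binarize
from .engine import ClimateStack, EngineConfig, SuitabilityMap, map_suitability
from .geo import (FUTURE_PERIODS, GCM_CODES, GeometryError, GridGeometry,
                  archive_name, cell_area_grid, write_geotiff)
from .registry import CropParameters, CropRegistry

__all__ = [
    "RunManifest",
    "RunPlan",
    "enumerate_runs",
    "run_crop",
    "run_ensemble",
    "percent_suitable_area",
    "summarize_ensemble_spread",
]


@dataclass
class RunManifest:
    """Accounting of produced layers; filenames must be unique."""

    rows: list[dict] = field(default_factory=list)

    def add(self, crop_code: str, crop_class: str, data_type: str,
            period: str, model: str, filename: str, checksum: str) -> None:
        if any(r["filename"] == filename for r in self.rows):
            raise ValueError(f"duplicate manifest entry: {filename}")
        self.rows.append({
            "crop_code": crop_code, "crop_class": crop_class,
            "data_type": data_type, "period": period, "model": model,
            "filename": filename, "checksum": checksum,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=[
            "crop_code", "crop_class", "data_type", "period", "model",
            "filename", "checksum"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def counts(self, dimension: str) -> pd.Series:
        return self.to_frame()[dimension].value_counts().sort_index()


@dataclass(frozen=True)
class RunEntry:
    crop_code: str
    period: str
    model: str      # "" for curr, GCM code or "mn"

    @property
    def kind(self) -> str:
        if self.period == "curr":
            return "current"
        return "ensemble_mean" if self.model == "mn" else "future"


@dataclass
class RunPlan:
    entries: list[RunEntry]

    def future_runs(self, crop_code: str | None = None) -> list[RunEntry]:
        return [e for e in self.entries if e.kind == "future"
                and (crop_code is None or e.crop_code == crop_code)]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {"current": 0, "future": 0, "ensemble_mean": 0}
        for e in self.entries:
            out[e.kind] += 1
        return out


def enumerate_runs(registry: CropRegistry,
                   scenarios: tuple[str, ...] = FUTURE_PERIODS,
                   gcms: tuple[str, ...] = GCM_CODES) -> RunPlan:
    """Per crop: one current run, |scenarios| × |gcms| future runs, and one
    ensemble-mean aggregate per scenario.
    """
    for s in scenarios:
        if s not in FUTURE_PERIODS:
            raise ValueError(f"unknown scenario token {s!r}")
    for g in gcms:
        if g not in GCM_CODES:
            raise ValueError(f"unknown GCM token {g!r}")
    entries: list[RunEntry] = []
    for crop in registry:
        entries.append(RunEntry(crop, "curr", ""))
        for s in scenarios:
            for g in gcms:
                entries.append(RunEntry(crop, s, g))
            entries.append(RunEntry(crop, s, "mn"))
    return RunPlan(entries)


def _checksum(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values.astype(np.float32)).tobytes()).hexdigest()


def run_crop(crop_code: str, crop_class: str, period: str, model: str,
             stack: ClimateStack, ph: np.ndarray, params: CropParameters,
             cfg: EngineConfig, threshold: float, outdir: str | Path,
             manifest: RunManifest) -> tuple[SuitabilityMap, np.ndarray]:
    """Produce and archive the suitability-score and binary-class layers
    for one crop/period/model combination.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    smap = map_suitability(stack, ph, params, cfg)
    smap.crop_code, smap.period, smap.model = crop_code, period, model
    binary = binarize(smap, threshold)
    for data_type, values in (("suit", smap.values), ("suit_cl", binary)):
        name = archive_name(crop_class, crop_code, data_type, period,
                            model or None)
        write_geotiff(outdir / name, values, stack.geom)
        manifest.add(crop_code, crop_class, data_type, period, model,
                     name, _checksum(values))
    return smap, binary


def run_ensemble(crop_code: str, crop_class: str, scenario: str,
                 gcm_stacks: dict[str, ClimateStack], ph: np.ndarray,
                 params: CropParameters, cfg: EngineConfig, threshold: float,
                 outdir: str | Path, manifest: RunManifest,
                 gcms: tuple[str, ...] = GCM_CODES) -> dict[str, SuitabilityMap]:
    """Run the engine for every GCM of a scenario, then write the
    ensemble-mean score layer (tagged ``mn``) and its binarization.
    """
    missing = [g for g in gcms if g not in gcm_stacks]
    if missing:
        raise ValueError(f"missing GCM stack(s): {', '.join(missing)}")
    maps: dict[str, SuitabilityMap] = {}
    for g in gcms:
        smap, _ = run_crop(crop_code, crop_class, scenario, g,
                           gcm_stacks[g], ph, params, cfg, threshold,
                           outdir, manifest)
        maps[g] = smap
    mean_values = np.mean(np.stack([maps[g].values for g in gcms]), axis=0)
    geom = gcm_stacks[gcms[0]].geom
    mean_map = SuitabilityMap(mean_values, geom, crop_code=crop_code,
                              period=scenario, model="mn")
    mean_binary = binarize(mean_map, threshold)
    outdir = Path(outdir)
    for data_type, values in (("suit", mean_values), ("suit_cl", mean_binary)):
        name = archive_name(crop_class, crop_code, data_type, scenario, "mn")
        write_geotiff(outdir / name, values, geom)
        manifest.add(crop_code, crop_class, data_type, scenario, "mn",
                     name, _checksum(values))
    maps["mn"] = mean_map
    return maps


def percent_suitable_area(binary: np.ndarray, land_mask: np.ndarray,
                          geom: GridGeometry) -> float:
    """Area-weighted percentage of land that is suitable."""
    if binary.shape != geom.shape or land_mask.shape != geom.shape:
        raise GeometryError("binary map and land mask must match the grid")
    areas = cell_area_grid(geom)
    land_area = areas[land_mask].sum()
    if land_area <= 0:
        raise ValueError("empty land mask")
    suitable = land_mask & np.nan_to_num(binary, nan=0.0).astype(bool)
    return float(100.0 * areas[suitable].sum() / land_area)


def summarize_ensemble_spread(percents) -> tuple[float, float, float]:
    """(mean, min, max) of per-GCM percent-suitable values."""
    values = np.asarray(list(percents), dtype=float)
    if values.size < 2:
        raise ValueError("need at least two ensemble members")
    return float(values.mean()), float(values.min()), float(values.max())
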