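"""Mechanistic crop-suitability engine.

A cell's suitability in [0, 1] is the best score over the 12 candidate
growing windows (one starting at each calendar month, with December →
January wrap-around).  A window's climate score combines the worst
monthly temperature score with the score of the window's total rainfall;
the climate score is then combined with soil-pH suitability.  Months
whose kill-test temperature falls below the kill temperature plus a
frost buffer zero the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geo import GeometryError, GridGeometry
from .registry import CropParameters, validate_parameters

__all__ = [
    "ClimateStack",
    "EngineConfig",
    "SuitabilityMap",
    "trapezoid_suitability",
    "duration_months",
    "growing_window",
    "temp_suitability_season",
    "rain_suitability_season",
    "ph_suitability",
    "cell_suitability",
    "map_suitability",
]


@dataclass
class ClimateStack:
    """12-month climatology triplet on one grid.

    ``tmean`` and ``prec`` are (12, ny, nx); ``tminm`` (monthly minimum
    temperature) is optional and used for the kill test when present.
    NaN marks missing data and propagates through the engine.
    """

    geom: GridGeometry
    tmean: np.ndarray
    prec: np.ndarray
    tminm: np.ndarray | None = None
    land_mask: np.ndarray | None = None

    def __post_init__(self):
        shape = (12, *self.geom.shape)
        for name in ("tmean", "prec"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise GeometryError(f"{name} must have shape {shape}, got {arr.shape}")
        if self.tminm is not None and self.tminm.shape != shape:
            raise GeometryError(f"tminm must have shape {shape}")
        if self.land_mask is None:
            self.land_mask = np.ones(self.geom.shape, dtype=bool)
        elif self.land_mask.shape != self.geom.shape:
            raise GeometryError("land_mask must match grid shape")
        with np.errstate(invalid="ignore"):
            if np.any(self.prec < 0):
                raise ValueError("precipitation must be non-negative")
            if self.tminm is not None and np.any(self.tminm > self.tmean + 1e-9):
                raise ValueError("monthly minimum temperature exceeds monthly mean")

    def rotated(self, k: int) -> "ClimateStack":
        """Rotate all monthly layers by ``k`` months (for invariance checks)."""
        def rot(a):
            return None if a is None else np.roll(a, k, axis=0)
        return ClimateStack(self.geom, rot(self.tmean), rot(self.prec),
                            rot(self.tminm), self.land_mask.copy())


@dataclass(frozen=True)
class EngineConfig:
    """Engine policy knobs.

    ``combine_rule`` joins temperature and rainfall scores; ``ph_rule``
    joins the climate score with soil suitability.  Both default to the
    product, preserving gradation; ``min`` is available for comparison.
    """

    combine_rule: str = "product"
    ph_rule: str = "product"
    frost_buffer: float = 4.0

    def __post_init__(self):
        for name in ("combine_rule", "ph_rule"):
            if getattr(self, name) not in ("product", "min"):
                raise ValueError(f"{name} must be 'product' or 'min'")
        if self.frost_buffer < 0:
            raise ValueError("frost_buffer must be non-negative")

    def combine(self, a, b, rule: str):
        if rule == "product":
            return a * b
        return np.minimum(a, b)


@dataclass
class SuitabilityMap:
    """A [0, 1] suitability grid tagged with run metadata."""

    values: np.ndarray
    geom: GridGeometry
    crop_code: str = ""
    period: str = ""
    model: str = ""

    def __post_init__(self):
        if self.values.shape != self.geom.shape:
            raise GeometryError("values do not match geometry")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")


def trapezoid_suitability(x, amin: float, omin: float, omax: float, amax: float):
    """Piecewise-linear niche response: 0 outside [amin, amax], 1 on
    [omin, omax], linear ramps between.  Degenerate equal bounds act as a
    step at that bound.  Accepts scalars or arrays; NaN propagates.
    """
    if not (amin <= omin <= omax <= amax):
        raise ValueError(
            f"niche bounds must satisfy amin ≤ omin ≤ omax ≤ amax, "
            f"got ({amin}, {omin}, {omax}, {amax})"
        )
    scalar = np.isscalar(x) or np.ndim(x) == 0
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    with np.errstate(invalid="ignore"):
        plateau = (x >= omin) & (x <= omax)
        out[plateau] = 1.0
        if omin > amin:
            lo = (x > amin) & (x < omin)
            out[lo] = (x[lo] - amin) / (omin - amin)
        if amax > omax:
            hi = (x > omax) & (x < amax)
            out[hi] = (amax - x[hi]) / (amax - omax)
    out[np.isnan(x)] = np.nan
    return float(out) if scalar else out


def duration_months(p: CropParameters) -> int:
    """Growing-window length in months from the crop's cycle-length range:
    round-half-up of the mean cycle length in months, clamped to [1, 12].
    """
    months = math.floor((p.gmin + p.gmax) / 60.0 + 0.5)
    return int(min(12, max(1, months)))


def growing_window(start_month: int, duration: int) -> list[int]:
    """Consecutive month indices (1-12) with December → January wrap."""
    if not 1 <= start_month <= 12:
        raise ValueError(f"start_month must be in 1..12, got {start_month}")
    if not 1 <= duration <= 12:
        raise ValueError(f"duration must be in 1..12, got {duration}")
    return [(start_month - 1 + k) % 12 + 1 for k in range(duration)]


def _kill_series(tmean_months, tminm_months):
    return tmean_months if tminm_months is None else tminm_months


def temp_suitability_season(tmean_months, p: CropParameters, window: list[int],
                            cfg: EngineConfig, tminm_months=None) -> float:
    """Worst monthly temperature score over the window; a month whose
    kill-test temperature drops below ktmp + frost_buffer zeroes it.
    """
    kill = _kill_series(tmean_months, tminm_months)
    score = 1.0
    for m in window:
        t = tmean_months[m - 1]
        k = kill[m - 1]
        if np.isnan(t) or np.isnan(k):
            return float("nan")
        s = 0.0 if k < p.ktmp + cfg.frost_buffer else trapezoid_suitability(
            t, p.tmin, p.topmin, p.topmax, p.tmax)
        score = min(score, s)
    return score


def rain_suitability_season(prec_months, p: CropParameters, window: list[int]) -> float:
    """Trapezoid response of the window's total rainfall."""
    total = 0.0
    for m in window:
        v = prec_months[m - 1]
        if np.isnan(v):
            return float("nan")
        total += v
    return trapezoid_suitability(total, p.rmin, p.ropmin, p.ropmax, p.rmax)


def ph_suitability(ph, p: CropParameters):
    """Trapezoid response of soil pH; NaN propagates."""
    return trapezoid_suitability(ph, p.phmin, p.phopmin, p.phopmax, p.phmax)


def cell_suitability(tmean_months, prec_months, ph: float, p: CropParameters,
                     cfg: EngineConfig | None = None, tminm_months=None) -> float:
    """Suitability of one cell: best window's combined climate score,
    combined with soil-pH suitability.
    """
    cfg = cfg or EngineConfig()
    dur = duration_months(p)
    best = float("nan")
    for start in range(1, 13):
        window = growing_window(start, dur)
        ts = temp_suitability_season(tmean_months, p, window, cfg, tminm_months)
        rs = rain_suitability_season(prec_months, p, window)
        if np.isnan(ts) or np.isnan(rs):
            return float("nan")
        score = float(cfg.combine(ts, rs, cfg.combine_rule))
        if np.isnan(best) or score > best:
            best = score
    ps = ph_suitability(ph, p)
    if np.isnan(ps):
        return float("nan")
    return float(cfg.combine(best, ps, cfg.ph_rule))


def map_suitability(stack: ClimateStack, ph_grid: np.ndarray, p: CropParameters,
                    cfg: EngineConfig | None = None, *,
                    validate: bool = True) -> SuitabilityMap:
    """Vectorized :func:`cell_suitability` over every land cell.

    Cells off the land mask, or with any missing input month / missing
    pH, come out NaN.  ``validate=False`` skips the parameter-invariant
    check (used by calibration, whose search may momentarily cross the
    ktmp ≤ tmin bound).
    """
    cfg = cfg or EngineConfig()
    if validate:
        problems = validate_parameters(p)
        if problems:
            raise ValueError("invalid crop parameters: " + "; ".join(problems))
    if ph_grid.shape != stack.geom.shape:
        raise GeometryError("pH grid does not match climate geometry")

    dur = duration_months(p)
    tmean, prec = stack.tmean, stack.prec
    kill = tmean if stack.tminm is None else stack.tminm

    with np.errstate(invalid="ignore"):
        monthly_t = trapezoid_suitability(tmean, p.tmin, p.topmin, p.topmax, p.tmax)
        monthly_t = np.where(kill < p.ktmp + cfg.frost_buffer, 0.0, monthly_t)

        best = np.full(stack.geom.shape, -np.inf)
        for start in range(12):
            months = [(start + k) % 12 for k in range(dur)]
            t_season = monthly_t[months].min(axis=0)
            total = prec[months].sum(axis=0)
            r_season = trapezoid_suitability(total, p.rmin, p.ropmin, p.ropmax, p.rmax)
            best = np.maximum(best, cfg.combine(t_season, r_season, cfg.combine_rule))

        ps = trapezoid_suitability(ph_grid, p.phmin, p.phopmin, p.phopmax, p.phmax)
        values = cfg.combine(best, ps, cfg.ph_rule)

    invalid = (
        ~stack.land_mask
        | np.isnan(tmean).any(axis=0)
        | np.isnan(prec).any(axis=0)
        | np.isnan(kill).any(axis=0)
        | np.isnan(ph_grid)
    )
    values = np.where(invalid, np.nan, values)
    return SuitabilityMap(values, stack.geom, crop_code=p.crop_code)
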