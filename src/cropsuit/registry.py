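"""Crop parameter registry.

Each crop is described by its climatic and edaphic niche: a growth-cycle
length range (days), a kill temperature, a trapezoidal mean-temperature
niche, a trapezoidal seasonal-rainfall niche, and a trapezoidal soil-pH
niche.  The packaged default table ships representative values that users
may replace with their own calibrated parameter sets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "CropParameters",
    "CropRegistry",
    "load_registry",
    "save_registry",
    "validate_parameters",
    "CROP_CLASSES",
    "REGISTRY_COLUMNS",
]

CROP_CLASSES = ("Cereals", "Pulses", "Roots", "Banana")

#: Canonical column order of the parameter CSV.
REGISTRY_COLUMNS = [
    "crop_code",
    "crop_class",
    "gmin",
    "gmax",
    "ktmp",
    "tmin",
    "topmin",
    "topmax",
    "tmax",
    "rmin",
    "ropmin",
    "ropmax",
    "rmax",
    "phmin",
    "phopmin",
    "phopmax",
    "phmax",
    "has_mapspam",
]

_NUMERIC_FIELDS = REGISTRY_COLUMNS[2:-1]


@dataclass(frozen=True)
class CropParameters:
    """Niche parameters for a single crop."""

    crop_code: str
    crop_class: str
    gmin: float
    gmax: float
    ktmp: float
    tmin: float
    topmin: float
    topmax: float
    tmax: float
    rmin: float
    ropmin: float
    ropmax: float
    rmax: float
    phmin: float
    phopmin: float
    phopmax: float
    phmax: float
    has_mapspam: bool = True

    def replace(self, **changes) -> "CropParameters":
        return dataclasses.replace(self, **changes)


def validate_parameters(p: CropParameters) -> list[str]:
    """Return a list of invariant violations (empty list when valid).

    Violations are reported, not raised, so callers can aggregate them
    across a whole table before failing.
    """
    violations: list[str] = []

    def _ordered(a: str, b: str) -> None:
        va, vb = getattr(p, a), getattr(p, b)
        if not va <= vb:
            violations.append(f"{a} ≤ {b} violated: {a}={va}, {b}={vb}")

    _ordered("tmin", "topmin")
    _ordered("topmin", "topmax")
    _ordered("topmax", "tmax")
    _ordered("rmin", "ropmin")
    _ordered("ropmin", "ropmax")
    _ordered("ropmax", "rmax")
    _ordered("phmin", "phopmin")
    _ordered("phopmin", "phopmax")
    _ordered("phopmax", "phmax")
    _ordered("ktmp", "tmin")
    if not 30 <= p.gmin:
        violations.append(f"30 ≤ gmin violated: gmin={p.gmin}")
    _ordered("gmin", "gmax")
    if not p.gmax <= 365:
        violations.append(f"gmax ≤ 365 violated: gmax={p.gmax}")
    if p.crop_class not in CROP_CLASSES:
        violations.append(
            f"crop_class must be one of {CROP_CLASSES}: got {p.crop_class!r}"
        )
    return violations


class CropRegistry(Mapping[str, CropParameters]):
    """Mapping of crop code -> :class:`CropParameters`.

    Lookup is case-sensitive on the archive tokens (``maize``,
    ``pmillet``, ...).  Unknown extra CSV columns are preserved for
    round-tripping.
    """

    def __init__(self, entries: dict[str, CropParameters], extra: pd.DataFrame | None = None):
        self._entries = dict(entries)
        self._extra = extra

    def __getitem__(self, code: str) -> CropParameters:
        return self._entries[code]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def crops(self) -> list[str]:
        return list(self._entries)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CROP_CLASSES}
        for p in self._entries.values():
            counts[p.crop_class] = counts.get(p.crop_class, 0) + 1
        return counts

    def mapspam_crops(self) -> list[str]:
        return [c for c, p in self._entries.items() if p.has_mapspam]

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(p) for p in self._entries.values()]
        frame = pd.DataFrame(rows, columns=REGISTRY_COLUMNS)
        if self._extra is not None and not self._extra.empty:
            frame = pd.concat([frame.reset_index(drop=True), self._extra.reset_index(drop=True)], axis=1)
        return frame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CropRegistry):
            return NotImplemented
        return self._entries == other._entries


class RegistryError(ValueError):
    """Raised when a parameter table fails to load or validate."""


def _default_source():
    return resources.files("cropsuit.data").joinpath("crops.csv")


def load_registry(source: str | Path | None = None) -> CropRegistry:
    """Load a crop parameter table from CSV.

    ``source=None`` loads the packaged default table of 23 crops.
    Raises :class:`RegistryError` naming the offending row/column on
    missing columns, duplicate crop codes, non-numeric values, or
    niche-ordering violations.
    """
    if source is None:
        with resources.as_file(_default_source()) as path:
            frame = pd.read_csv(path)
    else:
        frame = pd.read_csv(source)

    missing = [c for c in REGISTRY_COLUMNS if c not in frame.columns]
    if missing:
        raise RegistryError(f"missing column(s): {', '.join(missing)}")

    dupes = frame["crop_code"][frame["crop_code"].duplicated()].tolist()
    if dupes:
        raise RegistryError(f"duplicate crop_code(s): {', '.join(map(str, dupes))}")

    entries: dict[str, CropParameters] = {}
    problems: list[str] = []
    for _, row in frame.iterrows():
        code = str(row["crop_code"])
        values: dict[str, float] = {}
        for col in _NUMERIC_FIELDS:
            try:
                values[col] = float(row[col])
            except (TypeError, ValueError):
                problems.append(f"crop {code!r}: non-numeric value in column {col!r}: {row[col]!r}")
        if problems:
            continue
        p = CropParameters(
            crop_code=code,
            crop_class=str(row["crop_class"]),
            has_mapspam=_parse_flag(row["has_mapspam"]),
            **values,
        )
        for v in validate_parameters(p):
            problems.append(f"crop {code!r}: {v}")
        entries[code] = p

    if problems:
        raise RegistryError("; ".join(problems))

    extra_cols = [c for c in frame.columns if c not in REGISTRY_COLUMNS]
    extra = frame[extra_cols] if extra_cols else None
    return CropRegistry(entries, extra)


def _parse_flag(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes", "t"}
    return bool(value)


def save_registry(registry: CropRegistry, path: str | Path) -> None:
    """Write a registry back to CSV (canonical column order, '.' decimal)."""
    frame = registry.to_frame().copy()
    frame["has_mapspam"] = frame["has_mapspam"].map(lambda b: "true" if b else "false")
    frame.to_csv(path, index=False)
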