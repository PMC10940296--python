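"""Binary classification and iterative calibration.

Builds binary reference grids from yield surfaces, selects the threshold
that equalizes sensitivity and specificity, binarizes suitability maps,
and runs the two-stage rainfall / temperature calibration loop against a
reference grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ClimateStack, EngineConfig, SuitabilityMap, map_suitability
from .geo import GeometryError
from .registry import CropParameters, validate_parameters

__all__ = [
    "ReferenceGrid",
    "ThresholdResult",
    "CalibrationTrace",
    "reference_from_yield",
    "confusion_rates",
    "equalize_se_sp",
    "binarize",
    "match_score",
    "calibrate_rainfall",
    "calibrate_temperature",
]


@dataclass
class ReferenceGrid:
    """Binary suitable/unsuitable labels plus the evaluation mask."""

    labels: np.ndarray       # bool, defined wherever mask is True
    mask: np.ndarray         # bool: cells included in scoring
    percentile_value: float = float("nan")


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float
    candidates: int

    @property
    def gap(self) -> float:
        return abs(self.sensitivity - self.specificity)


@dataclass
class CalibrationTrace:
    """Ordered evaluation log of a calibration run."""

    rows: list[dict] = field(default_factory=list)
    status: str = ""          # "converged" | "retained_best"

    def record(self, iteration: int, params: CropParameters,
               threshold: float, match: float, **extra) -> None:
        row = {
            "iteration": iteration,
            "rmin": params.rmin, "ropmin": params.ropmin,
            "ropmax": params.ropmax, "rmax": params.rmax,
            "ktmp": params.ktmp, "tmin": params.tmin,
            "topmin": params.topmin, "topmax": params.topmax, "tmax": params.tmax,
            "threshold": threshold, "match": match,
        }
        row.update(extra)
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def best_index(self) -> int:
        matches = [r["match"] for r in self.rows]
        return int(np.argmax(matches))


def reference_from_yield(yield_grid: np.ndarray, percentile: float = 25.0) -> ReferenceGrid:
    """Label cells below the given percentile of positive yield unsuitable.

    The percentile (linear interpolation between order statistics) is
    computed over cells with yield > 0 only.  Zero-yield cells are
    labelled unsuitable; cells with undefined yield fall outside the
    evaluation mask.
    """
    y = np.asarray(yield_grid, dtype=float)
    mask = np.isfinite(y)
    positive = y[mask & (y > 0)]
    if positive.size == 0:
        raise ValueError("no cell with positive yield; cannot build reference")
    cut = float(np.percentile(positive, percentile))
    labels = np.zeros(y.shape, dtype=bool)
    labels[mask] = y[mask] >= cut
    return ReferenceGrid(labels=labels, mask=mask, percentile_value=cut)


def _check_two_classes(labels: np.ndarray) -> None:
    if not labels.any() or labels.all():
        raise ValueError("labels contain a single class; need positives and negatives")


def confusion_rates(scores: np.ndarray, labels: np.ndarray,
                    threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) of ``score >= threshold`` predictions."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    pred = scores >= threshold
    tp = np.count_nonzero(pred & labels)
    fn = np.count_nonzero(~pred & labels)
    tn = np.count_nonzero(~pred & ~labels)
    fp = np.count_nonzero(pred & ~labels)
    return tp / (tp + fn), tn / (tn + fp)


def equalize_se_sp(scores: np.ndarray, labels: np.ndarray) -> ThresholdResult:
    """Threshold minimizing |Se − Sp| over all distinct score values
    (plus 0 and 1).  Ties break toward larger Se + Sp, then toward the
    smaller threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if np.isnan(scores).any():
        keep = ~np.isnan(scores)
        scores, labels = scores[keep], labels[keep]
    _check_two_classes(labels)

    cands = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    # Se(t) = #(pos >= t)/P, Sp(t) = #(neg < t)/N — step functions, so the
    # optimum over all real thresholds is attained at an observed score.
    se = (pos.size - np.searchsorted(pos, cands, side="left")) / pos.size
    sp = np.searchsorted(neg, cands, side="left") / neg.size
    gap = np.abs(se - sp)
    order = np.lexsort((cands, -(se + sp), gap))
    best = order[0]
    return ThresholdResult(
        threshold=float(cands[best]),
        sensitivity=float(se[best]),
        specificity=float(sp[best]),
        candidates=int(cands.size),
    )


def binarize(smap: SuitabilityMap | np.ndarray, threshold: float) -> np.ndarray:
    """Suitable (1.0) iff score >= threshold; NaN propagates."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    values = smap.values if isinstance(smap, SuitabilityMap) else np.asarray(smap, dtype=float)
    with np.errstate(invalid="ignore"):
        out = (values >= threshold).astype(float)
    out[np.isnan(values)] = np.nan
    return out


def match_score(binary: np.ndarray, reference: ReferenceGrid) -> float:
    """Overall accuracy: proportion of masked cells where the binary map
    agrees with the reference label.
    """
    if binary.shape != reference.labels.shape:
        raise GeometryError("binary map and reference must share geometry")
    mask = reference.mask & np.isfinite(binary)
    n = np.count_nonzero(mask)
    if n == 0:
        raise ValueError("empty evaluation mask")
    agree = (binary[mask] > 0) == reference.labels[mask]
    return float(np.count_nonzero(agree) / n)


# ---------------------------------------------------------------------------
# calibration

def _evaluate(p: CropParameters, stack: ClimateStack, ph: np.ndarray,
              reference: ReferenceGrid, cfg: EngineConfig) -> tuple[float, float]:
    """Run the engine under ``p`` and score it against the reference.

    Returns (Se=Sp threshold, match score).
    """
    smap = map_suitability(stack, ph, p, cfg, validate=False)
    mask = reference.mask & np.isfinite(smap.values)
    th = equalize_se_sp(smap.values[mask], reference.labels[mask])
    binary = binarize(smap, th.threshold)
    return th.threshold, match_score(binary, reference)


def calibrate_rainfall(p: CropParameters, stack: ClimateStack, ph: np.ndarray,
                       reference: ReferenceGrid, cfg: EngineConfig | None = None,
                       step: float = 10.0, target: float = 0.7,
                       floor: float = 0.0) -> tuple[CropParameters, CalibrationTrace]:
    """Decrement the rainfall minima (rmin, ropmin) by ``step`` mm until
    the match score reaches ``target`` or both minima hit ``floor``.

    The starting state counts as iteration 0.  If the target is never
    reached, the best-scoring (earliest on ties) state is retained.
    """
    cfg = cfg or EngineConfig()
    if step <= 0:
        raise ValueError("step must be positive")
    problems = validate_parameters(p)
    if problems:
        raise ValueError("invalid crop parameters: " + "; ".join(problems))

    trace = CalibrationTrace()
    states = []
    current = p
    iteration = 0
    while True:
        threshold, match = _evaluate(current, stack, ph, reference, cfg)
        trace.record(iteration, current, threshold, match)
        states.append(current)
        if match >= target:
            trace.status = "converged"
            return current, trace
        if current.rmin <= floor and current.ropmin <= floor:
            break
        current = current.replace(
            rmin=max(floor, current.rmin - step),
            ropmin=max(floor, current.ropmin - step),
        )
        iteration += 1

    trace.status = "retained_best"
    return states[trace.best_index], trace


def _offset_order(limit: int) -> list[tuple[int, int]]:
    """(ktmp offset, niche offset) pairs ordered by ascending total shift."""
    pairs = [(k, n) for k in range(-limit, limit + 1) for n in range(-limit, limit + 1)]
    pairs.sort(key=lambda kn: (abs(kn[0]) + abs(kn[1]), max(abs(kn[0]), abs(kn[1])),
                               kn[1] < 0, kn[0] < 0, abs(kn[1]), abs(kn[0])))
    return pairs


def calibrate_temperature(p: CropParameters, stack: ClimateStack, ph: np.ndarray,
                          reference: ReferenceGrid, cfg: EngineConfig | None = None,
                          limit: int = 5, target: float = 0.7
                          ) -> tuple[CropParameters, CalibrationTrace]:
    """Grid-search ±``limit`` °C offsets of the kill temperature and of the
    temperature niche (tmin..tmax shifted as a block), nearest offsets
    first; stop at the first state reaching ``target``.
    """
    cfg = cfg or EngineConfig()
    problems = validate_parameters(p)
    if problems:
        raise ValueError("invalid crop parameters: " + "; ".join(problems))

    trace = CalibrationTrace()
    states = []
    for i, (koff, noff) in enumerate(_offset_order(limit)):
        cand = p.replace(
            ktmp=p.ktmp + koff,
            tmin=p.tmin + noff, topmin=p.topmin + noff,
            topmax=p.topmax + noff, tmax=p.tmax + noff,
        )
        threshold, match = _evaluate(cand, stack, ph, reference, cfg)
        trace.record(i, cand, threshold, match, ktmp_offset=koff, niche_offset=noff)
        states.append(cand)
        if match >= target:
            trace.status = "converged"
            return cand, trace

    trace.status = "retained_best"
    return states[trace.best_index], trace
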