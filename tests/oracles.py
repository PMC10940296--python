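"""Independent brute-force reference implementations.

These deliberately use plain Python loops and textbook formulas, sharing
no code with the package, so each test checks two routes to the same
number.
"""

import math

import numpy as np


def trapezoid_scalar(x, amin, omin, omax, amax):
    if math.isnan(x):
        return float("nan")
    if omin <= x <= omax:
        return 1.0
    if x <= amin or x >= amax:
        return 0.0
    if x < omin:
        return (x - amin) / (omin - amin)
    return (amax - x) / (amax - omax)


def cell_suitability_loop(tmean, prec, ph, p, frost_buffer=4.0,
                          tminm=None, combine="product", ph_rule="product"):
    """Scalar re-derivation of one cell's suitability (all 12 windows)."""

    def comb(a, b, rule):
        return a * b if rule == "product" else min(a, b)

    months = math.floor((p.gmin + p.gmax) / 60.0 + 0.5)
    duration = min(12, max(1, months))
    kill = tmean if tminm is None else tminm
    best = None
    for start in range(12):
        window = [(start + k) % 12 for k in range(duration)]
        tscore = 1.0
        for m in window:
            if math.isnan(tmean[m]) or math.isnan(kill[m]):
                return float("nan")
            if kill[m] < p.ktmp + frost_buffer:
                s = 0.0
            else:
                s = trapezoid_scalar(tmean[m], p.tmin, p.topmin, p.topmax, p.tmax)
            tscore = min(tscore, s)
        total = 0.0
        for m in window:
            if math.isnan(prec[m]):
                return float("nan")
            total += prec[m]
        rscore = trapezoid_scalar(total, p.rmin, p.ropmin, p.ropmax, p.rmax)
        score = comb(tscore, rscore, combine)
        best = score if best is None else max(best, score)
    if math.isnan(ph):
        return float("nan")
    return comb(best, trapezoid_scalar(ph, p.phmin, p.phopmin, p.phopmax, p.phmax),
                ph_rule)


def map_suitability_loop(stack, ph_grid, p, frost_buffer=4.0,
                         combine="product", ph_rule="product"):
    ny, nx = ph_grid.shape
    out = np.full((ny, nx), np.nan)
    for i in range(ny):
        for j in range(nx):
            if not stack.land_mask[i, j]:
                continue
            tminm = None if stack.tminm is None else [stack.tminm[m, i, j] for m in range(12)]
            out[i, j] = cell_suitability_loop(
                [stack.tmean[m, i, j] for m in range(12)],
                [stack.prec[m, i, j] for m in range(12)],
                float(ph_grid[i, j]), p, frost_buffer, tminm, combine, ph_rule)
    return out


def percentile_sorted(values, q):
    """Linear-interpolation percentile from first principles."""
    v = sorted(values)
    if not v:
        raise ValueError("empty")
    pos = (len(v) - 1) * q / 100.0
    lo = math.floor(pos)
    hi = math.ceil(pos)
    return v[lo] + (v[hi] - v[lo]) * (pos - lo)


def se_sp_scan(scores, labels):
    """Exhaustive candidate scan for the Se=Sp threshold (O(n·c))."""
    cands = sorted(set(list(scores) + [0.0, 1.0]))
    best = None
    for t in cands:
        tp = fn = tn = fp = 0
        for s, y in zip(scores, labels):
            pred = s >= t
            if y and pred:
                tp += 1
            elif y:
                fn += 1
            elif pred:
                fp += 1
            else:
                tn += 1
        se = tp / (tp + fn)
        sp = tn / (tn + fp)
        key = (abs(se - sp), -(se + sp), t)
        if best is None or key < best[0]:
            best = (key, t, se, sp)
    return best[1], best[2], best[3]


def cell_area_spherical(lat_deg, res_deg, radius_km=6371.0):
    """Spherical-cap band slice, evaluated independently."""
    phi1 = math.radians(lat_deg - res_deg / 2.0)
    phi2 = math.radians(lat_deg + res_deg / 2.0)
    return radius_km ** 2 * math.radians(res_deg) * (math.sin(phi2) - math.sin(phi1))


def pearson_hand(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
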