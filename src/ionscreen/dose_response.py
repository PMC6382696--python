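"""Hill-model concentration-response machinery.

Shared by the fluorescence (eYFP / Ca-flux), patch-clamp, and organ-bath
analyses.  The model is the four-parameter logistic in log-concentration

    response(c) = bottom + (top - bottom) / (1 + (c / midpoint) ** hill_slope)

with ``top`` the zero-concentration asymptote and ``bottom`` the
infinite-concentration asymptote; ``hill_slope`` is always positive and the
curve is descending when ``top > bottom`` (inhibition) and ascending when
``top < bottom`` (e.g. contraction or relaxation read-outs).

Two named fitting presets cover the screen's use cases:

``fit_partial_efficacy``
    Free four-parameter fit.  Used for the 22-point eYFP dose responses,
    where partial blockers plateau well short of full inhibition, so the
    high-concentration asymptote must stay free.

``fit_normalized_group``
    Pooled fit with asymptotes constrained to 1 (vehicle) and 0 (full
    block), applied to vehicle-normalized patch-clamp responses pooled
    across cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ConcResponsePoint",
    "ConcResponseFit",
    "hill_model",
    "fit_hill",
    "fit_partial_efficacy",
    "fit_normalized_group",
    "ec_fraction",
    "dilution_series",
    "fits_to_frame",
    "write_fits_csv",
    "read_fits_csv",
]

# Midpoint search window: this many decades beyond the tested range.
_MIDPOINT_PAD_DECADES = 2.0
_SLOPE_BOUNDS = (0.1, 10.0)
_N_GRID = 40
# A fit only claims a midpoint when its amplitude is resolvable above the
# residual noise; below this span/RMS ratio the response is indistinguishable
# from a flat curve and the fit is censored.
_MIN_SPAN_RMS_RATIO = 6.0


@dataclass(frozen=True)
class ConcResponsePoint:
    """One (concentration, response) observation.

    concentration is in μM and must be positive; replicate identifies the
    contributing well/cell/ring when points are pooled.
    """

    concentration: float
    response: float
    replicate: str | None = None

    def __post_init__(self) -> None:
        if not (self.concentration > 0):
            raise ValueError(f"concentration must be > 0, got {self.concentration}")
        if not math.isfinite(self.response):
            raise ValueError("response must be finite")


@dataclass
class ConcResponseFit:
    """Fitted Hill parameters plus convergence/censoring bookkeeping.

    ``converged`` is False for censored fits; ``censored_at`` then carries
    the tested-concentration bound the midpoint fell beyond (top tested
    concentration for "no crossing within range", lowest tested for fully
    saturated responses).
    """

    midpoint: float
    hill_slope: float
    top: float
    bottom: float
    converged: bool = True
    censored_at: float | None = None
    residual_rms: float = 0.0
    n_points: int = 0

    def predict(self, c):
        return hill_model(c, self.midpoint, self.hill_slope, self.top, self.bottom)


def hill_model(c, midpoint: float, hill_slope: float = 1.0,
               top: float = 1.0, bottom: float = 0.0):
    """Four-parameter logistic response at concentration ``c`` (μM).

    Vectorized over ``c``.  ``top`` is the response as c → 0, ``bottom`` the
    response as c → ∞; with ``top > bottom`` and ``hill_slope > 0`` the curve
    descends (inhibition convention).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if midpoint <= 0:
        raise ValueError("midpoint must be > 0")
    out = bottom + (top - bottom) / (1.0 + (c / midpoint) ** hill_slope)
    return float(out) if out.ndim == 0 else out


def _as_arrays(points: Iterable) -> tuple[np.ndarray, np.ndarray]:
    conc, resp = [], []
    for p in points:
        if isinstance(p, ConcResponsePoint):
            conc.append(p.concentration)
            resp.append(p.response)
        else:
            c, r = p[0], p[1]
            conc.append(float(c))
            resp.append(float(r))
    c = np.asarray(conc, dtype=float)
    y = np.asarray(resp, dtype=float)
    if c.size == 0:
        raise ValueError("no concentration-response points supplied")
    if np.any(c <= 0):
        raise ValueError("non-positive concentrations are not allowed")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite responses are not allowed")
    return c, y


def fit_hill(points: Iterable, *, top: float | None = None,
             bottom: float | None = None) -> ConcResponseFit:
    """Least-squares Hill fit in log10-concentration space.

    ``top`` / ``bottom`` fix the respective asymptote when given a number and
    leave it free when None.  Requires ≥ 4 distinct concentrations for a free
    fit, ≥ 3 with one asymptote fixed, ≥ 2 with both fixed.

    Initialization scans a log-spaced grid of midpoint candidates (slope 1);
    for each candidate the asymptotes are solved linearly, the best candidate
    (ties broken toward the lowest midpoint) seeds a bounded refinement.
    Fits whose midpoint falls outside the tested concentration range — i.e.
    the curve never crosses its half-maximal response within tested
    concentrations — are returned censored rather than extrapolated.
    """
    c, y = _as_arrays(points)
    n_free_asym = (top is None) + (bottom is None)
    n_distinct = np.unique(c).size
    if n_distinct < 2 + n_free_asym:
        raise ValueError(
            f"need at least {2 + n_free_asym} distinct concentrations, got {n_distinct}"
        )

    cmin, cmax = float(c.min()), float(c.max())
    if np.ptp(y) == 0.0:
        # Flat responses carry no midpoint information.
        t = top if top is not None else float(y[0])
        b = bottom if bottom is not None else float(y[0])
        return ConcResponseFit(midpoint=cmax, hill_slope=1.0, top=t, bottom=b,
                               converged=False, censored_at=cmax,
                               residual_rms=0.0, n_points=int(y.size))

    x = np.log10(c)
    lo, hi = x.min() - _MIDPOINT_PAD_DECADES, x.max() + _MIDPOINT_PAD_DECADES

    def solve_asymptotes(lm: float, slope: float) -> tuple[float, float, float]:
        """Given midpoint+slope, best top/bottom (respecting fixes) and SSE."""
        w = 1.0 / (1.0 + 10.0 ** (slope * (x - lm)))  # weight of `top`
        if top is None and bottom is None:
            a = np.column_stack([w, 1.0 - w])
            coef, *_ = np.linalg.lstsq(a, y, rcond=None)
            t, b = float(coef[0]), float(coef[1])
        elif top is None:
            resid = y - bottom * (1.0 - w)
            denom = float(w @ w)
            t = float(w @ resid) / denom if denom > 0 else float(y.mean())
            b = float(bottom)
        elif bottom is None:
            resid = y - top * w
            omw = 1.0 - w
            denom = float(omw @ omw)
            b = float(omw @ resid) / denom if denom > 0 else float(y.mean())
            t = float(top)
        else:
            t, b = float(top), float(bottom)
        sse = float(np.sum((t * w + b * (1.0 - w) - y) ** 2))
        return t, b, sse

    grid = np.linspace(lo, hi, _N_GRID)
    sses = np.empty(_N_GRID)
    asyms = []
    for i, lm in enumerate(grid):
        t, b, sse = solve_asymptotes(lm, 1.0)
        sses[i] = sse
        asyms.append((t, b))
    # Ascending grid + first-minimum pick ⇒ ties resolve to lowest midpoint.
    best = int(np.nonzero(sses <= sses.min() * (1.0 + 1e-12))[0][0])
    lm0 = float(grid[best])
    t0, b0 = asyms[best]

    p0, lb, ub = [lm0, 1.0], [lo, _SLOPE_BOUNDS[0]], [hi, _SLOPE_BOUNDS[1]]
    span = max(np.ptp(y), 1e-12)
    if top is None:
        p0.append(t0); lb.append(y.min() - 10 * span); ub.append(y.max() + 10 * span)
    if bottom is None:
        p0.append(b0); lb.append(y.min() - 10 * span); ub.append(y.max() + 10 * span)

    # The linear asymptote solve can land outside the refinement box when a
    # grid candidate sits at the edge of the midpoint window.
    p0 = np.clip(p0, lb, ub)

    def unpack(p):
        lm, slope = p[0], p[1]
        k = 2
        if top is None:
            t = p[k]; k += 1
        else:
            t = top
        if bottom is None:
            b = p[k]
        else:
            b = bottom
        return lm, slope, t, b

    def residuals(p):
        lm, slope, t, b = unpack(p)
        w = 1.0 / (1.0 + 10.0 ** (slope * (x - lm)))
        return t * w + b * (1.0 - w) - y

    sol = least_squares(residuals, p0, bounds=(lb, ub), method="trf", xtol=1e-12,
                        ftol=1e-12, gtol=1e-12)
    lm, slope, t, b = unpack(sol.x)
    midpoint = float(10.0 ** lm)
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))

    fit = ConcResponseFit(midpoint=midpoint, hill_slope=float(slope), top=float(t),
                          bottom=float(b), converged=bool(sol.success),
                          residual_rms=rms, n_points=int(y.size))
    # Censoring: midpoint (= half-maximal crossing of the monotone curve)
    # outside the tested range means the data never cross half-maximum; an
    # amplitude smaller than a few residual RMS means no response at all.
    if abs(t - b) < _MIN_SPAN_RMS_RATIO * rms:
        fit.converged = False
        fit.censored_at = cmax
    elif midpoint > cmax:
        fit.converged = False
        fit.censored_at = cmax
    elif midpoint < cmin:
        fit.converged = False
        fit.censored_at = cmin
    return fit


def fit_partial_efficacy(points: Iterable) -> ConcResponseFit:
    """Free four-parameter fit (eYFP 22-point preset; bottom stays free so
    partial blockers are not forced to full inhibition)."""
    return fit_hill(points)


def fit_normalized_group(points: Iterable) -> ConcResponseFit:
    """Pooled fit on vehicle-normalized responses with asymptotes constrained
    to 1 (baseline) and 0 (full block) — patch-clamp group preset."""
    return fit_hill(points, top=1.0, bottom=0.0)


def ec_fraction(ec50: float, hill_slope: float, fraction_percent: float) -> float:
    """Concentration producing F% of the maximal effect.

    EC_F = EC50 · (F / (100 − F)) ** (1 / hill_slope); F must lie in (0, 100).
    """
    if not (ec50 > 0):
        raise ValueError("ec50 must be > 0")
    if not (hill_slope > 0):
        raise ValueError("hill_slope must be > 0")
    f = float(fraction_percent)
    if not (0.0 < f < 100.0):
        raise ValueError("fraction_percent must be in (0, 100)")
    return float(ec50 * (f / (100.0 - f)) ** (1.0 / hill_slope))


def dilution_series(top: float, factor: float, n: int) -> np.ndarray:
    """Ascending n-point serial dilution ending at ``top`` μM.

    dilution_series(30, 5, 5) reproduces the 1:5 cumulative patch-clamp
    series 0.048, 0.24, 1.2, 6, 30 μM.
    """
    if not (top > 0):
        raise ValueError("top concentration must be > 0")
    if not (factor > 1):
        raise ValueError("dilution factor must be > 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    powers = np.arange(n - 1, -1, -1, dtype=float)
    return top / factor ** powers


# ---------------------------------------------------------------------------
# Serialization

def fits_to_frame(fits: dict[str, ConcResponseFit], assay: str = "") -> pd.DataFrame:
    rows = []
    for cid, f in fits.items():
        rows.append({
            "compound_id": cid, "assay": assay, "midpoint_uM": f.midpoint,
            "hill_slope": f.hill_slope, "top": f.top, "bottom": f.bottom,
            "converged": f.converged, "censored_at_uM": f.censored_at,
            "residual_rms": f.residual_rms, "n_points": f.n_points,
        })
    return pd.DataFrame(rows)


def write_fits_csv(fits: dict[str, ConcResponseFit], path, assay: str = "") -> None:
    fits_to_frame(fits, assay).to_csv(path, index=False)


def read_fits_csv(path) -> dict[str, ConcResponseFit]:
    df = pd.read_csv(path)
    out: dict[str, ConcResponseFit] = {}
    for _, r in df.iterrows():
        cens = r.get("censored_at_uM")
        out[str(r["compound_id"])] = ConcResponseFit(
            midpoint=float(r["midpoint_uM"]), hill_slope=float(r["hill_slope"]),
            top=float(r["top"]), bottom=float(r["bottom"]),
            converged=bool(r["converged"]),
            censored_at=None if pd.isna(cens) else float(cens),
            residual_rms=float(r.get("residual_rms", 0.0)),
            n_points=int(r.get("n_points", 0)),
        )
    return out
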