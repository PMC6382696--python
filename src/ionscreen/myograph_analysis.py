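"""Wire-myograph tension-trace analysis.

A ring experiment is a tension time series punctuated by events: ascending
contractant (carbachol) doses for per-ring calibration, test-compound doses
on a pre-contracted ring, washes, and a final theophylline addition that
defines the 100%-relaxation floor.  Analyses:

* plateau extraction — trailing-window mean before the next event, accepted
  as a plateau only when the within-window slope is small;
* per-ring calibration — Hill fit of plateau tension vs contractant
  concentration, from which EC25/EC50/EC75/EC95 are derived;
* theophylline-anchored percent relaxation — 0% at the contracted tension,
  100% at the post-theophylline floor, linear in tension and not clamped
  (rings can relax below the floor);
* bronchodilation EC50 — ascending Hill fit of percent relaxation, censored
  when 50% relaxation is never reached;
* onset-of-action timing — elapsed time from a dose until tension first
  comes within a set fraction of its post-dose plateau span.

Concentrations are μM throughout (theophylline's 2.2 mM is carried as
2200 μM); tension is mN.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import (ConcResponseFit, ConcResponsePoint, ec_fraction,
                            fit_hill)

__all__ = [
    "EventKind",
    "Event",
    "TensionTrace",
    "RingCalibration",
    "PlateauResult",
    "OnsetResult",
    "RingDisqualifiedError",
    "plateau_tension",
    "calibrate_ring",
    "percent_relaxation",
    "bronchodilation_ec50",
    "onset_time",
    "read_tension_csv",
    "write_tension_csv",
    "DEFAULT_PLATEAU_WINDOW_S",
    "DEFAULT_SLOPE_TOL_MN_PER_S",
]

DEFAULT_PLATEAU_WINDOW_S = 30.0
DEFAULT_SLOPE_TOL_MN_PER_S = 0.005


class EventKind(enum.Enum):
    DOSE_CONTRACTANT = "DOSE_CONTRACTANT"
    DOSE_TEST = "DOSE_TEST"
    DOSE_THEOPHYLLINE = "DOSE_THEOPHYLLINE"
    WASH = "WASH"


@dataclass(frozen=True)
class Event:
    time_s: float
    kind: EventKind
    conc_uM: float | None = None


class RingDisqualifiedError(ValueError):
    """Raised when a ring fails tissue qualification (non-monotone or flat
    contraction response)."""


@dataclass
class TensionTrace:
    """Force time series for one tissue ring with dose/wash event markers."""

    ring_id: str
    times: np.ndarray
    tension: np.ndarray
    events: list[Event]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tension = np.asarray(self.tension, dtype=float)
        if self.times.shape != self.tension.shape or self.times.ndim != 1:
            raise ValueError("times and tension must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.tension < 0):
            raise ValueError("tension must be >= 0")
        self.events = sorted(self.events, key=lambda e: e.time_s)
        theo = [e for e in self.events if e.kind is EventKind.DOSE_THEOPHYLLINE]
        if len(theo) > 1:
            raise ValueError("at most one theophylline event per trace")
        if theo:
            doses = [e for e in self.events if e.kind is not EventKind.WASH]
            if doses[-1].kind is not EventKind.DOSE_THEOPHYLLINE:
                raise ValueError("theophylline must be the last dose event")

    def events_of_kind(self, kind: EventKind) -> list[tuple[int, Event]]:
        return [(i, e) for i, e in enumerate(self.events) if e.kind is kind]

    def segment_end(self, event_index: int) -> float:
        """End time of the segment started by the given event (the next
        event's time, or the end of the trace)."""
        t_next = [e.time_s for e in self.events[event_index + 1:]]
        return min(t_next) if t_next else float(self.times[-1])


@dataclass
class PlateauResult:
    value_mN: float
    plateaued: bool
    short_window: bool = False


@dataclass
class OnsetResult:
    time_s: float
    censored: bool


@dataclass
class RingCalibration:
    """Per-ring contractant sensitivity: fitted contraction curve and the
    EC25 < EC50 < EC75 < EC95 concentrations derived from it."""

    ec25: float
    ec50: float
    ec75: float
    ec95: float
    contraction_fit: ConcResponseFit
    baseline_mN: float

    def __post_init__(self) -> None:
        if not (self.ec25 < self.ec50 < self.ec75 < self.ec95):
            raise ValueError("EC fractions must be strictly increasing")

    def ec(self, fraction_percent: float) -> float:
        return ec_fraction(self.contraction_fit.midpoint,
                           self.contraction_fit.hill_slope, fraction_percent)


def plateau_tension(trace: TensionTrace, event_index: int,
                    window_s: float = DEFAULT_PLATEAU_WINDOW_S,
                    slope_tol: float = DEFAULT_SLOPE_TOL_MN_PER_S) -> PlateauResult:
    """Mean tension over the trailing window before the next event.

    Accepted as a plateau only when the within-window slope magnitude is at
    most ``slope_tol`` (mN/s); otherwise the value is still returned with
    ``plateaued=False``.  A window truncated by the end of the trace is
    flagged ``short_window``.
    """
    event = trace.events[event_index]
    t_end = trace.segment_end(event_index)
    short = t_end >= float(trace.times[-1]) and (t_end - event.time_s) < window_s
    t_start = max(event.time_s, t_end - window_s)
    mask = (trace.times >= t_start) & (trace.times <= t_end)
    if mask.sum() < 2:
        raise ValueError(
            f"ring {trace.ring_id}: fewer than 2 samples after event {event_index}"
        )
    t, y = trace.times[mask], trace.tension[mask]
    slope = float(np.polyfit(t, y, 1)[0])
    return PlateauResult(value_mN=float(y.mean()),
                         plateaued=abs(slope) <= slope_tol,
                         short_window=bool(short))


def calibrate_ring(trace: TensionTrace,
                   window_s: float = DEFAULT_PLATEAU_WINDOW_S,
                   slope_tol: float = DEFAULT_SLOPE_TOL_MN_PER_S,
                   monotone_tol_frac: float = 0.05,
                   min_span_mN: float = 0.2) -> RingCalibration:
    """Fit the ascending-contractant plateau tensions and derive EC fractions.

    The zero-concentration asymptote is fixed at the pre-dose baseline (mean
    tension over the window before the first contractant dose); the maximal
    contraction stays free.  Rings whose plateau sequence decreases by more
    than ``monotone_tol_frac`` of the response span, or whose span is below
    ``min_span_mN``, are disqualified — the tissue-qualification step.
    """
    doses = trace.events_of_kind(EventKind.DOSE_CONTRACTANT)
    if len(doses) < 4:
        raise ValueError("need >= 4 contractant doses to calibrate a ring")
    first_t = doses[0][1].time_s
    pre = (trace.times >= first_t - window_s) & (trace.times < first_t)
    if not pre.any():
        raise ValueError("no pre-dose baseline samples")
    baseline = float(trace.tension[pre].mean())

    concs, plateaus = [], []
    for idx, ev in doses:
        if ev.conc_uM is None or ev.conc_uM <= 0:
            raise ValueError("contractant doses need positive concentrations")
        res = plateau_tension(trace, idx, window_s, slope_tol)
        concs.append(ev.conc_uM)
        plateaus.append(res.value_mN)
    concs = np.asarray(concs)
    plateaus = np.asarray(plateaus)
    span = float(plateaus.max() - baseline)
    if span < min_span_mN:
        raise RingDisqualifiedError(
            f"ring {trace.ring_id}: contraction span {span:.3f} mN below minimum"
        )
    drops = np.diff(plateaus)
    if np.any(drops < -monotone_tol_frac * span):
        raise RingDisqualifiedError(
            f"ring {trace.ring_id}: non-monotone contraction response"
        )

    fit = fit_hill(list(zip(concs, plateaus)), top=baseline)
    if not fit.converged:
        raise RingDisqualifiedError(
            f"ring {trace.ring_id}: contraction curve not resolvable "
            f"(censored at {fit.censored_at} uM)"
        )
    return RingCalibration(
        ec25=ec_fraction(fit.midpoint, fit.hill_slope, 25),
        ec50=fit.midpoint,
        ec75=ec_fraction(fit.midpoint, fit.hill_slope, 75),
        ec95=ec_fraction(fit.midpoint, fit.hill_slope, 95),
        contraction_fit=fit,
        baseline_mN=baseline,
    )


def percent_relaxation(t_contracted: float, t_theophylline: float,
                       t_t) -> float | np.ndarray:
    """Theophylline-anchored relaxation.

    100% contraction is the tension after the contractant dose minus the
    stable post-theophylline tension; relaxation of a test tension T is
    100 · (T_contracted − T) / (T_contracted − T_theophylline).  Exceeds
    100 when tension falls below the theophylline floor (reported as-is).
    """
    if not (t_contracted > t_theophylline):
        raise ValueError("invalid ring: contracted tension must exceed the "
                         "theophylline floor")
    out = 100.0 * (t_contracted - np.asarray(t_t, dtype=float)) \
        / (t_contracted - t_theophylline)
    return float(out) if out.ndim == 0 else out


def bronchodilation_ec50(points, constrain_full_relaxation: bool = False
                         ) -> ConcResponseFit:
    """Ascending Hill fit of percent relaxation vs test-compound dose.

    The zero-dose asymptote is fixed at 0% relaxation; the maximal
    relaxation stays free by default (``constrain_full_relaxation=True``
    fixes it at 100%).  Fits whose curve never reaches 50% relaxation
    within the tested doses are censored at the top tested concentration.
    """
    pts = [p if isinstance(p, ConcResponsePoint) else ConcResponsePoint(p[0], p[1])
           for p in points]
    if len({p.concentration for p in pts}) < 4:
        raise ValueError("need >= 4 test-compound doses")
    bottom = 100.0 if constrain_full_relaxation else None
    fit = fit_hill(pts, top=0.0, bottom=bottom)
    cmax = max(p.concentration for p in pts)
    # Anchored scale: EC50 only meaningful if 50% absolute relaxation is
    # reached within the tested range.
    if fit.converged and fit.predict(cmax) < 50.0:
        fit.converged = False
        fit.censored_at = cmax
    return fit


def onset_time(trace: TensionTrace, event_index: int, fraction: float = 0.95,
               window_s: float = DEFAULT_PLATEAU_WINDOW_S,
               slope_tol: float = DEFAULT_SLOPE_TOL_MN_PER_S) -> OnsetResult:
    """Time from a dose until tension first comes within (1 − fraction) of
    its post-dose plateau span.  Censored at the segment end when the
    trailing window never plateaus."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    event = trace.events[event_index]
    t_end = trace.segment_end(event_index)
    mask = (trace.times > event.time_s) & (trace.times <= t_end)
    if mask.sum() < 2:
        raise ValueError("too few samples after the dose")
    t, y = trace.times[mask], trace.tension[mask]

    res = plateau_tension(trace, event_index, window_s, slope_tol)
    if not res.plateaued:
        return OnsetResult(time_s=float(t[-1] - t[0]), censored=True)
    span = abs(float(y[0]) - res.value_mN)
    tol = (1.0 - fraction) * span
    within = np.abs(y - res.value_mN) <= tol
    idx = int(np.argmax(within))
    if not within[idx]:
        return OnsetResult(time_s=float(t[-1] - t[0]), censored=True)
    return OnsetResult(time_s=float(t[idx] - t[0]), censored=False)


# ---------------------------------------------------------------------------
# CSV interface: tension table (ring_id, time_s, tension_mN) + events table
# (ring_id, time_s, kind, conc_uM).

def write_tension_csv(traces: list[TensionTrace], tension_path, events_path) -> None:
    tension_frames, event_rows = [], []
    for tr in traces:
        tension_frames.append(pd.DataFrame({
            "ring_id": tr.ring_id, "time_s": tr.times, "tension_mN": tr.tension,
        }))
        for e in tr.events:
            event_rows.append({
                "ring_id": tr.ring_id, "time_s": e.time_s, "kind": e.kind.value,
                "conc_uM": np.nan if e.conc_uM is None else e.conc_uM,
            })
    pd.concat(tension_frames, ignore_index=True).to_csv(tension_path, index=False)
    pd.DataFrame(event_rows).to_csv(events_path, index=False)


def read_tension_csv(tension_path, events_path) -> list[TensionTrace]:
    tdf = pd.read_csv(tension_path, dtype={"ring_id": str})
    edf = pd.read_csv(events_path, dtype={"ring_id": str})
    out = []
    for rid, grp in tdf.groupby("ring_id", sort=True):
        grp = grp.sort_values("time_s")
        erows = edf[edf["ring_id"] == rid].sort_values("time_s")
        events = [Event(time_s=float(r["time_s"]), kind=EventKind(r["kind"]),
                        conc_uM=None if pd.isna(r["conc_uM"]) else float(r["conc_uM"]))
                  for _, r in erows.iterrows()]
        out.append(TensionTrace(ring_id=str(rid),
                                times=grp["time_s"].to_numpy(),
                                tension=grp["tension_mN"].to_numpy(),
                                events=events))
    return out
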