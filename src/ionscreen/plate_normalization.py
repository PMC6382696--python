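"""Control-based plate normalization and assay-quality statistics.

Raw Max-Min/Max responses are anchored to the two on-plate control columns:
the neutral control (DMSO only; defines 100% channel activity, POC = 100)
and the full-inhibitor control (benzbromarone; defines 0% activity,
POC = 0).  POC values beyond the control envelope are preserved, never
clamped — stimulators and super-inhibitors are informative.

Plate quality is summarized by S/B and the Z-family statistics

    Z' = 1 − 3·(σ_neutral + σ_inhibitor) / |μ_neutral − μ_inhibitor|

with the Z-factor replacing the neutral controls by the test-well
population, and robust variants (RZ', RZ) substituting median and
1.4826·MAD for mean and SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ControlSummary",
    "PlateQC",
    "normalize_poc",
    "poc_to_poi",
    "membrane_potential_poc",
    "plate_qc",
    "robust_scale",
    "write_qc_csv",
    "DEFAULT_Z_PRIME_MIN",
]

DEFAULT_Z_PRIME_MIN = 0.5  # community-standard acceptance bar


@dataclass(frozen=True)
class ControlSummary:
    """Location/scale of the two control populations on one plate."""

    neutral_mean: float
    neutral_sd: float
    inhibitor_mean: float
    inhibitor_sd: float
    n_neutral: int
    n_inhibitor: int

    def __post_init__(self) -> None:
        if self.n_neutral < 2 or self.n_inhibitor < 2:
            raise ValueError("need >= 2 wells per control role")
        if self.neutral_mean == self.inhibitor_mean:
            raise ValueError("degenerate controls: neutral and inhibitor means equal")

    @classmethod
    def from_responses(cls, neutral: Sequence[float],
                       inhibitor: Sequence[float]) -> "ControlSummary":
        neu = np.asarray(neutral, dtype=float)
        inh = np.asarray(inhibitor, dtype=float)
        if neu.size < 2 or inh.size < 2:
            raise ValueError("need >= 2 wells per control role")
        return cls(
            neutral_mean=float(neu.mean()), neutral_sd=float(neu.std(ddof=1)),
            inhibitor_mean=float(inh.mean()), inhibitor_sd=float(inh.std(ddof=1)),
            n_neutral=int(neu.size), n_inhibitor=int(inh.size),
        )


@dataclass
class PlateQC:
    """Assay-quality statistics for one plate; NaN marks an undefined
    statistic (e.g. too few wells), −inf a degenerate control separation."""

    s_b: float
    z_factor: float
    z_prime: float
    rz_factor: float
    rz_prime: float

    def passes(self, z_prime_min: float = DEFAULT_Z_PRIME_MIN) -> bool:
        return math.isfinite(self.z_prime) and self.z_prime >= z_prime_min


def normalize_poc(response, controls: ControlSummary):
    """Percent-of-control: 100 at the neutral anchor, 0 at the inhibitor
    anchor, linear in the raw response.  Vectorized; not clamped."""
    sep = controls.neutral_mean - controls.inhibitor_mean
    response = np.asarray(response, dtype=float)
    poc = 100.0 * (response - controls.inhibitor_mean) / sep
    return float(poc) if poc.ndim == 0 else poc


def poc_to_poi(poc):
    """Percent inhibition: POI = 100 − POC (an involution)."""
    poi = 100.0 - np.asarray(poc, dtype=float)
    return float(poi) if poi.ndim == 0 else poi


def membrane_potential_poc(auc, hi_controls: Sequence[float],
                           lo_controls: Sequence[float]):
    """Membrane-potential assay POC from baseline-normalized AUCs:

        POC = 100 · (AUC − mean(LO)) / (mean(HI) − mean(LO))

    HI controls are vehicle + contractant (full depolarization), LO controls
    received no contractant."""
    hi = np.asarray(hi_controls, dtype=float)
    lo = np.asarray(lo_controls, dtype=float)
    if hi.size < 2 or lo.size < 2:
        raise ValueError("need >= 2 HI and >= 2 LO control values")
    mh, ml = float(hi.mean()), float(lo.mean())
    if mh == ml:
        raise ValueError("degenerate controls: HI and LO means equal")
    poc = 100.0 * (np.asarray(auc, dtype=float) - ml) / (mh - ml)
    return float(poc) if poc.ndim == 0 else poc


def robust_scale(x: np.ndarray) -> float:
    """1.4826 × MAD — consistent with the SD under a Gaussian."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _z_statistic(a: np.ndarray, b: np.ndarray, robust: bool) -> float:
    if a.size < 2 or b.size < 2:
        return float("nan")
    if robust:
        loc_a, loc_b = np.median(a), np.median(b)
        sc_a, sc_b = robust_scale(a), robust_scale(b)
    else:
        loc_a, loc_b = a.mean(), b.mean()
        sc_a, sc_b = a.std(ddof=1), b.std(ddof=1)
    sep = abs(loc_a - loc_b)
    if sep == 0:
        return float("-inf")
    return float(1.0 - 3.0 * (sc_a + sc_b) / sep)


def plate_qc(neutral: Sequence[float], inhibitor: Sequence[float],
             test: Sequence[float] | None = None) -> PlateQC:
    """Compute S/B and the Z-statistic family from raw per-well responses.

    The Z'-pair uses the two control groups; the Z-pair replaces the neutral
    controls with the test-well population (in an antagonist screen the test
    wells are overwhelmingly inactive and so play the neutral role).  S/B is
    +inf when the inhibitor mean is zero.
    """
    neu = np.asarray(neutral, dtype=float)
    inh = np.asarray(inhibitor, dtype=float)
    tst = np.asarray(test, dtype=float) if test is not None else np.empty(0)
    if inh.mean() != 0:
        s_b = float(neu.mean() / inh.mean()) if neu.size >= 2 and inh.size >= 2 else float("nan")
    else:
        s_b = float("inf")
    return PlateQC(
        s_b=s_b,
        z_prime=_z_statistic(neu, inh, robust=False),
        rz_prime=_z_statistic(neu, inh, robust=True),
        z_factor=_z_statistic(tst, inh, robust=False),
        rz_factor=_z_statistic(tst, inh, robust=True),
    )


def write_qc_csv(qc_by_plate: dict[str, PlateQC], path,
                 z_prime_min: float = DEFAULT_Z_PRIME_MIN) -> None:
    """One row per plate with all five statistics plus a pass/fail flag."""
    rows = []
    for pid, qc in qc_by_plate.items():
        rows.append({
            "plate_id": pid, "s_b": qc.s_b, "z_factor": qc.z_factor,
            "z_prime": qc.z_prime, "rz_factor": qc.rz_factor,
            "rz_prime": qc.rz_prime, "qc_pass": qc.passes(z_prime_min),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
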