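"""Patch-clamp current analysis for cumulative concentration-response runs.

The whole-cell protocol holds cells at 0 mV and steps through an IV family
every 20 s; block is read from the +100 mV step of the *third* IV protocol
run after each solution addition, which guarantees ≥ 60 s of incubation per
concentration.  The per-sweep current statistic is the mean over the
540–550 ms window at the end of the 500-ms step — a steady-state tail
window (a literal per-sample peak would only maximize noise).

Each cell is normalized to its own vehicle-period current before pooling,
removing between-cell current-size variation; pooled points across ≥ 2
cells per concentration feed the constrained "normalized group" Hill fit
(asymptotes 1 and 0) from :mod:`ionscreen.dose_response`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import ConcResponseFit, ConcResponsePoint, fit_normalized_group

__all__ = [
    "SweepRecord",
    "CellSeries",
    "sweep_current",
    "normalize_cell",
    "pooled_concentration_response",
    "percent_inhibition_iwb",
    "average_iwb_inhibition",
    "read_sweeps_csv",
    "write_sweeps_csv",
    "MEASUREMENT_WINDOW_MS",
    "MEASUREMENT_PROTOCOL_IDX",
    "MEASUREMENT_VOLTAGE_MV",
]

MEASUREMENT_WINDOW_MS = (540.0, 550.0)
MEASUREMENT_PROTOCOL_IDX = 3   # third and final IV protocol per addition
MEASUREMENT_VOLTAGE_MV = 100.0  # outward-current step
PROTOCOL_VOLTAGES_MV = tuple(range(-100, 101, 20))


@dataclass
class SweepRecord:
    """Current samples for one voltage step of one IV protocol run.

    ``conc_uM`` is None for vehicle additions.  ``t_ms`` are sample times
    within the step; they must cover the measurement window for measured
    steps.  Currents are signed nA.
    """

    cell_id: str
    addition_idx: int
    protocol_idx: int
    conc_uM: float | None
    voltage_mV: float
    t_ms: np.ndarray
    current_nA: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.current_nA = np.asarray(self.current_nA, dtype=float)
        if self.t_ms.shape != self.current_nA.shape or self.t_ms.ndim != 1:
            raise ValueError("t_ms and current_nA must be matching 1-D arrays")
        if self.voltage_mV not in PROTOCOL_VOLTAGES_MV:
            raise ValueError(
                f"voltage {self.voltage_mV} mV outside the protocol set "
                f"{PROTOCOL_VOLTAGES_MV}"
            )


@dataclass
class CellSeries:
    """Ordered sweeps for one cell across the cumulative addition sequence."""

    cell_id: str
    sweeps: list[SweepRecord]

    def vehicle_additions(self) -> list[int]:
        return sorted({s.addition_idx for s in self.sweeps if s.conc_uM is None})

    def compound_additions(self) -> list[int]:
        return sorted({s.addition_idx for s in self.sweeps if s.conc_uM is not None})


def sweep_current(sweep: SweepRecord) -> float:
    """Steady-state current: mean over the 540–550 ms window of the step."""
    lo, hi = MEASUREMENT_WINDOW_MS
    mask = (sweep.t_ms >= lo) & (sweep.t_ms <= hi)
    if not mask.any():
        raise ValueError(
            f"sweep (cell {sweep.cell_id}, addition {sweep.addition_idx}) has no "
            f"samples in the {lo}-{hi} ms measurement window"
        )
    return float(sweep.current_nA[mask].mean())


def _measurement_sweep(series: CellSeries, addition_idx: int) -> SweepRecord:
    """The +100 mV sweep of the third IV protocol for one addition."""
    candidates = [s for s in series.sweeps
                  if s.addition_idx == addition_idx
                  and s.protocol_idx == MEASUREMENT_PROTOCOL_IDX
                  and s.voltage_mV == MEASUREMENT_VOLTAGE_MV]
    if not candidates:
        raise ValueError(
            f"cell {series.cell_id}, addition {addition_idx}: no +100 mV sweep "
            f"for protocol {MEASUREMENT_PROTOCOL_IDX}"
        )
    return candidates[0]


def normalize_cell(series: CellSeries) -> dict[int, tuple[float | None, float]]:
    """Vehicle-normalized response per addition.

    The reference current is the mean measured current over the vehicle
    additions (≥ 2 required before the first compound addition); each
    addition's response is I_addition / I_vehicle, invariant to the cell's
    absolute current scale.  Returns {addition_idx: (conc_uM, response)}.
    """
    veh = series.vehicle_additions()
    cmp_adds = series.compound_additions()
    if len(veh) < 2:
        raise ValueError(f"cell {series.cell_id}: needs >= 2 vehicle additions")
    if cmp_adds and min(cmp_adds) < max(veh):
        raise ValueError(
            f"cell {series.cell_id}: vehicle additions must precede compounds"
        )
    ref = float(np.mean([sweep_current(_measurement_sweep(series, a)) for a in veh]))
    if ref <= 0:
        raise ValueError(
            f"cell {series.cell_id}: non-positive vehicle reference current; "
            "cell excluded"
        )
    out: dict[int, tuple[float | None, float]] = {}
    for a in veh + cmp_adds:
        sweep = _measurement_sweep(series, a)
        out[a] = (sweep.conc_uM, sweep_current(sweep) / ref)
    return out


def pooled_concentration_response(
        cells: Iterable[CellSeries],
        min_cells_per_conc: int = 2) -> tuple[ConcResponseFit, dict[float, int]]:
    """Assemble all cells' vehicle-normalized (concentration, response)
    points and run the constrained normalized-group fit.

    Concentrations contributed by fewer than ``min_cells_per_conc`` cells
    are flagged and excluded; the fit proceeds while ≥ 2 concentrations
    remain (the constrained fit's minimum).  Returns (fit, cells-per-
    concentration map; flagged concentrations have counts below the minimum).
    """
    points: list[ConcResponsePoint] = []
    cells_per_conc: dict[float, set[str]] = {}
    for series in cells:
        for conc, resp in normalize_cell(series).values():
            if conc is None:
                continue
            points.append(ConcResponsePoint(conc, resp, replicate=series.cell_id))
            cells_per_conc.setdefault(conc, set()).add(series.cell_id)
    counts = {c: len(ids) for c, ids in sorted(cells_per_conc.items())}
    keep = {c for c, n in counts.items() if n >= min_cells_per_conc}
    if len(keep) < 2:
        raise ValueError(
            f"only {len(keep)} concentrations have >= {min_cells_per_conc} cells"
        )
    fit = fit_normalized_group([p for p in points if p.concentration in keep])
    return fit, counts


def percent_inhibition_iwb(i_ta, i_baseline):
    """Perforated-patch percent inhibition: (1 − I_TA / I_baseline) × 100%."""
    i_ta = np.asarray(i_ta, dtype=float)
    i_baseline = np.asarray(i_baseline, dtype=float)
    if np.any(i_baseline == 0):
        raise ValueError("zero baseline current: well excluded")
    out = (1.0 - i_ta / i_baseline) * 100.0
    return float(out) if out.ndim == 0 else out


def average_iwb_inhibition(records: Iterable[tuple[float, float, float]]
                           ) -> dict[float, float]:
    """Mean percent inhibition per concentration from (conc, I_TA,
    I_baseline) replicate records — transform first, then average."""
    per_conc: dict[float, list[float]] = {}
    for conc, i_ta, i_base in records:
        per_conc.setdefault(float(conc), []).append(
            percent_inhibition_iwb(i_ta, i_base))
    return {c: float(np.mean(v)) for c, v in sorted(per_conc.items())}


# ---------------------------------------------------------------------------
# Sweep-table CSV interface
# Columns: cell_id, addition_idx, protocol_idx, conc_uM, voltage_mV, t_ms,
# current_nA; one row per sample.

_SWEEP_COLUMNS = ["cell_id", "addition_idx", "protocol_idx", "conc_uM",
                  "voltage_mV", "t_ms", "current_nA"]


def write_sweeps_csv(cells: Iterable[CellSeries], path) -> None:
    frames = []
    for series in cells:
        for s in series.sweeps:
            frames.append(pd.DataFrame({
                "cell_id": s.cell_id, "addition_idx": s.addition_idx,
                "protocol_idx": s.protocol_idx,
                "conc_uM": np.nan if s.conc_uM is None else s.conc_uM,
                "voltage_mV": s.voltage_mV, "t_ms": s.t_ms,
                "current_nA": s.current_nA,
            }))
    pd.concat(frames, ignore_index=True)[_SWEEP_COLUMNS].to_csv(path, index=False)


def read_sweeps_csv(path) -> list[CellSeries]:
    df = pd.read_csv(path, dtype={"cell_id": str})
    missing = [c for c in _SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sweep table missing columns: {missing}")
    out: list[CellSeries] = []
    for cid, cgrp in df.groupby("cell_id", sort=True):
        sweeps = []
        keys = ["addition_idx", "protocol_idx", "voltage_mV", "conc_uM"]
        for (add, prot, volt, conc), sgrp in cgrp.groupby(keys, sort=True, dropna=False):
            sgrp = sgrp.sort_values("t_ms")
            sweeps.append(SweepRecord(
                cell_id=str(cid), addition_idx=int(add), protocol_idx=int(prot),
                conc_uM=None if pd.isna(conc) else float(conc),
                voltage_mV=float(volt),
                t_ms=sgrp["t_ms"].to_numpy(),
                current_nA=sgrp["current_nA"].to_numpy(),
            ))
        sweeps.sort(key=lambda s: (s.addition_idx, s.protocol_idx, s.voltage_mV))
        out.append(CellSeries(cell_id=str(cid), sweeps=sweeps))
    return out
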