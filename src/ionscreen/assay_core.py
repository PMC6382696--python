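"""Shared domain types and kinetic-trace scoring for plate-based assays.

A FLIPR-style kinetic read consists of a short baseline segment (the screen
recorded 7 reads) followed by dispense of a trigger solution and a longer
response segment (40 reads).  Wells are scored with the "Max-Min/Max"
aggregation: the response is the fractional excursion of the post-trigger
extremum from the baseline mean, oriented by assay direction — fluorescence
*decrease* for the iodide/eYFP quench assay, *increase* for the calcium-flux
counterscreen.
"""

from __future__ import annotations

import enum
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WellRole",
    "KineticTrace",
    "Well",
    "PlateRead",
    "CompoundRecord",
    "score_trace_max_min_max",
    "baseline_fluorescence",
    "auc_normalized",
    "read_plate_reads_csv",
    "write_plate_reads_csv",
    "well_name",
    "PLATE_ROWS",
    "PLATE_COLS",
]

PLATE_ROWS = 16
PLATE_COLS = 24
_ROW_LETTERS = string.ascii_uppercase[:PLATE_ROWS]


class WellRole(enum.Enum):
    TEST = "TEST"
    NEUTRAL_CONTROL = "NEUTRAL_CONTROL"
    INHIBITOR_CONTROL = "INHIBITOR_CONTROL"
    BLANK = "BLANK"


def well_name(row: int, col: int) -> str:
    """0-based (row, col) → plate coordinate 'A1'..'P24'."""
    return f"{_ROW_LETTERS[row]}{col + 1}"


@dataclass
class KineticTrace:
    """Time-stamped fluorescence reads for one well.

    times are seconds, strictly ascending; values are positive fluorescence
    in arbitrary units.  ``trigger_time`` separates baseline from response;
    ``baseline_window`` is a (start, end) interval with end ≤ trigger_time
    containing at least one sample.
    """

    times: np.ndarray
    values: np.ndarray
    trigger_time: float
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times.size < 2:
            raise ValueError("a trace needs at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("fluorescence values must be finite and > 0")
        start, end = self.baseline_window
        if end > self.trigger_time:
            raise ValueError("baseline window must end at or before the trigger")
        if not (self.times[0] <= self.trigger_time <= self.times[-1]):
            raise ValueError("trigger_time must lie within the sampled interval")
        if not np.any((self.times >= start) & (self.times <= end)):
            raise ValueError("baseline window contains no samples")

    def baseline_mask(self) -> np.ndarray:
        start, end = self.baseline_window
        return (self.times >= start) & (self.times <= end)

    def post_trigger_mask(self) -> np.ndarray:
        return self.times > self.trigger_time


@dataclass
class Well:
    role: WellRole
    compound_id: str | None
    conc_uM: float | None
    trace: KineticTrace

    def __post_init__(self) -> None:
        if self.role is WellRole.TEST:
            if self.compound_id is None or self.conc_uM is None:
                raise ValueError("TEST wells require a compound id and concentration")


@dataclass
class PlateRead:
    """One 384-well plate of kinetic traces with per-well roles."""

    plate_id: str
    wells: dict[str, Well]

    def wells_by_role(self, role: WellRole) -> dict[str, Well]:
        return {k: w for k, w in self.wells.items() if w.role is role}

    def require_normalizable(self) -> None:
        for role in (WellRole.NEUTRAL_CONTROL, WellRole.INHIBITOR_CONTROL):
            if len(self.wells_by_role(role)) < 2:
                raise ValueError(
                    f"plate {self.plate_id}: needs >= 2 {role.value} wells to normalize"
                )


@dataclass
class CompoundRecord:
    """Per-compound scores and triage status.

    POC (percent of control; neutral control = 100, full inhibitor = 0) and
    POI (percent inhibition) satisfy POC + POI = 100 whenever both are set.
    """

    compound_id: str
    poc: float | None = None
    poi: float | None = None
    baseline_fi: float | None = None
    status: str = "PENDING"
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.poc is not None and self.poi is not None:
            if abs(self.poc + self.poi - 100.0) > 1e-9:
                raise ValueError("POC + POI must equal 100")


# ---------------------------------------------------------------------------
# Trace scoring

def baseline_fluorescence(trace: KineticTrace) -> float:
    """Mean fluorescence over the baseline window (pre-trigger FI)."""
    return float(trace.values[trace.baseline_mask()].mean())


def score_trace_max_min_max(trace: KineticTrace, direction: str = "decrease") -> float:
    """Max-Min/Max response of a kinetic trace, as a fraction of signal.

    direction='decrease' (iodide quench):  (B − min_post) / B
    direction='increase' (calcium flux):   (max_post − B) / max_post

    where B is the baseline-window mean.  Clamped at 0 when the post-trigger
    extremum does not cross baseline; well-formed signals score in [0, 1).
    """
    b = baseline_fluorescence(trace)
    if b <= 0:
        raise ValueError("baseline fluorescence must be > 0")
    post = trace.values[trace.post_trigger_mask()]
    if post.size == 0:
        raise ValueError("trace has no post-trigger samples")
    if direction == "decrease":
        response = (b - float(post.min())) / b
    elif direction == "increase":
        peak = float(post.max())
        response = (peak - b) / peak
    else:
        raise ValueError("direction must be 'increase' or 'decrease'")
    return max(response, 0.0)


def auc_normalized(trace: KineticTrace) -> float:
    """Trapezoidal AUC of the baseline-normalized excursion F(t)/B − 1 over
    the post-trigger segment.  Negative for hyperpolarizing/quenching
    responses; additive over adjacent time segments."""
    b = baseline_fluorescence(trace)
    if b <= 0:
        raise ValueError("baseline fluorescence must be > 0")
    mask = trace.post_trigger_mask()
    t = trace.times[mask]
    if t.size == 0:
        raise ValueError("trace has no post-trigger samples")
    y = trace.values[mask] / b - 1.0
    return float(np.trapezoid(y, t))


# ---------------------------------------------------------------------------
# Long-format CSV interface
#
# Columns: plate_id, well, role, compound_id, conc_uM, time_s, fluorescence.
# One row per (well, time point); trigger time and baseline window are
# carried as per-plate metadata columns to keep the table self-describing.

_CSV_COLUMNS = ["plate_id", "well", "role", "compound_id", "conc_uM",
                "time_s", "fluorescence", "trigger_time_s",
                "baseline_start_s", "baseline_end_s"]


def write_plate_reads_csv(plates: list[PlateRead], path) -> None:
    frames = []
    for plate in plates:
        for name, w in plate.wells.items():
            tr = w.trace
            frames.append(pd.DataFrame({
                "plate_id": plate.plate_id,
                "well": name,
                "role": w.role.value,
                "compound_id": w.compound_id if w.compound_id is not None else "",
                "conc_uM": w.conc_uM if w.conc_uM is not None else np.nan,
                "time_s": tr.times,
                "fluorescence": tr.values,
                "trigger_time_s": tr.trigger_time,
                "baseline_start_s": tr.baseline_window[0],
                "baseline_end_s": tr.baseline_window[1],
            }))
    pd.concat(frames, ignore_index=True)[_CSV_COLUMNS].to_csv(path, index=False)


def read_plate_reads_csv(path) -> list[PlateRead]:
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "compound_id": str},
                     keep_default_na=False, na_values=[""])
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate-read table missing columns: {missing}")
    plates: list[PlateRead] = []
    for pid, pgrp in df.groupby("plate_id", sort=True):
        wells: dict[str, Well] = {}
        for wname, wgrp in pgrp.groupby("well", sort=True):
            wgrp = wgrp.sort_values("time_s")
            first = wgrp.iloc[0]
            cid = first["compound_id"]
            conc = first["conc_uM"]
            trace = KineticTrace(
                times=wgrp["time_s"].to_numpy(),
                values=wgrp["fluorescence"].to_numpy(),
                trigger_time=float(first["trigger_time_s"]),
                baseline_window=(float(first["baseline_start_s"]),
                                 float(first["baseline_end_s"])),
            )
            wells[str(wname)] = Well(
                role=WellRole(first["role"]),
                compound_id=None if pd.isna(cid) or cid == "" else str(cid),
                conc_uM=None if pd.isna(conc) else float(conc),
                trace=trace,
            )
        plates.append(PlateRead(plate_id=str(pid), wells=wells))
    return plates
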