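"""Seeded generators for every input the analysis funnel consumes.

Each generator is a pure function of (parameters, seed) and returns its
ground truth alongside the data, so recovery tests can join results back to
what was planted.  The statistical structure mirrors the assays:

* **Screen plates** — 384-well plates, columns 1–22 test compounds at the
  5 μM screening concentration, column 23 neutral control (DMSO), column 24
  full-inhibitor control (benzbromarone).  Baseline fluorescence F0 is
  log-normal between wells; the iodide-quench response after the trigger is
  F(t) = F0·[1 − q·A·(1 − e^(−t/τ))] with A the compound-dependent channel
  activity and q the neutral quench fraction, under multiplicative Gaussian
  read noise.  Auto-fluorescent artifacts add a constant offset to all
  reads, which both raises their baseline FI and dilutes their apparent
  quench — the real artifact mechanism.
* **Ca-flux plates** — signal-increasing traces F(t) = F0·[1 + g·C·(1 −
  e^(−t/τ))]; calcium interferers reduce C via their own Hill potency,
  column 23 is the ionomycin neutral control, column 24 a no-trigger blank.
* **Patch-clamp cells** — per-cell log-normal reference current, optional
  exponential rundown, and first-order compound binding dB/dt = k_on·c·
  (B_eq − B), so slow binders measured after short incubations understate
  their equilibrium potency.
* **Myograph rings** — tension approaches each dose's equilibrium
  first-order; contraction follows the contractant Hill curve; relaxants
  act either proportionally on the contractile drive (channel-blocker-like)
  or by removing a bounded amount of drive (β-agonist-like 'capacity'
  mechanism), and theophylline drives tension to the floor.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .assay_core import (KineticTrace, PlateRead, Well, WellRole, well_name,
                         PLATE_ROWS)
from .dose_response import dilution_series, hill_model
from .ephys_analysis import CellSeries, SweepRecord
from .myograph_analysis import Event, EventKind, TensionTrace

__all__ = [
    "CompoundClass",
    "CompoundTruth",
    "ScreenScenario",
    "gen_compound_truths",
    "gen_screen",
    "gen_screen_plates",
    "gen_ca_flux",
    "gen_ephys_cells",
    "gen_calibration_ring",
    "gen_precontracted_ring",
    "truths_to_frame",
    "time_to_fraction_block_min",
    "DEFAULT_KON_SLOW",
    "THEOPHYLLINE_UM",
]

# Niclosamide-like slow-binding preset: at 1.11 μM, 95% of equilibrium block
# takes −ln(0.05)/(k_on·c) ≈ 10 min.
DEFAULT_KON_SLOW = 0.27  # μM⁻¹·min⁻¹
THEOPHYLLINE_UM = 2200.0  # 2.2 mM, stored in μM like every concentration


class CompoundClass(enum.Enum):
    INACTIVE = "INACTIVE"
    FULL_BLOCKER = "FULL_BLOCKER"
    PARTIAL_BLOCKER = "PARTIAL_BLOCKER"
    FLUORESCENT_ARTIFACT = "FLUORESCENT_ARTIFACT"
    CA_INTERFERER = "CA_INTERFERER"


@dataclass(frozen=True)
class CompoundTruth:
    """Planted ground truth for one library compound.

    ``ic50_uM`` is the channel IC50 for blockers and the calcium-signaling
    IC50 for interferers; ``emax`` is the maximal inhibited fraction (1 for
    full blockers); ``k_on`` (μM⁻¹·min⁻¹, inf = instant equilibrium) only
    matters for kinetic patch-clamp scenarios; ``fi_offset_frac`` is the
    artifact's constant fluorescence offset as a fraction of its F0.
    """

    compound_id: str
    cls: CompoundClass
    ic50_uM: float = math.nan
    emax: float = 1.0
    hill: float = 1.0
    k_on: float = math.inf
    fi_offset_frac: float = 0.0

    def is_strong_active(self) -> bool:
        return (self.cls in (CompoundClass.FULL_BLOCKER, CompoundClass.PARTIAL_BLOCKER)
                and self.ic50_uM < 1.0 and self.emax >= 0.5)

    def channel_activity(self, conc_uM: float) -> float:
        """Fractional channel activity A ∈ [0, 1] at a test concentration.

        Blockers reduce A through their Hill curve; calcium interferers
        reduce the ionomycin calcium signal and thereby activation of the
        calcium-gated channel; artifacts and inactives leave A = 1.
        """
        if self.cls in (CompoundClass.FULL_BLOCKER, CompoundClass.PARTIAL_BLOCKER):
            return 1.0 - self.emax * conc_uM ** self.hill / (
                conc_uM ** self.hill + self.ic50_uM ** self.hill)
        if self.cls is CompoundClass.CA_INTERFERER:
            return self.calcium_response(conc_uM)
        return 1.0

    def calcium_response(self, conc_uM: float) -> float:
        """Fractional ionomycin-triggered calcium response C ∈ [0, 1]."""
        if self.cls is CompoundClass.CA_INTERFERER:
            return 1.0 - conc_uM ** self.hill / (
                conc_uM ** self.hill + self.ic50_uM ** self.hill)
        return 1.0


@dataclass
class ScreenScenario:
    """Generative parameters of a synthetic screening campaign.

    Defaults are desk-scale study conditions: a 10,000-compound library with
    a 97% inactive background, 2% read noise, a 60% neutral quench fraction
    and FLIPR-like timing (7 baseline reads, 40 response reads, 1 s apart).
    """

    n_compounds: int = 10_000
    mixture: dict = field(default_factory=lambda: {
        "INACTIVE": 0.970,
        "FULL_BLOCKER": 0.008,
        "PARTIAL_BLOCKER": 0.008,
        "FLUORESCENT_ARTIFACT": 0.007,
        "CA_INTERFERER": 0.007,
    })
    read_cv: float = 0.02
    f0_median: float = 1000.0
    f0_sigma: float = 0.15
    neutral_quench: float = 0.6
    ca_gain: float = 2.0
    screening_conc_uM: float = 5.0
    reads_before: int = 7
    reads_after: int = 40
    read_interval_s: float = 1.0
    tau_quench_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions must sum to 1, got {total}")

    # -- timing helpers -----------------------------------------------------
    @property
    def trigger_time_s(self) -> float:
        return (self.reads_before - 0.5) * self.read_interval_s

    @property
    def baseline_window(self) -> tuple[float, float]:
        return (0.0, (self.reads_before - 1) * self.read_interval_s)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.reads_before + self.reads_after) * self.read_interval_s

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScreenScenario":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Compound truths

def gen_compound_truths(scenario: ScreenScenario,
                        rng: np.random.Generator) -> list[CompoundTruth]:
    classes = [CompoundClass(k) for k in scenario.mixture]
    probs = np.array([scenario.mixture[c.value] for c in classes])
    draw = rng.choice(len(classes), size=scenario.n_compounds, p=probs)
    width = len(str(scenario.n_compounds))
    truths = []
    for i, k in enumerate(draw):
        cls = classes[k]
        cid = f"C{i + 1:0{width}d}"
        if cls in (CompoundClass.FULL_BLOCKER, CompoundClass.PARTIAL_BLOCKER):
            ic50 = 10.0 ** rng.uniform(-2.0, 0.5)  # 0.01–3.2 μM
            emax = 1.0 if cls is CompoundClass.FULL_BLOCKER else rng.uniform(0.3, 0.7)
            truths.append(CompoundTruth(cid, cls, ic50_uM=float(ic50),
                                        emax=float(emax)))
        elif cls is CompoundClass.CA_INTERFERER:
            ic50 = 10.0 ** rng.uniform(math.log10(0.05), math.log10(2.0))
            truths.append(CompoundTruth(cid, cls, ic50_uM=float(ic50)))
        elif cls is CompoundClass.FLUORESCENT_ARTIFACT:
            truths.append(CompoundTruth(cid, cls,
                                        fi_offset_frac=float(rng.uniform(2.0, 10.0))))
        else:
            truths.append(CompoundTruth(cid, cls))
    return truths


def truths_to_frame(truths: list[CompoundTruth]) -> pd.DataFrame:
    return pd.DataFrame([{
        "compound_id": t.compound_id, "class": t.cls.value, "ic50_uM": t.ic50_uM,
        "emax": t.emax, "hill": t.hill, "k_on": t.k_on,
        "fi_offset_frac": t.fi_offset_frac,
    } for t in truths])


# ---------------------------------------------------------------------------
# Plate-based generators

def _quench_traces(f0: np.ndarray, amplitude: np.ndarray, offset: np.ndarray,
                   scenario: ScreenScenario, rng: np.random.Generator,
                   increase: bool) -> np.ndarray:
    """(n_wells, n_reads) fluorescence matrix for quench or flux plates.

    ``amplitude`` is q·A for quench plates and g·C for flux plates; the
    post-trigger kinetic is a saturating exponential with the scenario's
    time constant.  ``offset`` is the artifacts' additive FI (absolute)."""
    t = scenario.times_s
    post = np.clip(t - scenario.trigger_time_s, 0.0, None)
    kin = 1.0 - np.exp(-post / scenario.tau_quench_s)
    kin[t <= scenario.trigger_time_s] = 0.0
    sign = 1.0 if increase else -1.0
    clean = f0[:, None] * (1.0 + sign * amplitude[:, None] * kin[None, :])
    clean = clean + offset[:, None]
    noisy = clean * (1.0 + scenario.read_cv * rng.standard_normal(clean.shape))
    return np.maximum(noisy, 1e-9)


def _build_plates(entries: list[tuple[str, float, float, float]],
                  scenario: ScreenScenario, rng: np.random.Generator,
                  plate_prefix: str, increase: bool,
                  high_amplitude: float, blank_col24: bool) -> list[PlateRead]:
    """Lay out test entries (compound_id, conc, amplitude_fraction,
    fi_offset_frac) onto 384-well plates with control columns 23/24."""
    per_plate = PLATE_ROWS * 22
    plates: list[PlateRead] = []
    n_plates = max(1, math.ceil(len(entries) / per_plate))
    for p in range(n_plates):
        chunk = entries[p * per_plate:(p + 1) * per_plate]
        names, roles, cids, concs = [], [], [], []
        amp_frac, off_frac = [], []
        for j, (cid, conc, amp, off) in enumerate(chunk):
            names.append(well_name(j % PLATE_ROWS, j // PLATE_ROWS))
            roles.append(WellRole.TEST)
            cids.append(cid)
            concs.append(conc)
            amp_frac.append(amp)
            off_frac.append(off)
        for row in range(PLATE_ROWS):  # column 23: neutral control
            names.append(well_name(row, 22))
            roles.append(WellRole.NEUTRAL_CONTROL)
            cids.append(None)
            concs.append(None)
            amp_frac.append(high_amplitude)
            off_frac.append(0.0)
        for row in range(PLATE_ROWS):  # column 24: inhibitor control / blank
            names.append(well_name(row, 23))
            roles.append(WellRole.BLANK if blank_col24 else WellRole.INHIBITOR_CONTROL)
            cids.append(None)
            concs.append(None)
            amp_frac.append(0.0)
            off_frac.append(0.0)

        n = len(names)
        f0 = scenario.f0_median * np.exp(
            scenario.f0_sigma * rng.standard_normal(n))
        values = _quench_traces(f0, np.asarray(amp_frac),
                                np.asarray(off_frac) * f0, scenario, rng, increase)
        t = scenario.times_s
        wells = {}
        for i, name in enumerate(names):
            trace = KineticTrace(times=t, values=values[i],
                                 trigger_time=scenario.trigger_time_s,
                                 baseline_window=scenario.baseline_window)
            wells[name] = Well(role=roles[i], compound_id=cids[i],
                               conc_uM=concs[i], trace=trace)
        plates.append(PlateRead(plate_id=f"{plate_prefix}{p + 1:03d}", wells=wells))
    return plates


def gen_screen_plates(truths: list[CompoundTruth], scenario: ScreenScenario,
                      rng: np.random.Generator, plate_prefix: str = "P",
                      concs: dict[str, float] | None = None) -> list[PlateRead]:
    """Iodide-quench plates for the given compounds.

    By default every compound sits at the scenario's screening
    concentration; ``concs`` overrides per compound (dose-response runs call
    this once per concentration set)."""
    entries = []
    for t in truths:
        c = scenario.screening_conc_uM if concs is None else concs[t.compound_id]
        amp = scenario.neutral_quench * t.channel_activity(c)
        entries.append((t.compound_id, c, amp, t.fi_offset_frac))
    return _build_plates(entries, scenario, rng, plate_prefix, increase=False,
                         high_amplitude=scenario.neutral_quench, blank_col24=False)


def gen_screen(scenario: ScreenScenario) -> tuple[list[PlateRead], list[CompoundTruth]]:
    """Primary-screen plates plus the planted truth table (pure in seed)."""
    rng = np.random.default_rng(scenario.seed)
    truths = gen_compound_truths(scenario, rng)
    plates = gen_screen_plates(truths, scenario, rng)
    return plates, truths


def gen_dose_response_plates(truths: list[CompoundTruth], scenario: ScreenScenario,
                             rng: np.random.Generator, concs_uM: np.ndarray,
                             plate_prefix: str = "D") -> list[PlateRead]:
    """eYFP dose-response plates: every compound at every concentration of
    the (typically 22-point, 1:2) dilution series."""
    entries = []
    for t in truths:
        for c in concs_uM:
            amp = scenario.neutral_quench * t.channel_activity(float(c))
            entries.append((t.compound_id, float(c), amp, t.fi_offset_frac))
    return _build_plates(entries, scenario, rng, plate_prefix, increase=False,
                         high_amplitude=scenario.neutral_quench, blank_col24=False)


def gen_ca_flux(truths: list[CompoundTruth], scenario: ScreenScenario,
                rng: np.random.Generator, concs_uM: np.ndarray,
                plate_prefix: str = "X") -> list[PlateRead]:
    """Calcium-flux counterscreen plates (signal-increasing traces).

    Column 23 carries the full ionomycin response (neutral), column 24 the
    no-trigger blank.  Only calcium interferers reduce the response."""
    entries = []
    for t in truths:
        for c in concs_uM:
            amp = scenario.ca_gain * t.calcium_response(float(c))
            entries.append((t.compound_id, float(c), amp, t.fi_offset_frac))
    return _build_plates(entries, scenario, rng, plate_prefix, increase=True,
                         high_amplitude=scenario.ca_gain, blank_col24=True)


# ---------------------------------------------------------------------------
# Patch-clamp generator

def time_to_fraction_block_min(k_on: float, conc_uM: float,
                               fraction: float = 0.95) -> float:
    """Closed form of the first-order binding ODE: minutes until block
    reaches ``fraction`` of its equilibrium value at a fixed concentration."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if math.isinf(k_on):
        return 0.0
    return float(-math.log(1.0 - fraction) / (k_on * conc_uM))


def gen_ephys_cells(truth: CompoundTruth, *, incubation_s: float = 60.0,
                    n_cells: int = 4, top_conc_uM: float = 30.0,
                    dilution_factor: float = 5.0, n_concs: int = 5,
                    rundown_tau_s: float = math.inf, noise_cv: float = 0.02,
                    i0_median_nA: float = 2.0, i0_sigma: float = 0.3,
                    seed: int = 0) -> list[CellSeries]:
    """Cumulative-addition whole-cell recordings for one compound.

    Two vehicle additions precede the ascending 1:5 concentration series;
    each addition hosts three IV protocol runs, the third falling exactly
    ``incubation_s`` after the addition.  Block accumulates within each
    addition per dB/dt = k_on·c·(B_eq − B) (k_on = inf ⇒ instant
    equilibrium); measured current is I0·e^(−t/τ_rundown)·(1 − B)."""
    rng = np.random.default_rng(seed)
    concs = dilution_series(top_conc_uM, dilution_factor, n_concs)
    window = np.arange(540.0, 550.5, 1.0)
    cells = []
    for ci in range(n_cells):
        i0 = i0_median_nA * math.exp(i0_sigma * rng.standard_normal())
        sweeps: list[SweepRecord] = []
        b = 0.0  # block carried across the cumulative additions
        t_clock = 0.0
        additions: list[float | None] = [None, None, *concs.tolist()]
        for add_idx, conc in enumerate(additions, start=1):
            if conc is None:
                b_eq, rate = 0.0, math.inf  # vehicle leaves block unchanged
            else:
                b_eq = truth.emax * conc ** truth.hill / (
                    conc ** truth.hill + truth.ic50_uM ** truth.hill) \
                    if truth.cls is not CompoundClass.INACTIVE else 0.0
                rate = truth.k_on * conc / 60.0  # per second
            for prot in (1, 2, 3):
                dt = incubation_s * prot / 3.0
                if conc is None:
                    b_now = b
                elif math.isinf(rate):
                    b_now = b_eq
                else:
                    b_now = b_eq + (b - b_eq) * math.exp(-rate * dt)
                t_abs = t_clock + dt
                decay = math.exp(-t_abs / rundown_tau_s) if math.isfinite(
                    rundown_tau_s) else 1.0
                current = i0 * decay * (1.0 - b_now) * (
                    1.0 + noise_cv * rng.standard_normal())
                sweeps.append(SweepRecord(
                    cell_id=f"cell{ci + 1}", addition_idx=add_idx,
                    protocol_idx=prot, conc_uM=conc, voltage_mV=100.0,
                    t_ms=window, current_nA=np.full(window.size, current)))
            # state at the end of the addition
            if conc is not None:
                if math.isinf(rate):
                    b = b_eq
                else:
                    b = b_eq + (b - b_eq) * math.exp(-rate * incubation_s)
            t_clock += incubation_s
        cells.append(CellSeries(cell_id=f"cell{ci + 1}", sweeps=sweeps))
    return cells


# ---------------------------------------------------------------------------
# Myograph generators

def _first_order_segments(segments: list[tuple[float, float, float]],
                          t0_value: float, dt_s: float,
                          noise_sd: float, rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate first-order approaches: segments of (duration_s,
    equilibrium, tau_s) starting from ``t0_value``."""
    times, tension = [], []
    t_clock, current = 0.0, t0_value
    for duration, eq, tau in segments:
        t = np.arange(dt_s, duration + dt_s / 2, dt_s)
        y = eq + (current - eq) * np.exp(-t / tau)
        times.append(t_clock + t)
        tension.append(y)
        current = float(y[-1])
        t_clock += duration
    tt = np.concatenate(times)
    yy = np.concatenate(tension)
    yy = yy + noise_sd * rng.standard_normal(yy.shape)
    return tt, np.maximum(yy, 0.0)


def gen_calibration_ring(ring_id: str = "ring1", *, cch_ec50_uM: float = 0.3,
                         cch_slope: float = 1.0, baseline_mN: float = 5.0,
                         span_mN: float = 10.0, tau_s: float = 45.0,
                         doses_uM: np.ndarray | None = None,
                         segment_s: float = 300.0, dt_s: float = 1.0,
                         noise_sd_mN: float = 0.02, seed: int = 0
                         ) -> tuple[TensionTrace, dict]:
    """Ascending-contractant qualification trace for one ring.

    Default doses are eight half-log steps, 0.01–30 μM carbachol; each dose
    segment lasts 5 min and tension approaches its Hill-curve equilibrium
    first-order.  Returns (trace, truth dict)."""
    rng = np.random.default_rng(seed)
    if doses_uM is None:
        doses_uM = 10.0 ** np.arange(-2.0, 1.6, 0.5)  # 0.01 .. ~31.6 μM
    pre_s = 60.0
    segments = [(pre_s, baseline_mN, tau_s)]
    events = []
    t_clock = pre_s
    for c in doses_uM:
        drive = c ** cch_slope / (c ** cch_slope + cch_ec50_uM ** cch_slope)
        events.append(Event(time_s=t_clock, kind=EventKind.DOSE_CONTRACTANT,
                            conc_uM=float(c)))
        segments.append((segment_s, baseline_mN + span_mN * drive, tau_s))
        t_clock += segment_s
    times, tension = _first_order_segments(segments, baseline_mN, dt_s,
                                           noise_sd_mN, rng)
    trace = TensionTrace(ring_id=ring_id, times=times, tension=tension,
                         events=events)
    truth = {"cch_ec50_uM": cch_ec50_uM, "cch_slope": cch_slope,
             "baseline_mN": baseline_mN, "span_mN": span_mN}
    return trace, truth


def gen_precontracted_ring(ring_id: str, *, precontract_conc_uM: float,
                           cch_ec50_uM: float = 0.3, cch_slope: float = 1.0,
                           baseline_mN: float = 5.0, span_mN: float = 10.0,
                           relax_ec50_uM: float = 0.05, relax_slope: float = 1.0,
                           relax_emax: float = 1.0,
                           mechanism: str = "proportional",
                           capacity: float = 0.5,
                           test_doses_uM: np.ndarray | None = None,
                           tau_s: float = 45.0, segment_s: float = 600.0,
                           precontract_s: float = 1500.0,
                           theophylline_s: float = 300.0, dt_s: float = 1.0,
                           noise_sd_mN: float = 0.02, seed: int = 0
                           ) -> TensionTrace:
    """Pre-contracted ring treated with ascending relaxant doses then
    theophylline.

    ``mechanism='proportional'`` scales the contractile drive by
    (1 − relaxation fraction) — a channel blocker acting on the contraction
    machinery itself, reaching ~100% relaxation at any pre-contraction
    level.  ``mechanism='capacity'`` subtracts at most ``capacity`` of
    absolute drive — a β-agonist-like relaxant whose maximal relaxation
    falls as the pre-contraction level rises."""
    if mechanism not in ("proportional", "capacity"):
        raise ValueError("mechanism must be 'proportional' or 'capacity'")
    rng = np.random.default_rng(seed)
    if test_doses_uM is None:
        test_doses_uM = 10.0 ** np.arange(-3.0, 0.1, 0.5)  # 0.001 .. 1 μM
    c0 = precontract_conc_uM
    drive0 = c0 ** cch_slope / (c0 ** cch_slope + cch_ec50_uM ** cch_slope)

    segments = [(60.0, baseline_mN, tau_s)]
    events: list[Event] = []
    t_clock = 60.0
    events.append(Event(time_s=t_clock, kind=EventKind.DOSE_CONTRACTANT,
                        conc_uM=float(c0)))
    segments.append((precontract_s, baseline_mN + span_mN * drive0, tau_s))
    t_clock += precontract_s
    for c in test_doses_uM:
        r = relax_emax * c ** relax_slope / (
            c ** relax_slope + relax_ec50_uM ** relax_slope)
        if mechanism == "proportional":
            drive = drive0 * (1.0 - r)
        else:
            drive = max(0.0, drive0 - capacity * r)
        events.append(Event(time_s=t_clock, kind=EventKind.DOSE_TEST,
                            conc_uM=float(c)))
        segments.append((segment_s, baseline_mN + span_mN * drive, tau_s))
        t_clock += segment_s
    events.append(Event(time_s=t_clock, kind=EventKind.DOSE_THEOPHYLLINE,
                        conc_uM=THEOPHYLLINE_UM))
    segments.append((theophylline_s, baseline_mN, tau_s / 2.0))

    times, tension = _first_order_segments(segments, baseline_mN, dt_s,
                                           noise_sd_mN, rng)
    return TensionTrace(ring_id=ring_id, times=times, tension=tension,
                        events=events)
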