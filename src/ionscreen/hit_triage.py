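"""The screen's multi-stage hit funnel.

Stage order follows the campaign: primary hit calling → triplicate
confirmation → auto-fluorescence artifact removal → calcium-flux
counterscreen → potency threshold.  All threshold comparisons are strict,
with directions chosen so that controls can never become hits.

The primary threshold is computed on the percent-inhibition (POI) scale as

    cutoff = median(POI) + 3 · IQR(POI) + 20

over all test wells; the equivalent POC cutoff is 100 − cutoff.  Applied to
a screen whose inhibition population sits near zero this yields cutoffs in
the high-20s (the campaign's was POI > 27.4, i.e. POC < 72.6).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .dose_response import ConcResponseFit

__all__ = [
    "TriageConfig",
    "FunnelReport",
    "ScreenDataset",
    "primary_hit_threshold",
    "call_primary_hits",
    "confirm_hits",
    "fluorescence_filter",
    "counterscreen_filter",
    "potency_filter",
    "run_funnel",
    "Reason",
]


class Reason:
    """Elimination-reason vocabulary used in funnel reports."""

    BELOW_PRIMARY_CUTOFF = "BELOW_PRIMARY_CUTOFF"
    MISSING_POI = "MISSING_POI"
    NOT_CONFIRMED = "NOT_CONFIRMED"
    RE_TEST = "RE_TEST"
    AUTO_FLUORESCENT = "AUTO_FLUORESCENT"
    CA_FLUX_INTERFERENCE = "CA_FLUX_INTERFERENCE"
    LOW_POTENCY = "LOW_POTENCY"
    NO_FIT = "NO_FIT"


@dataclass
class TriageConfig:
    """Thresholds of the hit funnel, defaulted to the campaign's values.

    poi_extra_margin: percentage points added to the primary threshold (20).
    iqr_multiplier: IQR multiples in the primary threshold (3).
    fluorescence_sd_multiplier: neutral-control SD multiples above the
        neutral median allowed before a compound counts as auto-fluorescent (10).
    counterscreen_ic50_max: Ca-flux IC50 (μM) below which a compound is
        eliminated as a calcium-signaling interferer (10).
    potency_ic50_max: eYFP IC50 (μM) a final hit must beat (5).
    confirmation_replicates: independent confirmation runs required (3).
    """

    poi_extra_margin: float = 20.0
    iqr_multiplier: float = 3.0
    fluorescence_sd_multiplier: float = 10.0
    counterscreen_ic50_max: float = 10.0
    potency_ic50_max: float = 5.0
    confirmation_replicates: int = 3
    min_test_wells: int = 100
    # Individual stages can be switched off for ablation studies.
    skip_confirmation: bool = False
    skip_fluorescence: bool = False
    skip_counterscreen: bool = False
    skip_potency: bool = False

    def __post_init__(self) -> None:
        for name in ("poi_extra_margin", "iqr_multiplier",
                     "fluorescence_sd_multiplier", "counterscreen_ic50_max",
                     "potency_ic50_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.confirmation_replicates < 1:
            raise ValueError("confirmation_replicates must be >= 1")


@dataclass
class FunnelReport:
    """Ordered stage counts plus a per-compound elimination map.

    Invariant: n_out ≤ n_in at every stage, and every input compound either
    survives all stages or appears in exactly one elimination bucket.
    """

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    eliminations: dict[str, str] = field(default_factory=dict)
    survivors: list[str] = field(default_factory=list)
    poi_cutoff: float | None = None

    def add_stage(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: n_out {n_out} > n_in {n_in}")
        self.stages.append((name, n_in, n_out))

    def to_json(self, path=None) -> str:
        payload = {
            "poi_cutoff": self.poi_cutoff,
            "poc_cutoff": None if self.poi_cutoff is None else 100.0 - self.poi_cutoff,
            "stages": [{"name": n, "n_in": i, "n_out": o} for n, i, o in self.stages],
            "eliminations": self.eliminations,
            "survivors": sorted(self.survivors),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary_text(self) -> str:
        lines = ["Hit-triage funnel"]
        if self.poi_cutoff is not None:
            lines.append(f"  primary cutoff: POI > {self.poi_cutoff:.1f}"
                         f" (POC < {100 - self.poi_cutoff:.1f})")
        for name, n_in, n_out in self.stages:
            lines.append(f"  {name:<16} {n_in:>7} -> {n_out:<7}")
        lines.append(f"  final hits: {len(self.survivors)}")
        return "\n".join(lines)


@dataclass
class ScreenDataset:
    """Everything the funnel consumes, keyed by compound id.

    Per-stage inputs may cover only the compounds that reached that stage;
    compounds eliminated earlier are never looked up downstream.
    """

    primary_poi: dict[str, float]
    replicate_poi: dict[str, list[float]] = field(default_factory=dict)
    baseline_fi: dict[str, float] = field(default_factory=dict)
    neutral_fi: list[float] = field(default_factory=list)
    ca_flux_fits: dict[str, ConcResponseFit] = field(default_factory=dict)
    eyfp_fits: dict[str, ConcResponseFit] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Individual stages

def primary_hit_threshold(test_poi: Sequence[float], cfg: TriageConfig) -> float:
    """POI-scale primary cutoff: median + k·IQR + margin over all test wells."""
    poi = np.asarray(test_poi, dtype=float)
    poi = poi[np.isfinite(poi)]
    if poi.size < cfg.min_test_wells:
        raise ValueError(
            f"need >= {cfg.min_test_wells} test wells to set a threshold, got {poi.size}"
        )
    q75, q25 = np.percentile(poi, [75, 25])
    return float(np.median(poi) + cfg.iqr_multiplier * (q75 - q25)
                 + cfg.poi_extra_margin)


def call_primary_hits(poi_by_compound: Mapping[str, float | None],
                      cutoff: float) -> tuple[set[str], set[str]]:
    """Hits are POI strictly above the cutoff.  Returns (hits, missing_poi);
    compounds without a POI are excluded and reported, never silently dropped."""
    hits, missing = set(), set()
    for cid, poi in poi_by_compound.items():
        if poi is None or not np.isfinite(poi):
            missing.add(cid)
        elif poi > cutoff:
            hits.add(cid)
    return hits, missing


def confirm_hits(replicate_poi: Mapping[str, Sequence[float]], cutoff: float,
                 cfg: TriageConfig) -> tuple[set[str], set[str]]:
    """Confirmed iff median replicate POI is strictly above the cutoff.

    Returns (confirmed, re_test): compounds with fewer than the required
    replicates go to a re-test bucket rather than being silently dropped.
    """
    confirmed, re_test = set(), set()
    for cid, reps in replicate_poi.items():
        reps = [r for r in reps if np.isfinite(r)]
        if len(reps) < cfg.confirmation_replicates:
            re_test.add(cid)
        elif float(np.median(reps)) > cutoff:
            confirmed.add(cid)
    return confirmed, re_test


def fluorescence_filter(baseline_fi: Mapping[str, float],
                        neutral_fi: Sequence[float],
                        cfg: TriageConfig) -> tuple[set[str], set[str]]:
    """Split compounds into (clean, auto-fluorescent).

    A compound is retained iff its pre-trigger baseline FI is strictly below
    median(neutral FI) + k·SD(neutral FI).  With zero neutral-control spread
    the filter degenerates to FI < median (a warning-worthy configuration,
    but still well defined).
    """
    neu = np.asarray(neutral_fi, dtype=float)
    if neu.size < 2:
        raise ValueError("need >= 2 neutral-control baseline FI values")
    cutoff = float(np.median(neu) + cfg.fluorescence_sd_multiplier * neu.std(ddof=1))
    clean, artifacts = set(), set()
    for cid, fi in baseline_fi.items():
        (clean if fi < cutoff else artifacts).add(cid)
    return clean, artifacts


def counterscreen_filter(ca_flux_fits: Mapping[str, ConcResponseFit],
                         cfg: TriageConfig) -> tuple[set[str], set[str]]:
    """Split compounds into (specific, interferer) on the Ca-flux IC50.

    Eliminated iff the counterscreen fit converged with IC50 strictly below
    the cutoff; censored / non-converged fits (no measurable interference up
    to the top tested concentration) are retained as specific.
    """
    specific, interferers = set(), set()
    for cid, fit in ca_flux_fits.items():
        if fit.converged and fit.midpoint < cfg.counterscreen_ic50_max:
            interferers.add(cid)
        else:
            specific.add(cid)
    return specific, interferers


def potency_filter(eyfp_fits: Mapping[str, ConcResponseFit],
                   cfg: TriageConfig) -> tuple[set[str], dict[str, str]]:
    """Final selection: retained iff the eYFP dose-response fit converged
    with IC50 strictly below the potency cutoff.  Returns (hits, eliminated
    reason map) where non-converged/censored fits carry reason NO_FIT."""
    hits: set[str] = set()
    eliminated: dict[str, str] = {}
    for cid, fit in eyfp_fits.items():
        if not fit.converged:
            eliminated[cid] = Reason.NO_FIT
        elif fit.midpoint < cfg.potency_ic50_max:
            hits.add(cid)
        else:
            eliminated[cid] = Reason.LOW_POTENCY
    return hits, eliminated


# ---------------------------------------------------------------------------
# Whole funnel

def run_funnel(dataset: ScreenDataset, cfg: TriageConfig | None = None) -> FunnelReport:
    """Execute primary → confirmation → fluorescence → counterscreen →
    potency and return the full accounting.  A stage receiving zero
    compounds ends the funnel gracefully with the report so far."""
    cfg = cfg or TriageConfig()
    report = FunnelReport()

    cutoff = primary_hit_threshold(list(dataset.primary_poi.values()), cfg)
    report.poi_cutoff = cutoff

    pool = set(dataset.primary_poi)
    hits, missing = call_primary_hits(dataset.primary_poi, cutoff)
    for cid in missing:
        report.eliminations[cid] = Reason.MISSING_POI
    for cid in pool - hits - missing:
        report.eliminations[cid] = Reason.BELOW_PRIMARY_CUTOFF
    report.add_stage("primary", len(pool), len(hits))
    pool = hits

    if not cfg.skip_confirmation and pool:
        reps = {cid: dataset.replicate_poi.get(cid, []) for cid in pool}
        confirmed, re_test = confirm_hits(reps, cutoff, cfg)
        for cid in re_test:
            report.eliminations[cid] = Reason.RE_TEST
        for cid in pool - confirmed - re_test:
            report.eliminations[cid] = Reason.NOT_CONFIRMED
        report.add_stage("confirmation", len(pool), len(confirmed))
        pool = confirmed

    if not cfg.skip_fluorescence and pool:
        fi = {cid: dataset.baseline_fi[cid] for cid in pool
              if cid in dataset.baseline_fi}
        clean, artifacts = fluorescence_filter(fi, dataset.neutral_fi, cfg)
        for cid in artifacts:
            report.eliminations[cid] = Reason.AUTO_FLUORESCENT
        for cid in pool - clean - artifacts:  # no FI recorded
            report.eliminations[cid] = Reason.RE_TEST
        report.add_stage("fluorescence", len(pool), len(clean))
        pool = clean

    if not cfg.skip_counterscreen and pool:
        fits = {cid: dataset.ca_flux_fits[cid] for cid in pool
                if cid in dataset.ca_flux_fits}
        specific, interferers = counterscreen_filter(fits, cfg)
        for cid in interferers:
            report.eliminations[cid] = Reason.CA_FLUX_INTERFERENCE
        # No counterscreen data ⇒ cannot demonstrate interference: retained.
        specific |= pool - set(fits)
        report.add_stage("counterscreen", len(pool), len(specific))
        pool = specific

    if not cfg.skip_potency and pool:
        fits = {cid: dataset.eyfp_fits[cid] for cid in pool
                if cid in dataset.eyfp_fits}
        final, eliminated = potency_filter(fits, cfg)
        report.eliminations.update(eliminated)
        for cid in pool - set(fits):
            report.eliminations[cid] = Reason.NO_FIT
        report.add_stage("potency", len(pool), len(final))
        pool = final

    report.survivors = sorted(pool)
    return report
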