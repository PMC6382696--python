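"""End-to-end orchestration of the screening funnel on plate data.

The pipeline scores kinetic traces, normalizes per plate against the
on-plate controls, applies plate QC, and walks the triage funnel, writing
every intermediate as CSV (per-well POC table, QC table, replicate POIs,
fit tables) plus a JSON funnel report.  All randomness is derived from the
scenario seed, so a run is a pure function of (scenario, config, seed), and
the funnel can be re-run from the written intermediates alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_core import (PlateRead, WellRole, baseline_fluorescence,
                         score_trace_max_min_max)
from .dose_response import (ConcResponseFit, dilution_series,
                            fit_partial_efficacy, fits_to_frame,
                            read_fits_csv, write_fits_csv)
from .hit_triage import (FunnelReport, Reason, ScreenDataset, TriageConfig,
                         call_primary_hits, confirm_hits, counterscreen_filter,
                         fluorescence_filter, primary_hit_threshold, run_funnel)
from .plate_normalization import (DEFAULT_Z_PRIME_MIN, ControlSummary, PlateQC,
                                  normalize_poc, plate_qc, poc_to_poi,
                                  write_qc_csv)
from . import synthetic_data as synth

__all__ = [
    "PipelineResult",
    "score_plates",
    "poc_table",
    "run_screen_pipeline",
    "rerun_from_intermediates",
    "DR_TOP_UM",
    "DR_N_POINTS",
    "DR_FACTOR",
]

# 22-step 1:2 dose-response series from a 55.6 μM top (the screen's format).
DR_TOP_UM = 55.6
DR_FACTOR = 2.0
DR_N_POINTS = 22


@dataclass
class PipelineResult:
    report: FunnelReport
    dataset: ScreenDataset
    truth: pd.DataFrame | None
    qc: dict[str, PlateQC]
    excluded_plates: list[str]


def score_plates(plates: list[PlateRead], direction: str) -> pd.DataFrame:
    """Per-well Max-Min/Max responses and baseline FI for a set of plates."""
    rows = []
    for plate in plates:
        for name, w in plate.wells.items():
            rows.append({
                "plate_id": plate.plate_id, "well": name, "role": w.role.value,
                "compound_id": w.compound_id, "conc_uM": w.conc_uM,
                "response": score_trace_max_min_max(w.trace, direction),
                "baseline_fi": baseline_fluorescence(w.trace),
            })
    return pd.DataFrame(rows)


def poc_table(scored: pd.DataFrame, z_prime_min: float = DEFAULT_Z_PRIME_MIN,
              low_role: str = WellRole.INHIBITOR_CONTROL.value
              ) -> tuple[pd.DataFrame, dict[str, PlateQC], list[str]]:
    """Normalize test wells per plate against its own controls.

    Plates failing the Z′ acceptance bar are excluded from hit calling and
    returned in the exclusion list.  ``low_role`` selects which column-24
    role anchors 0% activity (inhibitor control for the quench assay, blank
    for the Ca-flux counterscreen)."""
    qc_by_plate: dict[str, PlateQC] = {}
    excluded: list[str] = []
    frames = []
    for pid, grp in scored.groupby("plate_id", sort=True):
        neu = grp.loc[grp.role == WellRole.NEUTRAL_CONTROL.value, "response"].to_numpy()
        low = grp.loc[grp.role == low_role, "response"].to_numpy()
        tst = grp.loc[grp.role == WellRole.TEST.value, "response"].to_numpy()
        qc = plate_qc(neu, low, tst)
        qc_by_plate[str(pid)] = qc
        if not qc.passes(z_prime_min):
            excluded.append(str(pid))
            continue
        controls = ControlSummary.from_responses(neu, low)
        test = grp[grp.role == WellRole.TEST.value].copy()
        test["poc"] = normalize_poc(test["response"].to_numpy(), controls)
        test["poi"] = poc_to_poi(test["poc"].to_numpy())
        frames.append(test)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["plate_id", "well", "role", "compound_id", "conc_uM",
                 "response", "baseline_fi", "poc", "poi"])
    return out, qc_by_plate, excluded


def _fit_dose_responses(poc_df: pd.DataFrame) -> dict[str, ConcResponseFit]:
    """Free four-parameter fit of POC vs concentration per compound."""
    fits: dict[str, ConcResponseFit] = {}
    for cid, grp in poc_df.groupby("compound_id", sort=True):
        pts = list(zip(grp["conc_uM"].to_numpy(), grp["poc"].to_numpy()))
        fits[str(cid)] = fit_partial_efficacy(pts)
    return fits


def run_screen_pipeline(scenario: synth.ScreenScenario,
                        cfg: TriageConfig | None = None,
                        outdir: str | Path | None = None,
                        z_prime_min: float = DEFAULT_Z_PRIME_MIN) -> PipelineResult:
    """Generate (or re-analyze) a synthetic campaign and run the funnel.

    Stage data are generated only for the compounds that reach each stage —
    confirmation triplicates for primary hits, 22-point counterscreen and
    eYFP dose responses for the respective survivors — then the assembled
    dataset is passed through the pure funnel.
    """
    cfg = cfg or TriageConfig()
    seed_seq = np.random.SeedSequence(scenario.seed)
    rng_confirm, rng_ca, rng_dr = [np.random.default_rng(s)
                                   for s in seed_seq.spawn(3)]

    plates, truths = synth.gen_screen(scenario)
    truth_by_id = {t.compound_id: t for t in truths}
    scored = score_plates(plates, "decrease")
    primary, qc, excluded = poc_table(scored, z_prime_min)

    primary_poi = dict(zip(primary["compound_id"], primary["poi"]))
    baseline_fi = dict(zip(primary["compound_id"], primary["baseline_fi"]))
    neutral_fi = scored.loc[scored.role == WellRole.NEUTRAL_CONTROL.value,
                            "baseline_fi"].tolist()

    cutoff = primary_hit_threshold(list(primary_poi.values()), cfg)
    hits, _missing = call_primary_hits(primary_poi, cutoff)

    # Triplicate confirmation for primary hits only.
    replicate_poi: dict[str, list[float]] = {cid: [] for cid in hits}
    hit_truths = [truth_by_id[c] for c in sorted(hits)]
    for rep in range(cfg.confirmation_replicates):
        rep_plates = synth.gen_screen_plates(hit_truths, scenario, rng_confirm,
                                             plate_prefix=f"R{rep + 1}_")
        rep_poc, _, _ = poc_table(score_plates(rep_plates, "decrease"), z_prime_min)
        for cid, poi in zip(rep_poc["compound_id"], rep_poc["poi"]):
            replicate_poi[str(cid)].append(float(poi))
    confirmed, _retest = confirm_hits(replicate_poi, cutoff, cfg)

    clean, _artifacts = fluorescence_filter(
        {c: baseline_fi[c] for c in confirmed if c in baseline_fi},
        neutral_fi, cfg)

    dr_concs = dilution_series(DR_TOP_UM, DR_FACTOR, DR_N_POINTS)

    # Ca-flux counterscreen for the non-fluorescent confirmed hits.
    clean_truths = [truth_by_id[c] for c in sorted(clean)]
    ca_fits: dict[str, ConcResponseFit] = {}
    if clean_truths:
        ca_plates = synth.gen_ca_flux(clean_truths, scenario, rng_ca, dr_concs)
        ca_scored = score_plates(ca_plates, "increase")
        ca_poc, _, _ = poc_table(ca_scored, z_prime_min,
                                 low_role=WellRole.BLANK.value)
        ca_fits = _fit_dose_responses(ca_poc)
    specific, _interferers = counterscreen_filter(ca_fits, cfg)
    specific &= clean

    # eYFP 22-point dose response for the specific hits.
    eyfp_fits: dict[str, ConcResponseFit] = {}
    spec_truths = [truth_by_id[c] for c in sorted(specific)]
    if spec_truths:
        dr_plates = synth.gen_dose_response_plates(spec_truths, scenario,
                                                   rng_dr, dr_concs)
        dr_poc, _, _ = poc_table(score_plates(dr_plates, "decrease"), z_prime_min)
        eyfp_fits = _fit_dose_responses(dr_poc)

    dataset = ScreenDataset(
        primary_poi=primary_poi, replicate_poi=replicate_poi,
        baseline_fi=baseline_fi, neutral_fi=neutral_fi,
        ca_flux_fits=ca_fits, eyfp_fits=eyfp_fits,
    )
    report = run_funnel(dataset, cfg)
    result = PipelineResult(report=report, dataset=dataset,
                            truth=synth.truths_to_frame(truths), qc=qc,
                            excluded_plates=excluded)
    if outdir is not None:
        _write_intermediates(Path(outdir), scenario, cfg, result, primary)
    return result


def _write_intermediates(outdir: Path, scenario: synth.ScreenScenario,
                         cfg: TriageConfig, result: PipelineResult,
                         primary: pd.DataFrame) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    scenario.to_yaml(outdir / "scenario.yaml")
    with open(outdir / "triage_config.json", "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2)
    primary.to_csv(outdir / "primary_poc.csv", index=False)
    write_qc_csv(result.qc, outdir / "plate_qc.csv")
    pd.DataFrame(
        [{"compound_id": c, "replicate": i + 1, "poi": v}
         for c, vals in result.dataset.replicate_poi.items()
         for i, v in enumerate(vals)]
    ).to_csv(outdir / "replicate_poi.csv", index=False)
    pd.DataFrame({"baseline_fi": result.dataset.neutral_fi}).to_csv(
        outdir / "neutral_fi.csv", index=False)
    write_fits_csv(result.dataset.ca_flux_fits, outdir / "ca_flux_fits.csv",
                   assay="ca_flux")
    write_fits_csv(result.dataset.eyfp_fits, outdir / "eyfp_fits.csv",
                   assay="eyfp")
    if result.truth is not None:
        result.truth.to_csv(outdir / "compound_truth.csv", index=False)
    # Funnel JSON is written last so its presence marks a complete run.
    result.report.to_json(outdir / "funnel.json")
    with open(outdir / "funnel_summary.txt", "w") as fh:
        fh.write(result.report.summary_text() + "\n")


def rerun_from_intermediates(outdir: str | Path,
                             cfg: TriageConfig | None = None) -> FunnelReport:
    """Rebuild the funnel input from written intermediates and re-run it;
    with the original config this reproduces the stored funnel report."""
    outdir = Path(outdir)
    if cfg is None:
        with open(outdir / "triage_config.json") as fh:
            cfg = TriageConfig(**json.load(fh))
    primary = pd.read_csv(outdir / "primary_poc.csv")
    reps = pd.read_csv(outdir / "replicate_poi.csv")
    neutral = pd.read_csv(outdir / "neutral_fi.csv")
    replicate_poi: dict[str, list[float]] = {}
    for cid, grp in reps.groupby("compound_id"):
        replicate_poi[str(cid)] = grp.sort_values("replicate")["poi"].tolist()
    dataset = ScreenDataset(
        primary_poi=dict(zip(primary["compound_id"].astype(str), primary["poi"])),
        replicate_poi=replicate_poi,
        baseline_fi=dict(zip(primary["compound_id"].astype(str),
                             primary["baseline_fi"])),
        neutral_fi=neutral["baseline_fi"].tolist(),
        ca_flux_fits=read_fits_csv(outdir / "ca_flux_fits.csv"),
        eyfp_fits=read_fits_csv(outdir / "eyfp_fits.csv"),
    )
    return run_funnel(dataset, cfg)
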