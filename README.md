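# ionscreen

Analysis toolkit for high-throughput ion-channel antagonist screening and
the downstream pharmacology that turns primary hits into characterized
bronchodilator candidates. The package grew out of the analysis funnel
used to triage a large halide-sensitive-YFP screen against the
calcium-activated chloride channel TMEM16A (ANO1), but every stage is
generic: fluorescence kinetic plates in, ranked and fully accounted hit
lists out, plus patch-clamp, organ-bath and expression-matrix analyses.

## What it computes

**Kinetic-trace scoring.** FLIPR-style traces (a short baseline segment,
a trigger dispense, a response segment) are scored with the Max-Min/Max
aggregation: the fractional excursion of the post-trigger extremum from the
baseline mean, oriented for signal-decreasing (iodide quench) or
signal-increasing (calcium flux) assays. Membrane-potential assays use the
baseline-normalized trapezoidal AUC instead.

**Control-anchored normalization and QC.** Per plate, the neutral-control
column defines 100% channel activity and the full-inhibitor column 0%, so a
well's percent-of-control is

    POC = 100 · (response − μ_inhibitor) / (μ_neutral − μ_inhibitor),
    POI = 100 − POC.

Plate quality is summarized by S/B, Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋|, the
Z-factor (test wells vs inhibitor controls) and robust median/MAD variants;
plates below Z′ = 0.5 are excluded from hit calling.

**The hit funnel.** Primary hits are wells with POI above
median + 3·IQR + 20 percentage points of all test wells; they must then
survive triplicate confirmation (median replicate POI above the cutoff),
an auto-fluorescence filter (baseline FI below the neutral median plus
10 SD), a calcium-flux counterscreen (eliminated if Ca-flux IC50 < 10 μM)
and a potency threshold (eYFP IC50 < 5 μM). Every compound ends up either
in the final hit set or in exactly one elimination bucket.

**Concentration-response machinery.** Four-parameter logistic (Hill) fits
in log-concentration with named presets: a free-bottom fit for partial
blockers that plateau short of full inhibition, and a pooled fit with
asymptotes constrained to 1/0 for vehicle-normalized patch-clamp data.
Fits that never cross half-maximum within the tested range — or whose
amplitude is not resolvable above the residual noise — are censored rather
than extrapolated. EC-fraction algebra (EC_F = EC50·(F/(100−F))^(1/h)) and
serial-dilution construction round out the module.

**Patch-clamp analysis.** Steady-state current from the 540–550 ms window
of the +100 mV step, third IV protocol per addition; per-cell vehicle
normalization; pooled concentration-inhibition fits; and the
perforated-patch formula %inh = (1 − I_TA/I_baseline)·100.

**Wire-myograph analysis.** Plateau detection with slope tolerance,
per-ring contractant calibration (EC25/EC50/EC75/EC95),
theophylline-anchored percent relaxation, ascending bronchodilation EC50
fits, and onset-of-action timing.

**Expression normalization.** The modified upper-quartile rule for FPKM
matrices: per sample, the 70th percentile over included genes (excluding
high-homology families and transcripts < 500 bp) is fixed at 10.

**Synthetic data.** Seeded generators emulate all of the above with ground
truth attached — plate reads with planted blockers, fluorescent artifacts
and calcium interferers; patch-clamp cells with rundown and slow
first-order compound binding; myograph rings with first-order tension
kinetics — so recovery can be measured exactly.

## Worked example

Run a desk-scale synthetic campaign (1,056 compounds on three 384-well
plates) through the whole funnel:

```python
from ionscreen import ScreenScenario, run_screen_pipeline

result = run_screen_pipeline(ScreenScenario(n_compounds=1056, seed=3))
print(result.report.summary_text())
```

```
Hit-triage funnel
  primary cutoff: POI > 24.7 (POC < 75.3)
  primary             1056 -> 24
  confirmation          24 -> 24
  fluorescence          24 -> 20
  counterscreen         20 -> 14
  potency               14 -> 14
  final hits: 14
```

The primary cutoff lands where the inhibition population plus the
20-point margin puts it (near POI 25 for a quiet background). Of the 24
primary hits, 4 are removed as auto-fluorescent artifacts and 6 as
calcium-signaling interferers; all 7 planted strong actives (true
IC50 < 1 μM, efficacy ≥ 0.5) are among the 14 final hits, and
`result.report.eliminations` names the stage that removed everything else.

The same pipeline is scriptable from the shell:

```bash
ionscreen triage run --scenario scenario.yaml --seed 3 --out campaign/
ionscreen report --funnel campaign/funnel.json
```

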