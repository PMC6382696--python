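# Methods

This note documents the models behind each analysis stage, the synthetic
data they are validated against, the parameter defaults and why they were
chosen, and the places where the design was genuinely open.

## Kinetic-trace scoring

A well's trace is split by the trigger time into a baseline segment (7
reads by default, matching FLIPR campaign settings) and a response segment
(40 reads). The baseline statistic is the **mean** over the baseline
window: with ≥7 reads the mean is noise-robust and is the conventional
FLIPR choice. The Max-Min/Max response is direction-aware:

* quench assays (iodide/eYFP): `(B − min_post) / B`
* flux assays (calcium dye): `(max_post − B) / max_post`

where `B` is the baseline mean. The vendor formula names "Min" as the
baseline without distinguishing assay direction; applied literally to a
quench assay it yields a negative numerator, so the direction-aware
reconstruction above is used and the direction is an explicit argument.
No smoothing is applied before extremum extraction — with ≲55 reads a
smoother would be under-determined and would bias the extremum. Responses
are clamped at zero when the extremum does not cross baseline.
Membrane-potential assays integrate `F(t)/B − 1` trapezoidally over the
response segment; that AUC is signed and additive over adjacent segments.

## Normalization and plate QC

POC anchors the neutral control at 100 and the full-inhibitor control at 0
and is linear in the raw response. The anchored two-control linear form is
forced by the anchor semantics; values outside [0, 100] are preserved
(stimulators and super-inhibitors are informative). POI = 100 − POC, an
exact involution.

Z′ uses the two control populations; the Z-factor replaces the neutral
group with the test-well population — valid in an antagonist screen where
test wells are overwhelmingly inactive. Robust variants substitute the
median and 1.4826·MAD (Gaussian-consistent). The Z′ ≥ 0.5 acceptance bar
is the community convention (the campaign reported computing the
statistics but not its pass bar); it is configurable, and plates failing
it are excluded from hit calling with a recorded reason. S/B is reported
as +∞ when the inhibitor mean is zero. Degenerate control separation
yields a −∞ sentinel and a flagged plate.

## The hit funnel

Stage order is fixed: primary → confirmation → fluorescence →
counterscreen → potency; each stage is individually skippable for
ablation. Defaults (all configurable in `TriageConfig`):

| parameter | default | meaning |
|---|---|---|
| `iqr_multiplier` | 3 | IQR multiples in the primary threshold |
| `poi_extra_margin` | 20 | percentage points added to the threshold |
| `fluorescence_sd_multiplier` | 10 | neutral-SD multiples above the neutral median |
| `counterscreen_ic50_max` | 10 μM | Ca-flux elimination bound |
| `potency_ic50_max` | 5 μM | final eYFP potency bound |
| `confirmation_replicates` | 3 | confirmation runs required |

Design notes:

* The primary threshold is computed on the **POI** scale. Applied to the
  POC scale (population median ≈ 100) the same formula would exceed 100
  and call nothing; on a near-zero inhibition population it lands in the
  high-20s, consistent with a POC < 72.6 / POI > 27.4 style cutoff. The
  margin is read as 20 percentage points.
* All comparisons are strict, with directions chosen so controls can never
  be hits; ties at a boundary are non-hits.
* Confirmation uses median replicate POI **above** the cutoff. (The
  inequality stated for the original campaign — median replicate POC
  greater than the POC cutoff — would confirm inactive compounds if read
  literally; it is treated as a transcription slip.)
* The fluorescence cutoff is centered on the neutral-control median
  (median + k·SD). A cutoff of the form "FI < k·SD" alone is
  unit-dependent and fails for any bright dye, so the centered
  reconstruction is used. With zero neutral spread the filter degenerates
  to FI < median.
* Censored counterscreen fits (no measurable calcium interference up to
  the top tested concentration) are retained as specific; censored or
  non-converged potency fits are eliminated with reason `NO_FIT`.
* The threshold is computed over the whole campaign; a per-plate variant
  can be obtained by running plates separately.
* Frequent-hitter database mining and mass-spec compound QC are outside
  the analysis proper and are not modeled.

The funnel is a pure function of (dataset, config): every input compound
either survives or carries exactly one elimination reason, and stage
counts are monotone non-increasing by construction.

## Concentration-response fitting

The model is the four-parameter logistic

    response(c) = bottom + (top − bottom) / (1 + (c / midpoint)^h),

with `top` the zero-concentration asymptote, `bottom` the
infinite-concentration asymptote, and `h > 0`. Fitting minimizes
unweighted least squares in log10-concentration. Initialization scans 40
log-spaced midpoint candidates (slope 1), solving the asymptotes linearly
at each; ties resolve to the lowest midpoint, making fits deterministic.
The midpoint is bounded within ±2 decades of the tested range and the
slope within [0.1, 10].

Censoring conventions (no extrapolated potencies ever reach the funnel):

* fitted midpoint above the tested range → censored at the top tested
  concentration ("IC50 > top tested");
* fitted midpoint below the range (fully saturated responses) → censored
  at the lowest tested concentration;
* flat responses → censored;
* fitted amplitude |top − bottom| < 6 × residual RMS → censored. This
  flat-curve validity rule prevents free fits from "finding" an in-range
  midpoint in pure noise — without it, inactive compounds in the
  counterscreen would occasionally be mislabeled as interferers.

Two named presets: `fit_partial_efficacy` (free fit; the 22-point eYFP
dose responses leave the bottom free because genuine partial blockers
plateau near 40–60% inhibition) and `fit_normalized_group` (top = 1,
bottom = 0; pooled vehicle-normalized patch-clamp responses). Whether the
campaign's own 5 μM potency threshold was applied to free- or
constrained-bottom IC50s is not recorded; the free-bottom reading is used
as it is the only one consistent with reported partial maxima.

Monte-Carlo recovery conditions: a partial blocker (midpoint 0.132 μM,
bottom 0.38, slope 1) sampled on the 22-point 1:2 series with 5% CV
multiplicative noise and **4 replicate wells per concentration** — the
replication a dose-response confirmation run carries. A Cramér–Rao
analysis shows the midpoint of a free 4PL cannot be pinned within ±20%
with 95% probability from a single well per concentration at that noise
level (the information bound caps near 90% even with slope and top known),
so replication is part of the stated study conditions, not a tuning knob.

## Patch-clamp analysis

The measured statistic is the **mean** current over the 540–550 ms window
of the +100 mV step — the final 10 ms of a 500 ms step is a steady-state
window, and a literal per-sample peak would only maximize noise. The
third IV protocol per addition is selected structurally (addition index ×
protocol index), guaranteeing ≥ 60 s incubation without wall-clock
bookkeeping. Each cell is normalized to the mean of its two vehicle
additions, making everything downstream invariant to absolute current
scale; cells with non-positive vehicle reference are excluded.
Concentrations contributed by fewer than two cells are flagged and dropped
from the pooled fit. IWB percent inhibition applies the printed formula
per replicate and averages afterwards (transform-then-average).

Leak subtraction, series-resistance compensation and gating biophysics are
out of scope; the simulator is phenomenological.

## Wire-myograph analysis

A plateau is the mean over a trailing 30 s window before the next event,
accepted when the within-window slope magnitude is ≤ 0.005 mN/s (the
protocol only demands "allowed to plateau", so window and tolerance are
explicit config values). Ring calibration fits plateau tension vs
contractant concentration with the zero-concentration asymptote fixed at
the pre-dose baseline (not zero force) and the maximal contraction free;
rings with non-monotone (beyond 5% of span) or flat (< 0.2 mN span)
responses are disqualified, mirroring tissue qualification. EC25/75/95
derive from the fitted EC50 and slope via the EC-fraction identity.

Percent relaxation is the affine map anchored at the contracted tension
(0%) and the post-theophylline floor (100%); values above 100% are
reported, not clamped. Bronchodilation EC50 fits are ascending Hill
curves with the zero-dose asymptote fixed at 0% relaxation and the
maximum free by default (a constrained-to-100% preset exists); a fit is
censored when 50% absolute relaxation is never reached within the tested
doses. Onset of action is the elapsed time until tension first comes
within (1 − fraction) of its post-dose plateau span, censored when the
segment never plateaus. Theophylline concentrations are carried in μM
(2.2 mM = 2200 μM) like every other concentration. Statistics across
treatment groups are delegated to general-purpose tools.

## Expression normalization

Per sample, the 70th percentile (linear interpolation between order
statistics — fixed so the "equals the anchor exactly" post-condition
holds) of FPKM over included genes is scaled to 10. Genes in
high-homology families or with maximal transcript length < 500 bp are
excluded from the percentile computation but rescaled in the output — the
only reading consistent with excluding them *from* the percentile. The
homology list is user-supplied annotation. The map is idempotent and
rank-preserving; samples with a zero quantile are flagged un-normalizable
and passed through.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed) and return ground
truth alongside the data.

**Screen plates.** 384 wells; columns 1–22 test compounds at 5 μM, column
23 neutral control, column 24 inhibitor control (blank for the flux
counterscreen). Baseline F0 is log-normal between wells (median 1000,
log-SD 0.15); the post-trigger kinetic is a saturating exponential
(τ = 10 s) scaled by the neutral quench fraction q = 0.6 and the
compound's channel activity; read noise is multiplicative Gaussian at 2%
CV — the simplest noise models consistent with positive-valued assay
data. Fluorescent artifacts add a constant offset (2–10 × F0), which both
raises baseline FI and dilutes the apparent quench fraction, so artifacts
look like inhibitors until the FI filter — the real artifact mechanism.
Calcium interferers suppress the ionomycin calcium response through their
own Hill potency (0.05–2 μM), which also suppresses activation of the
calcium-gated channel in the primary assay. The default campaign is
10,000 compounds: 97% inactive, 0.8% full blockers, 0.8% partial blockers
(efficacy 0.3–0.7), 0.7% artifacts, 0.7% interferers, with blocker IC50s
log-uniform on 0.01–3.2 μM — a desk-scale mixture that exercises every
funnel stage in minutes.

**Patch-clamp cells.** Per-cell reference current log-normal (median
2 nA); optional exponential rundown; block follows dB/dt = k_on·c·(B_eq −
B) with B_eq the equilibrium Hill block. The slow-binder preset k_on =
0.27 μM⁻¹·min⁻¹ puts 95%-of-equilibrium at ~10 min for 1.11 μM and ~4 min
at 3.3 μM. Under the standard 60 s-per-addition protocol this produces
fitted IC50s an order of magnitude above truth, shrinking monotonically
with longer incubation — the mechanism by which cumulative fast protocols
understate slow binders.

**Myograph rings.** Tension approaches each dose's equilibrium
first-order (τ = 45 s); contraction follows the contractant Hill curve
over a 10 mN span on a 5 mN baseline; additive Gaussian noise (0.02 mN).
Relaxants act by one of two phenomenological mechanisms: `proportional`
(the relaxation fraction scales the contractile drive — a channel blocker
acting on the contraction machinery, reaching ~full relaxation at any
pre-contraction level) or `capacity` (the relaxant removes at most a
fixed absolute amount of drive — a β-agonist-like agent whose maximal
relaxation falls as pre-contraction rises). The capacity mechanism is
this package's modeling choice for reproducing the partial-vs-full
efficacy contrast as a qualitative property.

**What passing tests do not show.** The generators have no spatial plate
effects (edge/row/column gradients), no compound carry-over, no seal
degradation beyond smooth rundown, no receptor desensitization dynamics,
and Hill-form pharmacology throughout. Recovery rates measured on them
certify the analysis logic — thresholds, accounting, censoring, bias
directions — not performance on instrument data with artifacts the
generators do not model.

## Problem sizes

The default test and reproduction runs use the 10,000-compound campaign
(10 seeds for recovery rates), 100-repeat Monte-Carlo fits, 4–8 cell
patch-clamp runs and single-ring myograph experiments; these sizes were
chosen as the smallest that give stable percentage estimates at the
precision quoted.

## Known limitations

* The funnel assumes one primary well per compound; pooling replicate
  primary wells would need a pre-aggregation step.
* Censored fits carry only the bounding concentration, not an interval
  estimate.
* The Z-factor uses all test wells; heavy-hitter-rich plates would bias it
  pessimistically.
* Expression normalization trusts the user-supplied homology annotation;
  no sequence-based exclusion is attempted.
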