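# Methods

This note documents the models, parameter choices and numerical details
behind `mitopore`, in the order data flows through the package: the
channel simulator, the idealization chain, the per-experiment statistics,
the bulk-assay readouts, and the packaged study conditions.

## Channel gating model

A channel is a continuous-time Markov chain (CTMC) over a small set of
conductance states `(label, g in pS)` with generator matrix `Q` (s⁻¹,
off-diagonal ≥ 0, rows summing to zero). Paths are sampled by exact
exponential jumps and only then rasterized to the acquisition grid, so
true dwell times are exact and can serve as oracles; a per-sample Euler
scheme would quantize dwells at the sampling step. Current synthesis is

```
I(t) = I_baseline + g(state(t)) · V_h / 1000 + drift · t + ε(t)
```

with `V_h` in mV, `I` in pA, `ε` white Gaussian noise applied before
filtering. Openings are positive deflections at the study's V_h = +20 mV,
so G = I/V_h is positive.

Interventions (blocker or agonist additions) multiply selected rate
entries from their timestamp onward — no wash-in kinetics, the simplest
model consistent with pore closure rapidly following inhibitor addition.
Because the chain is memoryless, switching the generator at the
intervention time and restarting the holding clock is exact. A "full
block" zeroes every conductance-increasing rate, so the channel decays to
its lowest reachable state and stays there; an intervention with all
multipliers zero freezes the path outright.

The recording filter is a zero-phase Gaussian kernel with its −3 dB point
at the protocol cutoff (σ_t = √(ln 2)/(2π f_c)); at the default 500 Hz
this gives a 10–90 % step rise time of ≈ 0.68 ms. The kernel is symmetric,
ring-free, and preserves DC exactly, which the tests rely on. The choice
of topology is the package's own: only the cutoff is part of the recording
conditions.

## Idealization

1. **Amplitude fitting.** Conductance levels are found by multi-Gaussian
   fitting of the current amplitude histogram. The default fitter is a
   weighted EM over histogram bins (0.2 pA wide, far below the noise sd),
   where a bin's likelihood is the component's CDF mass over the bin — a
   proper multinomial likelihood. Evaluating densities at bin centers
   instead would let a component collapse onto a single bin's point mass;
   the CDF form caps any component's gain at the empirical bin mass, and a
   variance floor of (bin width)²/12 (the within-bin variance) keeps
   noise-free peaks finite. Model order k = 1…6 is selected by BIC with
   10 random restarts per order under a fixed internal seed, so fits are
   deterministic. A raw-sample EM via scikit-learn (`method="raw"`) is
   exposed as an independent cross-check and agrees with the binned fit on
   simulated mixtures; the binned route uses every sample at negligible
   cost instead of decimating.
2. **Level extraction.** The lowest-mean component is the baseline.
   Components within `event_threshold_sigmas` (default 3) baseline sds of
   the baseline are merged into it — the "events out of the noise range"
   rule — and, by the same threshold, adjacent non-baseline components are
   merged with each other (a split peak is one physical level). Components
   under 2 % weight are dropped first; they are filter-ramp smear, not
   levels. Conductances are (µ_i − µ_baseline)/V_h × 1000 pS.
3. **Assignment.** Samples are assigned to the nearest level with
   hysteresis: a switch requires crossing the midpoint between adjacent
   levels by 25 % of the gap (default), which suppresses chatter at
   midpoints. Runs shorter than `min_stable_dwell_ms` (default 20 ms,
   ≈ 30× the filter rise time) are merged into the flanking level with
   nearer current; the surviving dwells are the "stable states". The
   spec-level alternative of defining stability by histogram occupancy
   rather than dwell time is not implemented; dwell time is the
   documented operational choice.
4. **Offset correction.** A first fit/assignment pass locates closed
   dwells; a piecewise-linear baseline through their means (flat at the
   ends) is subtracted, and the final fit and idealization run on the
   corrected signal. One correction serves every statistic.
5. **Events.** Each segment boundary yields a transition event with
   signed ΔG and a duration measured as the 10→90 % crossing time of the
   filtered current between the two level currents (search capped at
   60 ms per side). A clean step reads ≈ 0.7 ms; a 20 ms linear ramp reads
   ≈ 16 ms. No duration filtering happens here.

## Per-experiment statistics

* **Inclusion** — a trace enters the G_mean analysis only if a
  non-baseline level survives the merge rule *and* carries at least one
  stable dwell. Excluded traces report "no current activity"; absent
  statistics propagate as `None`, never 0, so silence stays
  distinguishable from a measured zero conductance.
* **G_max** — max |ΔG| over events faster than 10 ms, within the
  pre-blocker span. Post-blocker G_max (for paired comparisons) starts
  5 s after the addition (`post_blocker_settle_s`) so the block's own
  closing transient is not scored as activity.
* **G_mean** — mean of the offset-corrected current over samples
  idealized to non-baseline levels in the 30 s before the blocker,
  divided by V_h. Activity samples are pooled across the window (the
  per-episode-mean alternative is not the default; pooling is exposed via
  `include_closed_in_gmean=False`, and setting it True averages over all
  window samples instead). If the blocker falls earlier than 30 s the
  window truncates to the trace start and is flagged.
* **Q_4s** — the maximum over all contiguous 4-s windows of the
  trapezoidal integral of the corrected current. "Maximal activity" is
  operationalized as the best window, which is deterministic and needs no
  manual window picking; the winning window is reported.
* **Comparisons** — `blocker_effect` is a two-sided paired t-test on
  per-experiment (pre − post) values with df = n − 1; `group_compare` is
  a two-sided two-sample Student's t-test (pooled variance; Welch as an
  option). Both delegate to scipy and are cross-checked against textbook
  formulas in the tests. All-zero paired differences return t = 0, p = 1;
  zero-variance groups with unequal means raise a degenerate-variance
  error rather than fabricating a p-value. For paired blocker contrasts,
  a trace with no post-blocker events contributes 0 pS to the test while
  remaining "absent" in per-trace reporting — a measured silence is a
  zero-conductance observation for the contrast.

## Bulk assays

* **Swelling** — fraction = (A_baseline − A_eval)/(A_baseline − A_ala),
  with A_baseline the pre-Ca²⁺ mean, A_eval the absorbance 9 min after
  Ca²⁺ (interpolated), and A_ala the post-alamethicin plateau; clamped to
  [0, 1] and invariant under affine rescaling. The normalization to the
  alamethicin maximum is an interpretation of the cited swelling method;
  the evaluation delay is configurable.
* **CRC** — a pulse is retained when fluorescence returns below its
  pre-pulse baseline plus 3× the pre-assay noise sd before the next
  pulse; CRC = retained × pulse_size / protein (µM·ml/mg = nmol/mg;
  defaults 2.5 µM and 0.4 mg/ml give 6.25 nmol/mg per pulse). Plateau
  means use the last 3 samples before an event, robust to injection
  transients.
* **OCR** — non-mitochondrial respiration (post rotenone + antimycin A
  plateau) is subtracted, then basal (pre-oligomycin) and
  oligomycin-sensitive OCR are normalized to protein. Adding a constant
  to the whole series cancels out of both.
* **Timecourses** — per ROI: background subtraction, normalization to the
  pre-addition mean (first-frame normalization is exposed as an option);
  per condition: mean ± SEM across ROIs pooled over experiments, exactly
  as imaging panels count n, with the scalar readout 8 min after the
  addition. The 475/410 GCaMP ratio masks non-positive denominators to
  NaN with a warning.

## Synthetic study conditions

The generators' defaults are the recording and assay conditions of the
study the presets emulate: 90-s traces at V_h = +20 mV, 10 kHz sampling,
500 Hz filtering, blocker at 60 s (so the G_mean window is 30–60 s);
swelling triggered by Ca²⁺ with an alamethicin end point; CRC trains of
2.5 µM pulses at 0.4 mg/ml; imaging sampled every 30 s with the readout
8 min post-addition; OCR injections oligomycin → FCCP (100 nM metadata) →
rotenone → antimycin A.

Presets anchor their conductance levels to reported per-genotype values
and add per-trace conductance jitter (CV 0.1, truncated at 0.5) so
recovery tests exercise realistic dispersion:

| preset | levels (pS) | kinetics | blocker |
|---|---|---|---|
| `wt_hela_ptp` | 0 / 460 / 827 | busy, dwells ~0.1–0.2 s | Ba²⁺ |
| `wt_hap1_ptp` | 0 / 460 / 827 | as wild-type HeLa | CsA |
| `dg_atr_ant` | 0 / 300 / 620 | sparse ~4-s full openings | BKA |
| `ant_channel` | 0 / 300 / 600 | as `dg_atr_ant` | Mg²⁺/ADP |
| `full_mmc` | 0 / 650 / 1400 | as wild-type | CsA |
| `null_closed` | 0 / (827) | no transitions possible | — |

Dwell-time statistics and open probabilities are not reported for any
genotype, so preset kinetics are free parameters. They were calibrated
once so that the *full pipeline's* batch means land on the printed
targets: for the wild-type-like channel, stationary occupancy ≈ 0.39
closed / 0.19 substate / 0.42 open reproduces G_mean ≈ 703 pS
(activity-weighted level mean) and Q_4s ≈ 48 pC (the best 4-s window mixes
open and closed time); for the ANT-type channel, rare long full openings
(~3.8 s, ~4 per minute) against brief substate sojourns reproduce the
low G_mean (434 pS) together with the near-full-open Q_4s (47 pC).
Direct closed↔open transitions are present in both so the full-level jump
appears as a fast event in essentially every trace. After calibration the
kinetics are frozen; they are conditions, not tuning knobs.

What the simulator does *not* emulate: wash-in kinetics of blockers,
open-channel (flicker) noise in excess of the stationary Gaussian noise,
baseline artifacts other than linear drift, voltage protocols other than
a constant holding potential, missed-event statistics of real recording
chains, and image formation (ROI tables are generated directly). Passing
recovery tests therefore demonstrates correctness of the analysis under
these idealized conditions, not robustness to every artifact of bench
data.

## Problem sizes and runtime choices

Round-trip batches use 20 traces of 90 s (the acceptance script and the
corresponding test both use n = 20, the package's chosen batch size for
stable means at modest runtime). The statistical-engine calibration runs
200 replicates of 5 paired experiments on 20-s traces at 5 kHz, using an
oracle-segmentation G_max estimator (true state path + empirical
per-window level currents) so the type-I check measures the t-test's
behavior on realistic estimator noise rather than the mixture fitter's
runtime. CTMC occupancy checks sample the state every 1.5 s of a 300-s
path — beyond the mixing time of the test models — so a χ² test against
the analytic stationary distribution is valid.

## Known limitations

* Level estimates carry a ≈ 0.5 % downward bias from filter-ramp samples
  absorbed into the mixture components; it is far below the
  between-experiment dispersion the presets model.
* The idealizer is a threshold/hysteresis assigner, not a hidden-Markov
  decoder; kinetics (dwell-time distributions) are recovered only down to
  the stability threshold, and no missed-event correction is applied.
* `extract_levels` assumes openings are positive deflections (V_h > 0),
  matching the study's recording convention.
* The CRC release criterion assumes a monotone post-release rise, as the
  simulator produces; oscillatory release would need a different rule.
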