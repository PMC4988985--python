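# Methods

## The analysis chain

One slice experiment is a cells × frames fluorescence matrix F (arbitrary
units, strictly positive), frame timestamps with constant spacing
(0.5–2 s), and an ROI table of centroids and radii in μm. Analyses use only
the first 10 min of a recording.

**Normalization.** R[c, i] = F[c, i] / mean(F[c, 0..49]) (the baseline frame
count is configurable). The per-cell mean of the first 50 normalized frames
is 1 by construction; responder calls are invariant to positive rescaling of
the raw input because the scale cancels.

**Responder calling.** A cell is a responder when R exceeds
baseline mean + k·SD (default k = 3; baseline statistics from the first 50
frames) for at least 3 consecutive frames between stimulus onset and
onset + horizon (default: stimulus duration + 120 s). The sustained-run
requirement exists because a single-frame max over a ~240-frame horizon at
3 SD has a 25–30% family-wise false-positive rate under 5% multiplicative
noise; requiring 3 consecutive supra-threshold frames drives that to
effectively zero while leaving genuine responses (which persist for tens of
seconds) untouched. There is no field-standard definition of "responding"
for this preparation; the thresholded criterion is this package's
operationalization, and k, the horizon and the run length are exposed.

**Classification.** Peaks above the responder threshold after onset are
counted with prominence 0.5 × (peak ratio − 1) and a 10 s minimum
inter-peak interval; 1–2 peaks → biphasic, ≥3 → oscillatory.

**Synchrony.** Spearman's ρ between the windowed ratio series of every
unordered responder pair: midranks (average ranks on ties), then the Pearson
formula, p two-sided from t = ρ√((n−2)/(1−ρ²)) on n−2 df. Rank correlation
is invariant to strictly monotone transforms, so correlating F_i/F_0 is
exactly equivalent to correlating ΔF/F_0. Zero-variance windows give a
flagged degenerate pair (ρ = NaN) that is excluded from statistics but kept
in pair counts. Analysis windows are half-open [start, end); the defaults
are before = [100, 200), during = [250, 350), after = [500, 600) s.
Group-level contrasts use the two-sided Mann–Whitney U with the tie-corrected
normal approximation. Sliding correlation matrices (default 50 s window,
10 s step — both free choices) feed heat-map plots.

**Distance analysis.** Pair distance is centroid-to-centroid or
membrane-to-membrane (centroid − r_a − r_b, floored at 0); membrane is the
default everywhere, including the <5 μm short-range comparison. The
ρ-vs-distance line is ordinary least squares over pairs with ρ > 0 (the
positive-only convention of the published workflow; a full-range flag
exists), preceded by a Pearson correlation screen that is reported with the
fit. Two fits are compared with t = (b₁−b₂)/√(SE₁²+SE₂²), df = n₁+n₂−4,
two-sided, α = 0.001 attached as metadata. This two-sample form is
algebraically the interaction-term t under equal residual variance.

**Coupling coefficient.** Per-sweep steady-state deflection = mean(V) over
the last 20% of the current step minus mean(V) over the 100 ms before step
onset. CC = mean deflection of the follower / mean deflection of the
injected cell; SEM is the standard error of per-sweep ratios. Ratios are
refused when the mean injected deflection is under 1 mV (unstable
denominator). A pair is "coupled" when CC > 3 × SEM in both injection
directions; the z-threshold is exposed because detectability has no
published operational definition.

**PWM scan.** Site score S = Σ log₂((f + p·bg)/bg) with total pseudocount
p = 0.8 split by the background (uniform 0.25 default); relative score
= 100 × (S − S_min)/(S_max − S_min) using per-position minima/maxima, so the
consensus scores 100% and the per-position-worst site 0%. Both strands are
scanned over the window_length bases upstream of the TSS; positions are
1-based bp upstream of the TSS measured to the hit edge nearest the TSS.
Sites containing N are skipped. Raw log-odds are available via
`PWM.log_odds`.

## The synthetic network model

The generator is a phenomenological model whose purpose is to produce, with
known ground truth, exactly the statistical structure the analysis chain
measures. It is not a biophysical (conductance-based) model, and no hormone
secretion or feedback is simulated.

* **Geometry.** n_cells (default 60) disks of radius 5 μm placed uniformly
  in a 150 × 150 μm field with hard-core minimum separation 2 × radius.
* **Timeline.** 600 s at 1 frame/s; F₀ reference baseline 0–120 s; the
  stimulus reaches the cells at 240 s and lasts 120 s, so evoked activity
  falls inside the canonical during window.
* **Responders.** A fraction (default 0.4, giving ≈24 responders and ≈276
  responder pairs per experiment, ≈1900–2000 pooled over 7 experiments per
  arm) respond after a per-cell latency; the others stay at baseline.
  Waveforms: biphasic = amplitude 1.5 Δratio, 4 s rise, 80 s decay to a 35%
  plateau; oscillatory = amplitude 1.2, (1−cos) cycles of period
  ~N(40 s, 3 s) under a 180 s decaying envelope. The waveform kinetics are
  free parameters (no quantitative description exists for this
  preparation); values were fixed once so responses complete within the
  10-min window and peak ratios (≈2–2.5) sit far above the detection
  threshold at default noise.
* **Latency.** latency = 15 s + 0.15 s/μm × (position projected on a random
  wash-in direction) + N(0, 4 s). The gradient models stimulus wash-in
  across the field under bath perfusion (≈22 s spread over 150 μm); it is
  what makes nearby cells respond at similar times even without gap
  junctions, and hence gives the *uncoupled* arm its negative ρ-vs-distance
  slope.
* **Coupling.** w_ij = coupling_strength × exp(−d_ij/10 μm) on membrane
  distance (strength default 1). It acts twice: (i) latencies and
  oscillation periods are entrained by iterated diffusive averaging over
  the full graph (50 iterations, i.e. near-consensus on the connected
  network — non-responding cells still relay timing), which flattens the
  distance dependence of synchrony; (ii) the evoked signals of responding
  cells are mixed one diffusive step over the responder subgraph, which
  adds short-range synchrony. Mixing is restricted to responders so that
  coupling does not recruit extra threshold-crossing cells and both arms
  keep comparable responder counts.
* **Tonic scenario.** With `tonic_coupling`, every cell carries a slow
  baseline fluctuation (Gaussian process, 20 s correlation time, sd 0.04 of
  baseline) which is mixed over the coupling graph when coupling is enabled
  and re-standardized to the same per-cell amplitude (mixing sets the
  correlation structure; the amplitude is its own parameter). This is the
  scenario in which short-distance pairs differ between arms in *all*
  windows, not only under stimulation.
* **Noise.** Multiplicative log-normal (σ = 0.05) plus additive Gaussian
  (2 a.u. on baselines of 300–800 a.u.).
* **Reproducibility.** One global seed fans out into named sub-streams
  (layout, classes, latency, periods, tonic, noise) via CRC32-keyed
  SeedSequences, so identical configs give bit-identical datasets and
  consuming one stream differently never perturbs the others.

The paired-recording simulator is ohmic and first-order: a current step I
into cell 1 gives ΔV1 = R_in·I (R_in = 200 MΩ) with τ = 10 ms kinetics;
cell 2 follows with ΔV2 = CC_true × ΔV1; independent Gaussian noise per
sample on both channels; 5 kHz sampling, 100 ms baseline, 500 ms step.
Step amplitude and duration are plausible defaults, not published values.

### What the generator does and does not emulate

It reproduces: responder fractions and pair counts at the scale of the
motivating experiments, biphasic/oscillatory waveform classes,
distance-dependent coupling with strongest effects below ~5 μm membrane
distance, higher during-window synchrony and flatter distance decay in the
coupled condition, and weak (~0.025) symmetric electrotonic coupling.

It does not emulate: photobleaching or focus drift, cell movement,
indicator saturation, spatially correlated shot noise, irregular frame
timing, secretion-coupled calcium dynamics, or any hormonal feedback. A
passing pipeline on synthetic data therefore demonstrates correctness of
the statistics and recoverability of coupling signatures under the model's
assumptions — not performance on any specific real recording.

## Numerical choices and degenerate inputs

* Zero-variance series: flagged degenerate, excluded from group statistics
  and regressions, never silently dropped from pair counts.
* |ρ| = 1 receives p = 0 (the t statistic diverges).
* Regression requires ≥3 pairs after filtering and non-zero distance
  spread; the error reports the observed counts.
* The short-range comparison reports both groups' minimum distances when no
  pair falls under the threshold.
* Mann–Whitney uses the asymptotic method with continuity correction;
  identical groups give p ≈ 1 (≥0.99).
* The CLI/pipeline report contains no timestamps, and JSON keys are sorted,
  so identical config + seed yields byte-identical reports.

## Problem sizes used in validation

The test-suite and acceptance runs use 7 simulated experiments per arm with
60 cells each (the scale of the motivating experiments), 10 replicate seed
sets for direction-of-effect checks, 100 Monte-Carlo seeds for
coupling-coefficient calibration, 1000 vector pairs for the Spearman oracle,
and 100 random 300-bp windows for PWM strand symmetry. These sizes make the
whole suite run in well under a minute of simulation compute while keeping
every statistical margin wide.

## Known limitations

* The responder criterion and the coupled/not-coupled z-test are this
  package's operationalizations of informally described procedures; both
  are parameterized rather than hard-coded for that reason.
* The between-fit slope test assumes independent fits and equal residual
  variance; pooled pairs within an arm share cells and are not strictly
  independent, so p-values at the group level are mildly anti-conservative
  (empirically ≈7% type-I at α = 5% for the pooled Mann–Whitney under the
  null). This mirrors the published analysis design rather than correcting
  it.
* Latency entrainment by graph diffusion is a stand-in for wave propagation
  through gap junctions; it reproduces the correlation structure but not
  propagation delays.
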