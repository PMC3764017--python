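# Methods

`nmjquant` analyzes intracellular recordings from the neuromuscular
junction (NMJ): spontaneous miniature endplate potentials (MEPPs), giant
MEPPs (GMEPPs) and nerve-evoked endplate potentials (EPPs), and the
classical quantal description of transmitter release built on them.  This
note documents the model, the measurement conventions, the synthetic-data
generator, and the design choices made where the procedure was genuinely
open.

## Signal model

A recording is a uniformly sampled voltage trace (mV) riding on a negative
resting membrane potential (RMP).  Each synaptic event is modelled as a
positive deflection with the two-parameter kernel

    k(t) = (1 − e^(−t/τr)) · e^(−t/τd),   t ≥ 0,

peak-normalized and scaled by the event amplitude.  Two time constants
reproduce the ~1 ms rise / ~3–4 ms decay kinetics of diaphragm endplate
potentials.  Events superpose linearly (no receptor saturation or driving
force nonlinearity is modelled); EPPs are the linear sum of a Poisson
number of quantal amplitudes released at a fixed latency after the
stimulus, which matches the ratio-of-means quantal-content estimator used
downstream (no nonlinear-summation correction anywhere).

A geometric limitation worth knowing: under the conventions below, this
kernel family cannot produce a measured decay constant much below ~2.8×
the measured 10–90% rise time.  Kinetic target pairs outside that region
(slow rise with fast decay) are calibrated best-effort and come out
compressed toward the feasible boundary.

## Measurement conventions

* **Amplitude** — positive peak deflection relative to a local baseline
  (median of a 10 ms pre-onset window, robust to overlapping decay tails).
  The detector estimates amplitude by least-squares projection of the raw
  segment onto the (per-fiber re-fitted) kernel, which is unbiased under
  zero-mean noise, unlike a raw max-sample readout.
* **Rise time** — 10–90% with linear interpolation between samples
  (20–80% available by configuration).
* **Decay time** — exponential time constant fitted to the log of the
  falling phase between 90% and 10% of the peak (half-decay time available
  by configuration).
* **Classes** — candidate deflections below 0.2 mV are rejected; the MEPP
  band is the half-open interval [0.2, 1.0) mV; amplitudes ≥ 1.0 mV are
  GMEPPs (the boundary value itself is a GMEPP).
* **Kinetic smoothing** — a quadratic Savitzky–Golay filter (0.9 ms
  window) is applied to measurement segments only; it preserves the
  locally parabolic peak while suppressing sampling noise.

## Event detection

The default detector is a matched filter: the baseline-subtracted trace is
correlated with a unit kernel (10 ms support), local maxima of the
matched-amplitude signal above 0.12 mV are candidate onsets, and
candidates closer than 5 ms are merged (the maximal peak wins, flagged).
A second pass re-fits the kernel time constants to the fiber's average
detected waveform before amplitudes and kinetics are measured; this
removes the shape-mismatch bias a fixed template would impose on fibers
with atypical kinetics.  Measurement segments are truncated at the next
candidate onset so a following event cannot contaminate a decay fit; a
truncated fit that never reaches 10% of the peak is flagged rather than
reported.  A simpler derivative-threshold detector (MAD-gated slope
threshold on the smoothed trace) is available as an alternative
configuration.

At the design noise level (0.05 mV SD) and the 0.2 mV floor the default
detector's recall and precision exceed 0.95 against ground truth, and on
noise-free traces it reproduces injected counts exactly and amplitudes to
within 1%.

## Quantal analysis

Amplitudes recorded at RMP `V_m` are normalized to the −75 mV reference as
`V_nor = V_obs · (−75) / V_m`; fibers are accepted only with a stable RMP
in [−80, −60] mV (inclusive).  Per fiber, the mean EPP is the average of
the first 60 consecutive sweeps (each sweep normalized at its own RMP) and
the mean MEPP averages the first 100 consecutive MEPPs; shorter records
are used in full and flagged.  Quantal content is the per-fiber ratio of
normalized means, m = ⟨EPP⟩nor / ⟨MEPP⟩nor, and group values average the
per-fiber m — deliberately not the ratio of group means, which differs on
heterogeneous cohorts.  Fibers without GMEPPs carry no GMEPP/MEPP
frequency ratio and are excluded from that group mean.

## Amplitude-distribution decomposition

Pooled MEPP amplitudes are histogrammed in 0.05 mV bins over [0.2, 1.0)
(boundary values go to the upper bin) and fitted by unweighted nonlinear
least squares with one Gaussian or a sum of two; goodness of fit is the
squared correlation coefficient R².  Initialization is deterministic:
moments of the histogram for the single fit; peaks at the weighted
25th/75th percentiles, widths at half the pooled SD, and local bin counts
as heights for the double fit.  Fitted peak locations are constrained to
the observed band (±0.02 mV): a component pushed outside it would model a
truncation edge, not a subpopulation.

The distribution is called **bimodal** only when three conditions hold:
ΔR² ≥ 0.03 over the single fit, peak separation ≥ 0.15 mV, and the smaller
component height at least 10% of the larger.  All three thresholds are
configurable and logged.  Fibers are then labelled A/B by their mean MEPP
amplitude against a cutoff that defaults to the cohort's pooled mean of
per-fiber means (ties go to B), and the grouping is validated by requiring
each group's own fitted peak to match the corresponding pooled peak within
0.05 mV.

## Group comparison

Two fiber-level samples are compared through a gatekeeper tree: Shapiro–
Wilk normality on each group (α = 0.05; applied at every n), then a
two-sided F test of variance equality (larger variance on top).  Both
normal and equal variances → Student's t; normal but unequal variances →
Welch's t; any non-normal group → Mann–Whitney U.  All tests are
two-sided, significance is p < 0.05, and no multiple-testing correction is
applied across summary-table rows (stated in every emitted header).  On
Gaussian nulls (n = 40 per group) the full choose-then-compare pipeline
holds its type-I error near the nominal 5% (the acceptance script measures
it over 2000 replicates).  Percent changes are reported signed with a
half-up integer rounding alongside the exact value.

## Synthetic-recording generator

The generator emulates the study conditions the presets come from: 100 s
gap-free traces at 10 kHz, additive white Gaussian noise of 0.05 mV SD,
Poisson MEPP trains with Gaussian amplitude spread of 0.09 mV SD within a
fiber, an independent GMEPP process (mean 1.6 mV, SD 0.35 mV, truncated at
1.05 mV — published GMEPP amplitude statistics are not available, so these
are a realistic choice), and 60 stimulus-locked sweeps at 0.5 Hz
with Poisson quantal counts.  Per-fiber RMPs are uniform on [−80, −60] mV.

Five presets parameterize fiber populations measured in wild-type and
SOD1(G93A) mouse diaphragm at two disease stages (young/adult wild type,
pre-symptomatic transgenic, and the symptomatic SOD1a/SOD1b
subpopulations).  Preset calibration works backwards from what the
pipeline measures:

* between-fiber spreads are the published SEM × √n of each measure;
  positive skewed quantities (frequencies, quantal content) draw from a
  lognormal with that mean and SD, others from clipped normals;
* per-fiber kernel time constants are solved numerically (cached on a
  0.05 ms grid) so that the package's own rise/decay conventions, applied
  to a noise-free sampled event, reproduce the fiber's kinetic targets;
* generative amplitude means and rates are inverse-corrected for the
  0.2 mV floor (root-finding on the band-truncated normal mean) so the
  *detected* MEPP amplitude and frequency match the targets, and the
  quantal mean is scaled by the matching factor so the estimated quantal
  content is comparable to its target;
* GMEPPs occur in the preset's published fraction of fibers, with the
  exhibiting-fiber frequency statistics.

Per-fiber seeds derive from the master seed via
`SeedSequence(seed, spawn_key=(fiber_index,))`, so ensembles are exactly
reproducible.  Ground truth (event times, amplitudes, generative classes,
quantal counts) is retained for recovery tests; classes reflect the
generating process, not the detection band.

What the generator does **not** emulate: line hum, electrode drift,
stimulus artifacts, muscle action potentials, correlated noise, biological
rise/decay correlation beyond a feasibility clip (decay ≥ 1.4× rise), or
any dependence of quantal content on RMP.  Passing recovery tests
therefore demonstrates correctness of the analysis under the stated
statistical structure, not robustness to every artifact of real
recordings.

## Problem sizes and replication

The study drivers use the published cohort sizes: 40 + 40 fibers for the
pre-symptomatic comparison and 19 + 20 for the symptomatic decomposition;
multi-seed rates use 50 replicate ensembles, and the null-calibration run
uses 2000 replicates of n = 40 per group.

One property of the published effect sizes is worth stating explicitly,
because the replication harness computes it: with between-fiber spreads
equal to SEM × √n of the source tables, the rise-time contrast
(1.32 ± 0.07 vs 1.11 ± 0.08 ms, n = 40) has only ~50% two-sided power at
α = 0.05, and the decay-time contrast (4.00 ± 0.15 vs 3.67 ± 0.14 ms) is
itself significant in roughly a third of replicates.  The probability that
one simulated replication reproduces the full seven-measure significance
pattern is therefore modest by construction; the acceptance script reports
the observed rate rather than forcing it.

## Known limitations

* The kernel family's rise/decay feasibility constraint (above) compresses
  extreme kinetic targets; the SOD1a preset's published combination sits
  outside the feasible region and its simulated kinetics are
  correspondingly approximate.
* The pooled amplitude histograms are frequency-weighted (every detected
  event counts), so a high-frequency low-amplitude fiber can dominate the
  low-amplitude component and push its fitted peak to the band edge; the
  classification cutoff, which works on per-fiber means, is insensitive to
  this.
* Fibers are treated as independent units; nesting within animals is not
  modelled (no mixed-effects machinery).
* Only one- and two-component Gaussian decompositions are considered; no
  general mixture-order selection or dip-test bimodality testing.
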