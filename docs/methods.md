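# Methods

This note documents the models, numerical choices, and design decisions
behind `slicephys`, and what the synthetic-data validation does and does not
establish about real recordings.

## Data model

A recording is a `SweepSet`: equally long sweeps sampled uniformly (fixtures
use 20 kHz, but every window is specified in seconds so arbitrary rates
work), with per-sweep stimulus epochs, a commanded holding level, and
free-form annotations. Current-clamp sweeps carry membrane potential in mV;
voltage-clamp sweeps carry pipette current in pA with inward currents
negative, stored as recorded. Two dialects round-trip the container: a text
dialect (CSV of `sweep,time_s,value` plus a JSON sidecar; values written
with 17 significant digits, so the round-trip is bit-exact) and an HDF5
dialect for long sweeps. No liquid-junction-potential correction is applied
anywhere.

## Test-pulse metrics and quality control

The −5 mV/250 ms test pulse at the start of each voltage-clamp sweep is
decomposed in the standard way: the capacitive-transient peak current sees
only the access resistance, so Rs = ΔV/I_peak; the steady-state current
(mean of the final 50 ms, relative to a 100 ms pre-pulse baseline) sees the
access and membrane resistances in series, so Rin = ΔV/I_ss − Rs. The peak
is taken from the sampled trace; at 20 kHz the first sample after the step
underestimates the true t=0 peak by roughly `dt/τ'` (a few percent for
typical cell parameters), which is the dominant, documented bias of the Rs
estimate. Both metrics are invariant to a constant holding-current offset.

Rs/Rin stability is evaluated from endpoint sweeps — (last − first)/first —
because monitoring "throughout the experiment" needs a definite comparison
rule; the per-sweep metrics remain available if a different rule is wanted.
QC fails a recording when RMP is more depolarized than −55 mV (−45 mV for
anterodorsal-thalamus recordings, which rest more depolarized), Rs exceeds
35 MΩ, |ΔRs| exceeds 25%, or Rin *decreases* by more than 25%. The Rs-change
rule is two-sided (either direction indicates an unstable access path); the
Rin rule is one-sided, matching the stated exclusion. All thresholds are
strict inequalities, every violated rule is reported, and the report is
monotone: worsening a measurement can never turn a failure into a pass.

## Synthetic membrane (current clamp)

The spiking simulator is an adaptive exponential integrate-and-fire (AdEx)
membrane with an additive slow sag current. Real neurons are not AdEx, but
AdEx reproduces every feature the extractor measures — a smooth spike
upswing with a well-defined dV/dt threshold, spike-frequency adaptation via
the spike-triggered increment `b` (the subthreshold coupling `a` defaults
to 0 so that the passive response is exactly RC and ground-truth Rin equals
the configured R), a refractory reset, and an Ih-like sag. The sag current
is `g_h·m·(E_h − V)` with `g_h` expressed as a fraction of the leak
conductance, `E_h = −45 mV`, activation `m_∞(V) = 1/(1+exp((V+80)/6))`
(activating on hyperpolarization), and first-order kinetics with
`sag_tau_ms`. The membrane is biased to −65 mV by an explicit holding
current solved from the resting steady state, mirroring the experimental
bias.

Integration is fixed-step exponential Euler at the trace sampling interval:
the leak/sag/adaptation terms are integrated exactly over each step with
the exponential spike term held constant, so the passive response is exact
to machine precision and spiking trajectories converge to a 10× oversampled
reference (the `oversample` argument) to within one spike per sweep. Spikes
are registered when V crosses 0 mV; the emitted sample is painted at
+35 mV and the state reset, so a spike occupies one sample with a realistic
upswing before it. Non-finite states abort with a simulation error.

Default step protocol: 0.2 s baseline, 1 s steps, one −20 pA passive step
plus 0–400 pA in 50 pA increments. The family deliberately includes 0 pA
because the F-I regression starts there; the passive step doubles as the
sag/Rin/τ probe.

## Intrinsic-property extraction

Spike threshold is located by backward search from each peak for the last
upward crossing of dV/dt (central differences) through 10 mV/ms — backward
search is robust to pre-spike wiggle; the criterion itself is fixed. On a
constructed piecewise-linear ramp the detected threshold is exactly the
first ramp sample, which the tests assert. Half-width uses linear
interpolation between samples on both flanks (0.05 ms quantization at
20 kHz would otherwise bias short spikes). The decay window runs from the
peak to the trough before the next spike (or 10 ms).

F-I analysis regresses count on current over [0 pA, argmax-count step],
capped at 400 pA, ties broken to the lowest current; rheobase is the
smallest step current with at least one spike, reported absent when nothing
spikes (gain is then computed over the full range and is 0). The adaptation
index selects the 1 s sweep closest to twice rheobase (ties to the lower
current); spikes are assigned to halves by peak time, a peak exactly at the
midpoint counting toward the first half.

The membrane time constant is fitted with a single exponential
(`c + a·exp(−t/τ)`, Levenberg–Marquardt, τ initialized from the 1−1/e
crossing) from step onset to the maximum response. The fit starts at onset
as specified; for strongly sagging cells the window ends at the early sag
peak, which shortens the fit but keeps it on the monotone segment.
Capacitance is reported as Cin = TC/Rin computed from the stored averages,
so the identity is exact on reported values. Sag uses absolute deflections
(sag ≥ 1 convention). Multiple hyperpolarizing steps are averaged.

## Spontaneous-EPSC detection

The detector mirrors a threshold-based commercial tool whose exact
algorithm is proprietary; the published parameters are kept verbatim
(negative direction, 5 ms local maximum period, 30 ms decay search,
8 pA threshold, 10 ms search period, 1 ms averaged baseline, curved
baseline). The open choices were resolved as follows:

- **Curved baseline**: rolling median over 0.5 s — drift-following but
  resistant to events at physiological rates. It is computed on a ~2 kHz
  decimated copy and re-interpolated; a 0.5 s median varies far more slowly
  than the decimation step, so this is numerically indistinguishable from
  the exact rolling median while fast on 600k-sample sweeps.
- **Candidates**: local minima of the baseline-subtracted signal (smoothed
  with the 1 ms averaged-baseline boxcar to reject single-sample noise)
  deeper than the threshold, with minima closer than the 5 ms local-maximum
  period merged into the deeper one. Using minima rather than raw threshold
  crossings also finds events that arrive while the trace is still below
  threshold from a preceding event. Each candidate is then refined to the
  most negative raw sample nearby and re-merged.
- **Onset and local baseline**: the onset is the latest pre-peak point where
  the smoothed deviation recovers to 20% of the peak deviation (the foot of
  the downstroke), searched within the 10 ms search period; the local
  baseline is the mean of the 1 ms immediately before onset, and amplitude
  is local baseline minus raw peak. On noise-free events this returns the
  configured amplitude exactly.
- **Noise rejection**: the manual inspection step is replaced by
  deterministic rise-time bounds (default 0.1–5 ms, peak minus onset);
  candidates that never recover to the 20% level inside the search window
  (they sit on another event's decay) are discarded.

Events whose peaks fall in exclusion epochs (test pulse, optical artifacts)
are dropped. Per-sweep frequency divides the post-discard event count by
the analysis window: sweep duration minus 1 s, or minus 2 s when
optogenetic stimulation is present (count/29 s and count/28 s for 30 s
sweeps). Kinetics come from the peak-aligned averaged event (−5 ms to
+30 ms, matching the decay search period): interpolated half-width and a
single-exponential fit to the decay from the peak. The biexponential rise
contaminates the first ~1 ms after the peak, biasing the fitted τ upward by
a few percent — within the 10% recovery tolerance the tests enforce.

The sEPSC generator draws homogeneous Poisson onsets over the whole sweep,
lognormal amplitudes, and a peak-normalized biexponential kernel
(`exp(−t/τ_d) − exp(−t/τ_r)`, default 0.5/8 ms) superposed linearly, with
white Gaussian noise (default 2 pA) and an optional sinusoidal drift that
exercises the curved baseline deterministically. Defaults (median 18 pA,
σ_log 0.35, 2 Hz) sit in the physiological range for cortical pyramidal
cells at −70 mV. What this validation shows: the detector recovers rates
within a few percent, is insensitive to slow drift, and has a sharp
sensitivity cliff around the 8 pA threshold. What it does not show: real
recordings have correlated (non-white) noise, multiplicative access-
resistance filtering, and non-Poisson event clustering; performance there
must be judged on real data.

## Evoked trains

Per-pulse truth follows the Tsodyks–Markram recurrence (resources `x`
recover with τ_rec; utilization `u` decays with τ_facil, `u₁ = U`,
release = u·x), scaled so the first pulse has the configured amplitude.
Measurement averages trials point-wise first (reduces peak-picking noise
bias), then re-measures a 5 ms baseline before each pulse — at 10 Hz the
50 ms windows leave gaps where incomplete kernel decay would bias later
pulses if a single sweep baseline were used — and takes amplitude as
baseline minus the window minimum and area as the baseline-subtracted
trapezoidal integral (pA·ms) over 50 ms. With an 8 ms kernel the per-pulse
baseline makes the recurrence recovery exact to machine precision;
slower kernels (τ ≳ 20 ms) would reintroduce a small overlap error.
Normalized profiles are invariant to amplitude scale and holding offset by
construction, and `normalized[0] = 1` always.

## Statistics

Spine counts and sEPSC frequency/amplitude are log-transformed before
testing — a fixed per-measure-class rule reflecting the empirical
lognormality of these measures, not re-decided per dataset; the
Shapiro–Wilk-based `distribution_shape` classifier (raw vs log, higher W
breaking ties) is applied only to measures outside those classes (and only
with n ≥ 8 per group). Two-sample tests are pooled-variance Student t
(df = n₁+n₂−2), two-tailed, matching the degrees-of-freedom convention of
the reported analyses; group summaries are always on the raw scale with
SEM = SD/√n. Paired tests guard the zero-variance-difference edge:
identical pairs give t = 0, p = 1; a constant nonzero (log-)shift gives
t = ±∞, p = 0 rather than overflow.

Dunnett many-to-one comparisons use `scipy.stats.dunnett` (multivariate-t
evaluation); with two groups this reduces to the plain t test, and adjusted
p-values never fall below the unadjusted p of the same statistic. The
calibration tests measure the empirical type-I error of the log-scale t
test (1000 replicates) and the Dunnett family-wise error with three null
groups (2000 replicates) against a 5% ± 1.5% band.

Spine density is count/length per dendrite with branches shorter than
40 µm excluded and at most 5 dendrites per compartment per neuron admitted
in the order supplied (densities can be reported per µm or per 10 µm).

The transcriptomic screen runs on synthetic negative-binomial cell tables
only; cluster labels are mapped to layers by exact-substring matching
against the enumerated annotation tokens (the lists are verbatim, so
substring matching — not regex — is the faithful rule), with the
low-rheobase retrosplenial cluster `133_L2 IT RSPv-POST-PRE` taking
priority over the generic L2 rule. Group contrasts use raw counts; whether
real analyses used raw, CPM, or log-normalized expression is left
configurable upstream of the contrast.

## Pipeline and reproducibility

The demo pipeline simulates a control and a drug cohort (defaults: 6 cells
each, 1.0 vs 1.8 Hz — a rate contrast of the size seen in acute-pharmacology
experiments), runs test-pulse QC, detection, and summaries per cell, and
compares cohorts with the log-scale unpaired t test. Per-cell seeds are
spawned from the master seed with `numpy.random.SeedSequence`, every seed
and parameter lands in the manifest together with SHA-256 hashes of the
output tables, and a rerun under the same configuration is byte-identical.

## Problem sizes

The validation suite and the acceptance script use deliberately moderate
problem sizes — 30–50 synthetic cells for recovery sweeps, 10 × 30 s sweeps
per rate for detection, 1000-replicate calibrations, 2-sweep demo cells —
chosen so the whole validation runs in well under an hour on a single CPU
while keeping Monte-Carlo error small against the stated tolerances (e.g.
±1.5 percentage points on a 5% rate needs ≳1000 replicates).

## Known limitations

- The AdEx + sag membrane is a stand-in; recovery results bound estimator
  error under the model, not under real biophysics.
- Rs estimation from the sampled transient peak carries a systematic
  percent-level underestimate of I_peak at 20 kHz (documented above).
- The TC fit starts at step onset as specified; if real traces carry a
  capacitive artifact in the first samples, the fit window may need a
  guard interval — the sensitivity is small for τ ≥ 8 ms.
- The detector's merged-event rule means two true events closer than 5 ms
  are reported as one; at 5 Hz this removes ~2.5% of events by design.
- Cell-level means are the analysis unit for group tests; sweep-within-cell
  hierarchies are not modeled.
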