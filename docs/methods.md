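# Methods

This note documents the models, estimators, parameter choices and numerical
decisions behind `envwhiten`, and what the synthetic-data tests do and do
not establish about real recordings.

## Stimulus model

The AM carrier is white Gaussian noise band-pass filtered to 5–15 Hz with a
4th-order (analog prototype) Butterworth response, applied
forward-backward so the carrier is zero-phase, then normalized to zero mean
and unit RMS.  Zero-phase filtering is used everywhere in the package:
amplitude comparisons, not latencies, are the scientific target, and phase
distortion would bias the spike-triggered average's lag structure.

Stimulus amplitudes are dimensionless **contrast units** with baseline 1.
No physical (mV/cm) calibration exists in silico, and every comparison the
pipeline makes is relative, so gain is expressed in Hz per unit contrast.

Envelopes:

- *Sinusoidal*: `E(t) = 1 + d·sin(2π f_env t)` with depth `d = 0.20` by
  default and `f_env ∈ {0.05, 0.1, 0.2, 0.5, 0.75, 1} Hz`.
- *Natural*: white Gaussian noise shaped in the frequency domain so its
  one-sided power spectrum follows `f^α` (default `α = −0.8`) over
  0.05–1 Hz and is zero outside, then offset to mean 1 and scaled so the
  RMS contrast equals the requested depth.  Depths that would force the
  envelope negative are rejected rather than clipped, because clipping
  distorts the spectrum the generator exists to produce.

A readout utility measures the realized modulation depth from the magnitude
of the analytic signal, low-pass smoothed (2nd-order Butterworth, 0.5 Hz,
zero-phase) and detected synchronously at the delivered envelope frequency
and phase.  The carrier magnitude of band-limited noise fluctuates with
substantial power inside the detection band, so a single 100 s realization
carries ~2–3 percentage points of stochastic error; the readout is unbiased
(lock-in detection), and depth estimates are therefore averaged over
independent carrier realizations wherever a population value is reported.

## Neuron model

Units are rate-model neurons:

```
r(t) = max(0, r0 + G0·f^β·(E(t) − 1)  +  k_am·s(t))
```

with baseline `r0`, envelope gain `G(f) = G0·f^β` applied to the envelope
deviation (for natural envelopes the deviation is filtered in the frequency
domain by the transfer function `G0·f^β·e^{iφ}`), and an AM-sensitivity
term `k_am·s(t)` coupling the fast stimulus waveform into the rate, which
is what the spike-triggered average measures.  Spikes are drawn as an
inhomogeneous Poisson process by thinning at the stimulus sampling step
(required ≤ 0.5 ms), with an optional absolute refractory period.  Rates
approaching the thinning resolution are rejected as model-invalid.

Condition presets encode the qualitative structure of the experimental
conditions — only the exponent values and gain directions are
condition-defining; the absolute coefficients are model choices:

| condition        | G0 (Hz/contrast) | β   | interpretation                       |
|------------------|------------------|-----|--------------------------------------|
| control_ell      | 60               | 0.4 | high-pass, whitening                 |
| np_inactivated   | 12               | 0.0 | all feedback blocked: gain down, flat|
| pet_inactivated  | 70               | 0.0 | indirect blocked: low-f gain up, flat|
| stellate         | 60               | 0.0 | direct-projecting, broadband         |
| multipolar       | 60               | 0.4 | indirect-projecting, whitened        |

Baseline rate is 30 Hz and AM sensitivity 2 Hz per unit AM amplitude for
all presets; `G0` and `r0` keep the rectifier inactive (minimum rate well
above zero) so the measured gain is not biased by clipping.  Population
heterogeneity is modeled as a log-normal multiplier on `G0` (σ = 0.2) per
unit, shared across paired conditions within a unit; β is fixed per
condition, which is what "a β = 0.4 population" means here.

## Gain estimation

Spike times (from simulation, or from voltage traces via a 100 Hz 8th-order
Butterworth high-pass and upward threshold crossings with linear
interpolation) are folded at the envelope frequency over complete cycles
into a 32-bin cycle histogram.  Data before the first complete cycle are
discarded to avoid onset transients.  Thirty-two bins oversample the
fundamental 16-fold; the histogram's mean rate equals the mean firing rate
over the analyzed span exactly.

The sinewave fit `offset + A·sin(2πφ + θ)` is computed as the histogram's
fundamental Fourier component, which for uniformly spaced bins *is* the
least-squares solution — deterministic, with no optimizer failure modes.
`A ≥ 0` is enforced by the phase convention.  Gain is `A` divided by the
envelope amplitude in contrast units (the sinusoidal depth).  Binning
attenuates the fundamental by `sinc(π/32) ≈ 0.9984`, two orders of
magnitude below the estimator's statistical error, and is left uncorrected.

Continuous firing-rate traces are the spike delta train (each spike
contributing unit area at its nearest sample) low-pass filtered with a
2nd-order Butterworth at the envelope-frequency-matched cutoffs 0.2, 0.35,
0.75, 1.5, 2.5 and 3.5 Hz for 0.05, 0.1, 0.2, 0.5, 0.75 and 1 Hz.  The two
gain routes (cycle histogram vs filtered-rate fundamental, after dividing
out the known filter attenuation) agree within a few percent; the test
suite enforces 10%.

The spike-triggered average is the mean stimulus over a 2 s window centered
on each spike; spikes whose window overruns the trace are skipped, not
zero-padded, keeping the mean unbiased.

## Response power, whitening index, sensitivity

Predicted response power is `gain(f)² · f^α` with the natural stimulus
power normalized to 1 at 1 Hz (the whitening index is scale-invariant, so
the constant is cosmetic).  The whitening index is the trapezoidal area
under the response-power curve divided by the trapezoidal area of the
constant-maximum curve over the same frequency range, evaluated on the
measured envelope frequencies only (no interpolation); it lies in (0, 1]
and equals 1 exactly iff the power vector is constant.  Both areas are
computed with the same trapezoid call so the flat case is exact in floating
point.  Sensitivity change is `100·(G_after − G_before)/G_before`.

Power-law tuning fits are ordinary least squares of `log10(gain)` on
`log10(f)`, unweighted, on all frequencies with positive gain (zero gains
are excluded with a warning rather than floored, since flooring injects an
arbitrary constant into the slope).

**Whitening index in the population pipeline.**  The max-normalized
trapezoid index is biased downward by per-frequency estimator noise: the
expected maximum of six noisy points exceeds the true maximum, so even a
perfectly whitened unit scores below 1 by roughly the noise amplitude
(e.g. ~0.89 at 5% gain error).  `run_experiment` therefore evaluates each
unit's index from its power-law-fitted tuning curve (the same fit plotted
as dashed lines through every tuning curve) evaluated at the six measured
frequencies; raw per-frequency response powers are tabulated alongside.
The standalone `white_index`/`predict_response_power` operations work on
raw values.

## Trial durations (power analysis)

Recording length per envelope frequency is
`min(max(800 s, 160 cycles/f), 3200 s)` — 3200, 1600, 800, 800, 800, 800 s
for the six frequencies.  The cycle-histogram amplitude estimator has
variance ≈ `2·r̄/T`, so the per-unit tuning-exponent standard error under
the default presets is ≈ 0.013, giving an expected fitted-curve whitening
index ≈ 0.97 for a β = 0.4 population (the index penalty is ≈ 0.8·|2Δβ|
and has a heavy left tail, which is why the durations are sized
generously).  Shorter records — e.g. 20 cycles — leave enough exponent
noise that even a perfectly whitening population scores ≈ 0.94 on average.
These durations are longer than typical in-vivo protocols; they are chosen
so that estimator noise, not the biology being modeled, never dominates the
whitening statistics.

## Behavior

The EOD is synthesized as `sin(2π φ(t))` with phase-continuous
instantaneous frequency
`f(t) = f_EOD + Gb·f_env^{β_b}·(E(t) − 1)`, defaults `f_EOD = 800 Hz`,
`Gb = 10 Hz/contrast`, `β_b = −0.5` (low-pass behavioral tracking, EOD
frequency excursions of a few Hz).  The model is deterministic given the
stimulus: it contains no EOD baseline drift or jitter.

Extraction follows the zero-crossing method: upward zero crossings (linear
interpolation) become a delta sequence — each crossing spread over its two
neighboring samples to preserve sub-sample timing and unit area, so a
constant-frequency EOD returns exactly its frequency — low-pass filtered
with a 2nd-order Butterworth at 0.05 Hz, zero-phase.  Reflection (`even`)
padding is essential here: default odd padding negates the delta train at
the boundaries and rings for tens of seconds.

The 0.05 Hz cutoff sits at or below every envelope frequency in the test
set and attenuates the tracked modulation by the forward-backward factor
`1/(1 + (f_env/0.05)^4)` — a factor of 1.6×10⁵ at 1 Hz.  Because the
extraction is numerically clean (amplitude noise floor below 10⁻⁸ Hz after
edge trimming), dividing this known gain out recovers programmed behavioral
gains across the whole band; `behavioral_gain` does so by default, with
`correct_filter_gain=False` available for strict replication of the
uncorrected convention (relative pre/post comparisons are unaffected by the
choice).  Gains are measured by cycle-averaging the EOD-frequency trace and
sinewave-fitting, after trimming three filter time constants (60 s) at each
end of the trace — the edge transient, though fast-decaying, is enormous
relative to the attenuated modulation that the correction rescales.

## Statistics

Paired contrasts use the Wilcoxon signed-rank test: zero differences are
dropped; for n ≤ 25 the two-sided p comes from the exact tie-aware null
distribution of `W+` (dynamic-programming enumeration over sign assignments
of the midranks); above that, a normal approximation with continuity and
tie corrections.  Unpaired contrasts use the Kruskal-Wallis H test (scipy,
average ranks, tie correction, χ² p-value).  Raw p-values at the 0.05
level are reported by default, matching the convention of reporting each
comparison uncorrected; a Holm step-down option exists.  Dispersion is
reported as mean ± SEM.

The paired design shares the stimulus seed across conditions within a unit
while spiking seeds differ, mirroring within-cell pre/post drug recordings;
unpaired condition groups get independent stimulus seeds.  All seeds derive
deterministically from the experiment's base seed via `SeedSequence`
spawning, so identical configurations reproduce byte-identical output
files.

## What the synthetic tests do and do not show

The generator reproduces the statistical structure the analysis assumes:
band-limited AM, 20% sinusoidal or `f^−0.8` natural envelopes, power-law
envelope gain per condition, Poisson spiking, power-law behavioral
tracking.  Passing tests therefore demonstrate that the estimators recover
programmed parameters without bias at the stated precision, and that the
condition contrasts come out in the right direction with the right
statistics — i.e. the pipeline is correct.  They do not validate the
biology: real pyramidal cells are non-Poisson (often more regular, with
bursts), have ON/OFF types (pooled here under a single positive-gain
convention), adapt over trials, and sit in correlated networks; real
behavioral responses drift and have trial-to-trial variability the EOD
model lacks.  Absolute gain coefficients in the presets are model choices,
not measurements.

## Known limitations

- No biophysical (conductance-based, SK-channel) mechanisms; the power-law
  gain is imposed, not emergent.
- No social (3-fish) envelopes, spatial receptive fields, or EOD carrier
  harmonics.
- Response power is predicted from the tuning curve, not estimated from
  spike-train spectra.
- The depth readout and gain estimators assume the sinusoidal envelope
  frequency is known (as it is for delivered stimuli).
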