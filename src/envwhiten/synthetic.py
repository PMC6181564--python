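"""Synthetic stimuli, spiking neurons, and electric-organ-discharge behavior.

Electrosensory envelope experiments drive neurons with a band-limited noise
amplitude modulation (AM, the "beat") whose amplitude is itself modulated by a
slow envelope.  This module builds those stimuli in dimensionless contrast
units (baseline amplitude = 1), simulates spiking units whose envelope gain
follows a power law G(f) = G0 * f**beta, and synthesizes EOD signals whose
instantaneous frequency tracks the envelope with a power-law behavioral gain.
Everything is seeded and reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as sps

__all__ = [
    "SINUSOIDAL_ENVELOPE_FREQUENCIES",
    "StimulusSpec",
    "StimulusSet",
    "NeuronSpec",
    "BehaviorSpec",
    "generate_am_noise",
    "apply_envelope",
    "generate_natural_envelope",
    "make_stimulus",
    "simulate_neuron",
    "programmed_rate",
    "simulate_behavior",
    "programmed_eod_frequency",
    "condition_preset",
    "default_trial_duration",
    "measure_modulation_depth",
    "CONDITION_LABELS",
]

#: Envelope frequencies used throughout (Hz).
SINUSOIDAL_ENVELOPE_FREQUENCIES = (0.05, 0.1, 0.2, 0.5, 0.75, 1.0)

CONDITION_LABELS = (
    "control_ell",
    "np_inactivated",
    "pet_inactivated",
    "stellate",
    "multipolar",
    "custom",
)


def default_trial_duration(envelope_frequency: float,
                           cycles: int = 160,
                           min_duration: float = 800.0,
                           max_duration: float = 3200.0) -> float:
    """Trial length (s) giving stable cycle averages at one envelope frequency.

    Chosen from a variance analysis of the cycle-histogram amplitude
    estimator (see docs/methods.md): the slowest envelope gets the cap,
    fast envelopes get at least ``min_duration`` seconds.
    """
    return float(min(max(min_duration, cycles / envelope_frequency), max_duration))


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one noisy-AM stimulus with a slow envelope.

    Amplitudes are dimensionless contrast units with baseline 1; the
    ``modulation_depth`` is the envelope excursion as a fraction of baseline
    (sinusoidal: sine amplitude; natural: RMS contrast).
    """

    duration: float
    sample_rate: float
    am_band_low: float = 5.0
    am_band_high: float = 15.0
    am_filter_order: int = 4
    envelope_kind: str = "sinusoidal"  # sinusoidal | natural | constant
    envelope_frequency: float = 0.1
    modulation_depth: float = 0.20
    natural_exponent: float = -0.8
    natural_band: tuple = (0.05, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 2.0 * self.am_band_high:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz too low: must exceed twice "
                f"the AM band upper edge ({self.am_band_high} Hz)")
        if not 0.0 <= self.modulation_depth < 1.0:
            raise ValueError("modulation_depth must be in [0, 1): the envelope "
                             "must stay positive")
        if self.envelope_kind not in ("sinusoidal", "natural", "constant"):
            raise ValueError(f"unknown envelope_kind {self.envelope_kind!r}")
        if self.envelope_kind == "sinusoidal":
            if self.envelope_frequency <= 0:
                raise ValueError("envelope_frequency must be positive")
            if self.duration * self.envelope_frequency < 2.0:
                raise ValueError("duration must cover at least 2 envelope cycles")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class StimulusSet:
    """A sampled stimulus: modulated AM waveform plus its envelope."""

    time: np.ndarray
    am: np.ndarray
    envelope: np.ndarray
    spec: StimulusSpec

    def __post_init__(self):
        if not (len(self.time) == len(self.am) == len(self.envelope)):
            raise ValueError("time, am and envelope must have equal length")
        if np.min(self.envelope) <= 0:
            raise ValueError("envelope must be positive everywhere")
        if abs(float(np.mean(self.envelope)) - 1.0) > 0.02:
            raise ValueError("envelope mean must be within 2% of 1")

    @property
    def sample_rate(self) -> float:
        return self.spec.sample_rate

    @property
    def envelope_amplitude(self) -> float:
        """Envelope modulation amplitude in contrast units.

        Sinusoidal envelopes: the programmed sine amplitude (= depth).
        Natural/constant envelopes: RMS of the envelope deviation.
        """
        if self.spec.envelope_kind == "sinusoidal":
            return self.spec.modulation_depth
        dev = self.envelope - 1.0
        return float(np.sqrt(np.mean(dev * dev)))


def generate_am_noise(spec: StimulusSpec) -> np.ndarray:
    """Band-limited Gaussian AM carrier, zero mean, unit RMS.

    White Gaussian noise band-pass filtered with a 4th-order (analog
    prototype) Butterworth response applied forward-backward, so the carrier
    is zero-phase and its band edges match the design band.
    """
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(spec.n_samples)
    sos = sps.butter(spec.am_filter_order,
                     [spec.am_band_low, spec.am_band_high],
                     btype="bandpass", fs=spec.sample_rate, output="sos")
    am = sps.sosfiltfilt(sos, white)
    am = am - np.mean(am)
    rms = np.sqrt(np.mean(am * am))
    if rms == 0:
        raise ValueError("degenerate carrier: zero RMS after filtering")
    return am / rms


def _sinusoidal_envelope(spec: StimulusSpec) -> np.ndarray:
    t = spec.time
    return 1.0 + spec.modulation_depth * np.sin(
        2.0 * np.pi * spec.envelope_frequency * t)


def generate_natural_envelope(spec: StimulusSpec) -> np.ndarray:
    """Envelope with a power-law spectrum over the natural band.

    White Gaussian noise is shaped in the frequency domain so its one-sided
    power spectrum follows f**alpha over ``natural_band`` (zero outside),
    then offset to mean 1 and scaled so the RMS contrast equals
    ``modulation_depth``.  Depths that would force the envelope negative are
    rejected rather than clipped, because clipping distorts the spectrum.
    """
    if spec.envelope_kind != "natural":
        raise ValueError("spec.envelope_kind must be 'natural'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate)
    lo, hi = spec.natural_band
    band = (freqs >= lo) & (freqs <= hi)
    if band.sum() < 4:
        raise ValueError("duration/sample_rate give too few spectral bins in "
                         "the natural band; lengthen the stimulus")
    shape = np.zeros_like(freqs)
    # power ~ f**alpha  ->  amplitude ~ f**(alpha/2)
    shape[band] = freqs[band] ** (spec.natural_exponent / 2.0)
    spectrum = shape * (rng.standard_normal(freqs.size)
                        + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spectrum, n=n)
    x = x - np.mean(x)
    std = np.std(x)
    if std == 0:
        raise ValueError("degenerate natural envelope: zero variance")
    env = 1.0 + spec.modulation_depth * (x / std)
    if np.min(env) <= 0:
        raise ValueError(
            f"modulation_depth {spec.modulation_depth} forces the natural "
            "envelope negative for this seed; reduce the depth")
    return env


def apply_envelope(am: np.ndarray, spec: StimulusSpec) -> StimulusSet:
    """Multiply the AM carrier by the envelope defined by ``spec``."""
    am = np.asarray(am, dtype=float)
    if len(am) != spec.n_samples:
        raise ValueError("am waveform length does not match spec")
    if spec.envelope_kind == "sinusoidal":
        if spec.modulation_depth >= 1.0:
            raise ValueError("modulation_depth >= 1 gives a negative envelope")
        env = _sinusoidal_envelope(spec)
    elif spec.envelope_kind == "natural":
        env = generate_natural_envelope(spec)
    else:
        env = np.ones_like(am)
    return StimulusSet(time=spec.time, am=am * env, envelope=env, spec=spec)


def make_stimulus(spec: StimulusSpec) -> StimulusSet:
    """Convenience: carrier generation plus envelope application."""
    if spec.envelope_kind == "sinusoidal":
        n_cycles = spec.duration * spec.envelope_frequency
        if n_cycles < 10:
            warnings.warn(
                f"only {n_cycles:.1f} envelope cycles at "
                f"{spec.envelope_frequency} Hz; cycle averages may be noisy",
                stacklevel=2)
    return apply_envelope(generate_am_noise(spec), spec)


# ---------------------------------------------------------------------------
# spiking neuron model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronSpec:
    """Rate-model neuron with power-law envelope tuning G(f) = G0 * f**beta.

    ``gain_coefficient`` (G0) is in Hz per unit envelope contrast;
    ``am_sensitivity`` couples the fast AM waveform into the rate and sets
    the spike-triggered-average magnitude.  The rate is rectified at zero and
    spikes are drawn as an inhomogeneous Poisson process by thinning.
    """

    baseline_rate: float = 30.0
    gain_coefficient: float = 60.0
    gain_exponent: float = 0.4
    response_phase: float = 0.0
    am_sensitivity: float = 2.0
    refractory: float = 0.0
    seed: int = 0
    condition_label: str = "custom"

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.gain_coefficient < 0:
            raise ValueError("gain_coefficient must be >= 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")

    def gain_at(self, envelope_frequency) -> np.ndarray:
        """Programmed envelope gain G0 * f**beta (Hz per unit contrast)."""
        f = np.asarray(envelope_frequency, dtype=float)
        return self.gain_coefficient * f ** self.gain_exponent


_PRESETS = {
    # condition label -> (G0 [Hz/contrast], beta)
    "control_ell": (60.0, 0.4),
    "np_inactivated": (12.0, 0.0),   # complete feedback block: gain scaled down, flat
    "pet_inactivated": (70.0, 0.0),  # indirect block: low-frequency gain scaled up, flat
    "stellate": (60.0, 0.0),
    "multipolar": (60.0, 0.4),
}


def condition_preset(label: str, **overrides) -> NeuronSpec:
    """NeuronSpec for one experimental condition.

    ``control_ell``/``multipolar`` are high-pass (beta = 0.4);
    ``np_inactivated``/``pet_inactivated``/``stellate`` are flat (beta = 0),
    with G0 scaled down (np) or up (pet) relative to control.  ``custom``
    passes the overrides through unchanged.
    """
    if label not in CONDITION_LABELS:
        raise ValueError(f"unknown condition label {label!r}; "
                         f"expected one of {CONDITION_LABELS}")
    if label == "custom":
        return NeuronSpec(condition_label="custom", **overrides)
    g0, beta = _PRESETS[label]
    spec = NeuronSpec(gain_coefficient=g0, gain_exponent=beta,
                      condition_label=label)
    return replace(spec, **overrides) if overrides else spec


def _envelope_drive(stim: StimulusSet, gain_coefficient: float,
                    gain_exponent: float, phase: float) -> np.ndarray:
    """Rate deviation driven by the envelope through the power-law gain.

    For a sinusoidal envelope this is exactly
    G0 * f_env**beta * depth * sin(2*pi*f_env*t + phase); for natural
    envelopes the deviation is filtered in the frequency domain by the
    transfer function G0 * f**beta * exp(i*phase).
    """
    spec = stim.spec
    if spec.envelope_kind == "sinusoidal":
        amp = gain_coefficient * spec.envelope_frequency ** gain_exponent
        return amp * spec.modulation_depth * np.sin(
            2.0 * np.pi * spec.envelope_frequency * stim.time + phase)
    if spec.envelope_kind == "constant":
        return np.zeros_like(stim.time)
    dev = stim.envelope - 1.0
    n = len(dev)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate)
    transfer = np.zeros(freqs.size, dtype=complex)
    nz = freqs > 0
    transfer[nz] = gain_coefficient * freqs[nz] ** gain_exponent * np.exp(1j * phase)
    return np.fft.irfft(np.fft.rfft(dev) * transfer, n=n)


def programmed_rate(stim: StimulusSet, neuron: NeuronSpec) -> np.ndarray:
    """Instantaneous firing rate r(t) >= 0 of the rate model (Hz)."""
    rate = (neuron.baseline_rate
            + _envelope_drive(stim, neuron.gain_coefficient,
                              neuron.gain_exponent, neuron.response_phase)
            + neuron.am_sensitivity * stim.am)
    return np.maximum(rate, 0.0)


def simulate_neuron(stim: StimulusSet, neuron: NeuronSpec):
    """Draw spikes from the rate model by Poisson thinning.

    Returns a :class:`envwhiten.spikes.SpikeTrain`.  The stimulus sampling
    step doubles as the thinning resolution and must be <= 0.5 ms; rates
    approaching 1/dt invalidate the point-process approximation and are
    rejected.
    """
    from .spikes import SpikeTrain  # local import to avoid a cycle

    dt = 1.0 / stim.sample_rate
    if dt > 5.0e-4 + 1e-12:
        raise ValueError("stimulus sample rate must be >= 2 kHz so the "
                         "thinning step is <= 0.5 ms")
    rate = programmed_rate(stim, neuron)
    rmax = float(np.max(rate))
    if rmax >= 0.8 / dt:
        raise ValueError(
            f"peak rate {rmax:.0f} Hz approaches 1/dt = {1.0 / dt:.0f} Hz; "
            "the Poisson thinning model is invalid at this rate")
    rng = np.random.default_rng(neuron.seed)
    duration = stim.spec.duration
    if rmax == 0:
        return SpikeTrain(times=np.empty(0), duration=duration)
    n_cand = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    idx = np.minimum((cand * stim.sample_rate).astype(np.intp), len(rate) - 1)
    keep = rng.uniform(0.0, 1.0, size=n_cand) < rate[idx] / rmax
    times = cand[keep]
    if neuron.refractory > 0 and len(times) > 1:
        kept = [times[0]]
        last = times[0]
        for t in times[1:]:
            if t - last >= neuron.refractory:
                kept.append(t)
                last = t
        times = np.asarray(kept)
    return SpikeTrain(times=times, duration=duration)


# ---------------------------------------------------------------------------
# behavioral EOD model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorSpec:
    """EOD whose frequency tracks the envelope with power-law gain.

    ``behavior_gain_coefficient`` (Gb, Hz per unit contrast) and
    ``behavior_gain_exponent`` (negative for the low-pass behavior seen in
    envelope tracking) set the frequency-modulation amplitude
    Gb * f_env**beta_b * depth around ``eod_base_frequency``.
    """

    eod_base_frequency: float = 800.0
    behavior_gain_coefficient: float = 10.0
    behavior_gain_exponent: float = -0.5
    seed: int = 0

    def __post_init__(self):
        if self.eod_base_frequency <= 0:
            raise ValueError("eod_base_frequency must be positive")


def programmed_eod_frequency(stim: StimulusSet, spec: BehaviorSpec) -> np.ndarray:
    """Instantaneous EOD frequency f(t) programmed by the behavior model."""
    return spec.eod_base_frequency + _envelope_drive(
        stim, spec.behavior_gain_coefficient, spec.behavior_gain_exponent, 0.0)


def simulate_behavior(stim: StimulusSet, spec: BehaviorSpec) -> np.ndarray:
    """Phase-continuous EOD signal sin(2*pi*phi(t)) tracking the envelope."""
    f_t = programmed_eod_frequency(stim, spec)
    fmax = float(np.max(f_t))
    if stim.sample_rate <= 2.0 * fmax:
        raise ValueError(
            f"stimulus sample rate {stim.sample_rate} Hz cannot represent an "
            f"EOD reaching {fmax:.1f} Hz; need > {2.0 * fmax:.0f} Hz")
    if np.min(f_t) <= 0:
        raise ValueError("programmed EOD frequency goes non-positive")
    dt = 1.0 / stim.sample_rate
    phase = np.cumsum(f_t) * dt
    return np.sin(2.0 * np.pi * phase)


# ---------------------------------------------------------------------------
# stimulus readout
# ---------------------------------------------------------------------------

def measure_modulation_depth(stim: StimulusSet,
                             smoothing_cutoff: float = 0.5,
                             edge_trim: float = 2.0) -> float:
    """Measured envelope modulation depth of a sinusoidal-envelope stimulus,
    as a percentage of the baseline amplitude.

    The slow envelope is read out from the magnitude of the analytic signal
    of the modulated waveform, low-pass smoothed (2nd-order Butterworth,
    zero-phase) to suppress carrier-magnitude fluctuations, then detected
    synchronously (lock-in) at the delivered envelope frequency and phase
    over complete cycles.  The known smoothing-filter gain at the envelope
    frequency is divided out.  The carrier magnitude of band-limited noise
    fluctuates within the detection band, so a single realization carries a
    few percentage points of stochastic error; average over independent
    carrier seeds for a population estimate.
    """
    spec = stim.spec
    if spec.envelope_kind != "sinusoidal":
        raise ValueError("depth readout is defined for sinusoidal envelopes")
    f_env = spec.envelope_frequency
    if not f_env < smoothing_cutoff < spec.am_band_low:
        raise ValueError("smoothing_cutoff must lie between the envelope "
                         "frequency and the AM band")
    mag = np.abs(sps.hilbert(stim.am))
    sos = sps.butter(2, smoothing_cutoff, btype="lowpass",
                     fs=spec.sample_rate, output="sos")
    smooth = sps.sosfiltfilt(sos, mag)
    fs = spec.sample_rate
    i0 = int(round(edge_trim * fs))
    n_cycles = int(np.floor((spec.duration - 2.0 * edge_trim) * f_env))
    if n_cycles < 2:
        raise ValueError("need at least 2 complete envelope cycles after trimming")
    i1 = i0 + int(round(n_cycles / f_env * fs))
    seg = smooth[i0:i1]
    t_abs = np.arange(i0, i1) / fs  # reference phase is that of the delivered envelope
    amp = 2.0 * np.mean(seg * np.sin(2 * np.pi * f_env * t_abs))
    # forward-backward 2nd-order Butterworth: |H|^2 = 1 / (1 + (f/fc)^4)
    filter_gain = 1.0 / (1.0 + (f_env / smoothing_cutoff) ** 4)
    return 100.0 * (amp / filter_gain) / float(np.mean(seg))
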