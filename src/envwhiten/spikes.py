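"""Spike detection, cycle histograms, filtered firing rates, and STAs.

The envelope response of a unit is quantified by folding its spike train at
the envelope frequency (cycle histogram), fitting a sinewave to the folded
rate, and dividing the fitted modulation amplitude by the envelope amplitude
(gain, done in :mod:`envwhiten.tuning`).  Continuous firing-rate traces are
obtained by low-pass filtering a spike delta train with an
envelope-frequency-dependent cutoff, and AM sensitivity is measured with a
spike-triggered average over a 2 s window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "SpikeTrain",
    "CycleHistogram",
    "SinewaveFit",
    "StaResult",
    "detect_spikes",
    "cycle_histogram",
    "fit_sinewave",
    "fit_sinewave_values",
    "filtered_rate",
    "cutoff_for_envelope_frequency",
    "compute_sta",
    "sta_percent_of_control",
    "RATE_FILTER_CUTOFFS",
]

#: Low-pass cutoff (Hz) of the firing-rate filter per envelope frequency (Hz).
RATE_FILTER_CUTOFFS = {
    0.05: 0.2,
    0.1: 0.35,
    0.2: 0.75,
    0.5: 1.5,
    0.75: 2.5,
    1.0: 3.5,
}


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) within a recording of known duration (s)."""

    times: np.ndarray
    duration: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if times.size:
            if times[0] < 0 or times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.duration


@dataclass(frozen=True)
class CycleHistogram:
    """Firing rate (Hz) versus envelope phase, averaged over complete cycles."""

    bin_centers: np.ndarray   # phase in [0, 1) cycles
    rate: np.ndarray          # Hz
    n_cycles: int
    envelope_frequency: float

    def __post_init__(self):
        if np.any(np.asarray(self.rate) < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.rate)


@dataclass(frozen=True)
class SinewaveFit:
    """Least-squares sinewave rate(phi) = offset + amplitude*sin(2*pi*phi + phase)."""

    amplitude: float
    phase: float
    offset: float
    residual_rms: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0 (phase carries the sign)")


@dataclass(frozen=True)
class StaResult:
    """Spike-triggered average stimulus over symmetric lags."""

    lags: np.ndarray            # seconds, symmetric about 0
    mean_stimulus: np.ndarray   # contrast units
    peak_to_peak: float
    n_spikes_used: int = 0


def detect_spikes(voltage: np.ndarray, sample_rate: float,
                  threshold: float) -> SpikeTrain:
    """Threshold-crossing spike times from a voltage trace.

    The trace is high-pass filtered (100 Hz, 8th-order Butterworth,
    zero-phase) and spike times are the upward threshold crossings, linearly
    interpolated between samples.
    """
    v = np.asarray(voltage, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage trace contains non-finite samples")
    if sample_rate <= 200.0:
        raise ValueError("sample rate too low for a 100 Hz high-pass")
    sos = sps.butter(8, 100.0, btype="highpass", fs=sample_rate, output="sos")
    f = sps.sosfiltfilt(sos, v)
    if np.min(f) > threshold:
        raise ValueError("filtered signal is always above threshold; "
                         "no upward crossings exist")
    below = f[:-1] < threshold
    above = f[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    frac = (threshold - f[idx]) / (f[idx + 1] - f[idx])
    times = (idx + frac) / sample_rate
    duration = len(v) / sample_rate
    times = times[times < duration]
    return SpikeTrain(times=times, duration=duration)


def cycle_histogram(spikes: SpikeTrain, envelope_frequency: float,
                    n_bins: int = 32, t_start: float = 0.0) -> CycleHistogram:
    """Fold spikes at the envelope frequency over complete cycles.

    Spikes before ``t_start`` (e.g. an onset transient) are discarded; only
    complete envelope cycles after it are analyzed.  Bin rates are
    count / (n_cycles * bin width in seconds), so the histogram mean equals
    the mean firing rate over the analyzed span.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    if envelope_frequency <= 0:
        raise ValueError("envelope_frequency must be positive")
    span = spikes.duration - t_start
    n_cycles = int(np.floor(span * envelope_frequency))
    if n_cycles < 2:
        raise ValueError(
            f"only {max(n_cycles, 0)} complete cycles after t_start; need >= 2")
    t_end = t_start + n_cycles / envelope_frequency
    t = spikes.times
    sel = t[(t >= t_start) & (t < t_end)]
    phase = np.mod((sel - t_start) * envelope_frequency, 1.0)
    counts, _ = np.histogram(phase, bins=n_bins, range=(0.0, 1.0))
    bin_width_s = 1.0 / (envelope_frequency * n_bins)
    rate = counts / (n_cycles * bin_width_s)
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return CycleHistogram(bin_centers=centers, rate=rate,
                          n_cycles=n_cycles,
                          envelope_frequency=envelope_frequency)


def fit_sinewave_values(phase_cycles: np.ndarray,
                        values: np.ndarray) -> SinewaveFit:
    """Fundamental sinewave fit to values sampled at phases in cycles.

    For uniformly spaced phases the Fourier projection below is exactly the
    least-squares solution of offset + A*sin(2*pi*phi + theta).
    """
    phi = np.asarray(phase_cycles, dtype=float)
    y = np.asarray(values, dtype=float)
    a = 2.0 * np.mean(y * np.sin(2.0 * np.pi * phi))
    b = 2.0 * np.mean(y * np.cos(2.0 * np.pi * phi))
    amplitude = float(np.hypot(a, b))
    phase = float(np.arctan2(b, a))
    offset = float(np.mean(y))
    model = offset + amplitude * np.sin(2.0 * np.pi * phi + phase)
    residual_rms = float(np.sqrt(np.mean((y - model) ** 2)))
    return SinewaveFit(amplitude=amplitude, phase=phase, offset=offset,
                       residual_rms=residual_rms)


def fit_sinewave(hist: CycleHistogram) -> SinewaveFit:
    """Sinewave fit to a cycle histogram (fundamental Fourier component)."""
    return fit_sinewave_values(hist.bin_centers, hist.rate)


def cutoff_for_envelope_frequency(envelope_frequency: float,
                                  strict: bool = False) -> float:
    """Rate-filter cutoff for one envelope frequency.

    Unlisted frequencies map to the nearest tabulated one with a warning,
    or are rejected in strict mode.
    """
    table = np.array(sorted(RATE_FILTER_CUTOFFS))
    if envelope_frequency in RATE_FILTER_CUTOFFS:
        return RATE_FILTER_CUTOFFS[envelope_frequency]
    if strict:
        raise ValueError(f"envelope frequency {envelope_frequency} Hz has no "
                         "tabulated rate-filter cutoff")
    nearest = float(table[np.argmin(np.abs(table - envelope_frequency))])
    warnings.warn(
        f"envelope frequency {envelope_frequency} Hz not tabulated; using the "
        f"cutoff for {nearest} Hz", stacklevel=2)
    return RATE_FILTER_CUTOFFS[nearest]


def _delta_train(spikes: SpikeTrain, sample_rate: float) -> np.ndarray:
    """Binary spike sequence scaled to unit area per spike (values in Hz)."""
    n = int(round(spikes.duration * sample_rate))
    delta = np.zeros(n)
    idx = np.minimum(np.round(spikes.times * sample_rate).astype(np.intp), n - 1)
    np.add.at(delta, idx, sample_rate)
    return delta


def filtered_rate(spikes: SpikeTrain, sample_rate: float,
                  envelope_frequency: float, strict: bool = False) -> np.ndarray:
    """Continuous firing-rate trace (Hz) sampled at ``sample_rate``.

    The spike delta train is low-pass filtered (2nd-order Butterworth,
    zero-phase) at a cutoff matched to the envelope frequency.
    """
    cutoff = cutoff_for_envelope_frequency(envelope_frequency, strict=strict)
    delta = _delta_train(spikes, sample_rate)
    sos = sps.butter(2, cutoff, btype="lowpass", fs=sample_rate, output="sos")
    padlen = min(len(delta) - 1, int(round(2.0 * sample_rate / cutoff)))
    return sps.sosfiltfilt(sos, delta, padlen=padlen)


def compute_sta(am: np.ndarray, sample_rate: float, spikes: SpikeTrain,
                window: float = 2.0) -> StaResult:
    """Spike-triggered average of the stimulus over a symmetric window.

    Stimulus segments of length ``window`` centered on each spike are
    averaged; spikes whose window overruns the trace are skipped rather than
    zero-padded, keeping the mean unbiased.
    """
    am = np.asarray(am, dtype=float)
    half = int(round(0.5 * window * sample_rate))
    n = len(am)
    idx = np.round(spikes.times * sample_rate).astype(np.intp)
    idx = idx[(idx >= half) & (idx < n - half)]
    if idx.size == 0:
        raise ValueError("no spikes with a complete STA window inside the trace")
    if idx.size < 50:
        warnings.warn(f"only {idx.size} usable spikes; STA will be noisy",
                      stacklevel=2)
    offsets = np.arange(-half, half + 1)
    acc = np.zeros(offsets.size)
    for start in range(0, idx.size, 256):  # chunked gather bounds memory
        chunk = idx[start:start + 256]
        acc += am[chunk[:, None] + offsets[None, :]].sum(axis=0)
    mean_stim = acc / idx.size
    lags = offsets / sample_rate
    return StaResult(lags=lags, mean_stimulus=mean_stim,
                     peak_to_peak=float(np.max(mean_stim) - np.min(mean_stim)),
                     n_spikes_used=int(idx.size))


def sta_percent_of_control(sta_drug: StaResult,
                           sta_control: StaResult) -> float:
    """STA peak-to-peak after a manipulation, as % of the control STA."""
    if sta_control.peak_to_peak <= 0:
        raise ValueError("control STA peak-to-peak must be positive")
    return 100.0 * sta_drug.peak_to_peak / sta_control.peak_to_peak
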