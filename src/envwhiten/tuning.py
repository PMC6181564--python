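"""Tuning curves, power-law fits, response-power prediction, whitening index.

A unit's envelope tuning curve is its gain (firing-rate modulation amplitude
divided by envelope amplitude) at each envelope frequency.  Natural movement
envelopes have spectral power decaying as f**alpha with alpha = -0.8, so a
neuron whose gain grows as f**0.4 produces response power
gain(f)**2 * f**alpha that is independent of frequency — temporal whitening.
The whitening index is the trapezoidal area under the response-power curve
divided by the area of the constant-maximum curve; 1 means fully whitened.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NATURAL_STIMULUS_EXPONENT",
    "TuningCurve",
    "PowerLawFit",
    "WhiteningResult",
    "compute_gain",
    "fit_power_law",
    "power_law_gains",
    "predict_response_power",
    "white_index",
    "sensitivity_change",
]

#: Spectral slope of natural movement envelopes (power ~ f**alpha).
NATURAL_STIMULUS_EXPONENT = -0.8


@dataclass(frozen=True)
class TuningCurve:
    """Envelope gain (Hz per unit contrast) per envelope frequency (Hz)."""

    frequencies: np.ndarray
    gains: np.ndarray
    unit_id: str = ""
    condition: str = ""

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        g = np.asarray(self.gains, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "gains", g)
        if f.shape != g.shape:
            raise ValueError("frequencies and gains must have equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly ascending")
        if np.any(g < 0):
            raise ValueError("gains must be non-negative")


@dataclass(frozen=True)
class PowerLawFit:
    """gain(f) = 10**log10_coefficient * f**exponent, fit by OLS in log-log."""

    exponent: float
    log10_coefficient: float
    r_squared: float

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class WhiteningResult:
    """Predicted response power per frequency and its whitening index."""

    frequencies: np.ndarray
    response_power: np.ndarray
    white_index: float
    stimulus_exponent: float

    def __post_init__(self):
        if np.any(np.asarray(self.response_power) < 0):
            raise ValueError("response power must be non-negative")
        if not 0.0 <= self.white_index <= 1.0 + 1e-12:
            raise ValueError("white index must lie in [0, 1]")


def compute_gain(fit, envelope_amplitude: float) -> float:
    """Gain = firing-rate modulation amplitude / envelope amplitude.

    ``fit`` is a :class:`envwhiten.spikes.SinewaveFit` of the cycle
    histogram; ``envelope_amplitude`` is in contrast units (the sinusoidal
    modulation depth).
    """
    if envelope_amplitude <= 0:
        raise ValueError("envelope amplitude must be positive")
    return fit.amplitude / envelope_amplitude


def fit_power_law(curve: TuningCurve) -> PowerLawFit:
    """OLS fit of log10(gain) on log10(frequency).

    Zero gains carry no information about the slope in log space and are
    excluded with a warning; at least 3 positive points are required.
    """
    pos = curve.gains > 0
    if np.count_nonzero(pos) < 3:
        raise ValueError("need at least 3 positive-gain points for a power-law fit")
    if not np.all(pos):
        warnings.warn(f"excluding {np.count_nonzero(~pos)} zero-gain point(s) "
                      "from the power-law fit", stacklevel=2)
    x = np.log10(curve.frequencies[pos])
    y = np.log10(curve.gains[pos])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return PowerLawFit(exponent=float(slope),
                       log10_coefficient=float(intercept),
                       r_squared=float(min(max(r2, 0.0), 1.0)))


def power_law_gains(fit: PowerLawFit, frequencies) -> np.ndarray:
    """Evaluate a fitted power law at the given frequencies."""
    f = np.asarray(frequencies, dtype=float)
    return 10.0 ** fit.log10_coefficient * f ** fit.exponent


def predict_response_power(curve: TuningCurve,
                           stimulus_exponent: float = NATURAL_STIMULUS_EXPONENT
                           ) -> WhiteningResult:
    """Response power under natural envelope statistics.

    response_power(f) = gain(f)**2 * f**stimulus_exponent, with the natural
    stimulus power normalized to 1 at 1 Hz (the whitening index is
    scale-invariant, so the normalization is cosmetic).  The whitening index
    of the predicted powers is filled in for convenience.
    """
    f = curve.frequencies
    power = curve.gains ** 2 * f ** stimulus_exponent
    wi = white_index(f, power) if np.any(power > 0) else 0.0
    return WhiteningResult(frequencies=f, response_power=power,
                           white_index=wi,
                           stimulus_exponent=stimulus_exponent)


def white_index(frequencies, response_power) -> float:
    """Trapezoidal area under the power curve over the area at the maximum.

    Ranges over (0, 1]; equals 1 exactly for a constant (flat) power
    spectrum, i.e. complete whitening.
    """
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(response_power, dtype=float)
    if f.size < 2:
        raise ValueError("need at least 2 frequencies")
    if np.any(np.diff(f) <= 0):
        raise ValueError("frequencies must be strictly ascending")
    if np.any(p < 0):
        raise ValueError("response power must be non-negative")
    pmax = float(np.max(p))
    if pmax == 0:
        raise ValueError("response power is all zero")
    # same trapezoid for both areas so a constant vector gives exactly 1
    area = float(np.trapezoid(p, f))
    area_max = float(np.trapezoid(np.full_like(p, pmax), f))
    return area / area_max


def sensitivity_change(gain_drug: float, gain_control: float) -> float:
    """Percent change in gain after a manipulation: 100*(Gd - Gc)/Gc."""
    if gain_control <= 0:
        raise ValueError("control gain must be positive")
    return 100.0 * (gain_drug - gain_control) / gain_control
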