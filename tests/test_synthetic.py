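"""Synthetic stimulus, neuron, and behavior generators."""

import numpy as np
import pytest
from scipy import signal as sps

import envwhiten as ew
from envwhiten.synthetic import (default_trial_duration,
                                 generate_natural_envelope,
                                 programmed_eod_frequency)


def _spec(**kw):
    base = dict(duration=100.0, sample_rate=2000.0, envelope_frequency=0.1,
                seed=0)
    base.update(kw)
    return ew.StimulusSpec(**base)


class TestAmNoise:
    def test_band_limited_spectrum(self):
        am = ew.generate_am_noise(_spec(duration=200, seed=1))
        f, p = sps.welch(am, fs=2000.0, nperseg=2 ** 14)
        p_at = lambda ff: p[np.argmin(np.abs(f - ff))]
        assert p_at(1.0) < 0.01 * p_at(10.0)
        assert p_at(50.0) < 0.01 * p_at(10.0)

    def test_deterministic_and_normalized(self):
        a = ew.generate_am_noise(_spec(seed=42))
        b = ew.generate_am_noise(_spec(seed=42))
        c = ew.generate_am_noise(_spec(seed=43))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert abs(a.mean()) < 1e-10  # relative to unit RMS
        assert np.isclose(np.sqrt(np.mean(a ** 2)), 1.0)

    def test_rejects_low_sample_rate(self):
        with pytest.raises(ValueError, match="sample_rate"):
            _spec(sample_rate=25.0)


class TestSinusoidalEnvelope:
    def test_depth_readout_near_programmed(self):
        # population-average the lock-in readout: a single realization has a
        # few points of carrier-fluctuation noise at the envelope frequency
        depths = [ew.measure_modulation_depth(
            ew.make_stimulus(_spec(duration=400, envelope_frequency=0.05,
                                   seed=s)))
            for s in range(12)]
        assert abs(np.mean(depths) - 20.0) < 1.0

    def test_zero_depth_is_identity(self):
        spec = _spec(modulation_depth=0.0)
        am = ew.generate_am_noise(spec)
        stim = ew.apply_envelope(am, spec)
        assert np.all(stim.envelope == 1.0)
        assert np.array_equal(stim.am, am)

    def test_envelope_cycle_count(self):
        spec = _spec(duration=10.0, envelope_frequency=1.0)
        stim = ew.apply_envelope(ew.generate_am_noise(spec), spec)
        peaks, _ = sps.find_peaks(stim.envelope)
        assert len(peaks) == 10

    def test_rejects_depth_ge_one(self):
        with pytest.raises(ValueError, match="depth"):
            _spec(modulation_depth=1.0)


class TestNaturalEnvelope:
    @pytest.mark.parametrize("alpha", [-2.0, -0.8, 0.0])
    def test_spectral_slope_recovery(self, alpha):
        fs, dur = 50.0, 200.0
        psds = []
        for s in range(10):
            spec = ew.StimulusSpec(duration=dur, sample_rate=fs,
                                   envelope_kind="natural",
                                   natural_exponent=alpha, seed=100 + s)
            env = generate_natural_envelope(spec)
            f, p = sps.welch(env - 1.0, fs=fs, nperseg=2 ** 12)
            psds.append(p)
        p = np.mean(psds, axis=0)
        sel = (f >= 0.05) & (f <= 1.0)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
        assert abs(slope - alpha) < 0.1

    def test_positive_for_moderate_depth(self):
        for s in range(100):
            spec = ew.StimulusSpec(duration=200.0, sample_rate=50.0,
                                   envelope_kind="natural",
                                   modulation_depth=0.2, seed=s)
            assert generate_natural_envelope(spec).min() > 0

    def test_rejects_depth_forcing_negative_envelope(self):
        spec = ew.StimulusSpec(duration=200.0, sample_rate=50.0,
                               envelope_kind="natural",
                               modulation_depth=0.95, seed=0)
        with pytest.raises(ValueError, match="negative"):
            generate_natural_envelope(spec)


class TestSimulateNeuron:
    def test_homogeneous_poisson_count(self):
        stim = ew.make_stimulus(_spec(seed=5))
        neuron = ew.condition_preset("custom", baseline_rate=30.0,
                                     gain_coefficient=0.0,
                                     am_sensitivity=0.0, seed=7)
        st = ew.simulate_neuron(stim, neuron)
        assert abs(st.n_spikes - 3000) < 3 * np.sqrt(3000)

    def test_programmed_modulation_recovered(self):
        # rate modulation G0 * f**beta * depth = 10 * 1**0.4 * 0.2 = 2 Hz
        stim = ew.make_stimulus(_spec(duration=400, envelope_frequency=1.0,
                                      seed=3))
        neuron = ew.condition_preset("custom", baseline_rate=30.0,
                                     gain_coefficient=10.0, gain_exponent=0.4,
                                     am_sensitivity=0.0, seed=11)
        st = ew.simulate_neuron(stim, neuron)
        fit = ew.fit_sinewave(ew.cycle_histogram(st, 1.0, t_start=1.0))
        se = np.sqrt(2 * 30.0 / 399)
        assert abs(fit.amplitude - 2.0) < 3 * se

    def test_seed_changes_spikes_not_gain(self):
        stim = ew.make_stimulus(_spec(duration=800, envelope_frequency=1.0,
                                      seed=3))
        neuron = ew.condition_preset("custom", baseline_rate=30.0,
                                     gain_coefficient=20.0, gain_exponent=0.4,
                                     am_sensitivity=0.0)
        gains = []
        trains = []
        for seed in (1, 2):
            st = ew.simulate_neuron(stim,
                                    ew.condition_preset(
                                        "custom", baseline_rate=30.0,
                                        gain_coefficient=20.0,
                                        gain_exponent=0.4,
                                        am_sensitivity=0.0, seed=seed))
            trains.append(st.times)
            fit = ew.fit_sinewave(ew.cycle_histogram(st, 1.0, t_start=1.0))
            gains.append(ew.compute_gain(fit, 0.2))
        assert not np.array_equal(trains[0], trains[1])
        se_diff = np.sqrt(2.0) * np.sqrt(2 * 30.0 / 799) / 0.2
        assert abs(gains[0] - gains[1]) < 4 * se_diff

    def test_rejects_rate_near_thinning_limit(self):
        stim = ew.make_stimulus(_spec(seed=5))
        neuron = ew.condition_preset("custom", baseline_rate=2000.0, seed=1)
        with pytest.raises(ValueError, match="thinning|rate"):
            ew.simulate_neuron(stim, neuron)

    def test_poisson_count_statistics(self):
        # mean and variance of 1 s counts agree for a constant-rate unit
        stim = ew.make_stimulus(_spec(seed=8))
        neuron = ew.condition_preset("custom", baseline_rate=30.0,
                                     gain_coefficient=0.0,
                                     am_sensitivity=0.0, seed=21)
        st = ew.simulate_neuron(stim, neuron)
        counts, _ = np.histogram(st.times, bins=100, range=(0.0, 100.0))
        m, v = counts.mean(), counts.var(ddof=1)
        se = np.sqrt(2.0 * m ** 2 / 99 + m / 100)
        assert abs(m - v) < 3 * se

    def test_refractory_enforced(self):
        stim = ew.make_stimulus(_spec(seed=5))
        neuron = ew.condition_preset("custom", baseline_rate=100.0,
                                     gain_coefficient=0.0,
                                     am_sensitivity=0.0, refractory=0.005,
                                     seed=2)
        st = ew.simulate_neuron(stim, neuron)
        assert np.diff(st.times).min() >= 0.005


class TestSimulateBehavior:
    def test_constant_frequency_without_tracking(self):
        spec = _spec(duration=30.0, sample_rate=20000.0,
                     envelope_frequency=0.1, seed=4)
        stim = ew.make_stimulus(spec)
        sig = ew.simulate_behavior(stim, ew.BehaviorSpec(
            behavior_gain_coefficient=0.0))
        x = sig
        idx = np.nonzero((x[:-1] < 0) & (x[1:] >= 0))[0]
        frac = -x[idx] / (x[idx + 1] - x[idx])
        crossings = (idx + frac) / 20000.0
        periods = np.diff(crossings)
        assert np.allclose(periods, 1.0 / 800.0, rtol=1e-4)

    def test_modulation_amplitude_ratio_follows_power_law(self):
        bs = ew.BehaviorSpec(behavior_gain_exponent=-0.5)
        amps = {}
        for f_env in (0.05, 1.0):
            spec = _spec(duration=60.0, sample_rate=20000.0,
                         envelope_frequency=f_env, seed=6)
            stim = ew.make_stimulus(spec)
            f_t = programmed_eod_frequency(stim, bs)
            amps[f_env] = (f_t.max() - f_t.min()) / 2.0
        assert np.isclose(amps[0.05] / amps[1.0], (0.05 / 1.0) ** -0.5,
                          rtol=1e-6)

    def test_phase_continuity(self):
        spec = _spec(duration=10.0, sample_rate=20000.0,
                     envelope_frequency=0.5, seed=4)
        stim = ew.make_stimulus(spec)
        bs = ew.BehaviorSpec()
        sig = ew.simulate_behavior(stim, bs)
        fmax = programmed_eod_frequency(stim, bs).max()
        assert np.abs(np.diff(sig)).max() <= 2 * np.pi * fmax / 20000.0

    def test_rejects_undersampled_eod(self):
        spec = _spec(duration=30.0, sample_rate=1000.0,
                     envelope_frequency=0.1, seed=4)
        stim = ew.make_stimulus(spec)
        with pytest.raises(ValueError, match="sample rate"):
            ew.simulate_behavior(stim, ew.BehaviorSpec())


class TestConditionPresets:
    def test_exponent_structure(self):
        assert ew.condition_preset("control_ell").gain_exponent == 0.4
        assert ew.condition_preset("multipolar").gain_exponent == 0.4
        for flat in ("np_inactivated", "pet_inactivated", "stellate"):
            assert ew.condition_preset(flat).gain_exponent == 0.0

    def test_gain_scaling_directions(self):
        control = ew.condition_preset("control_ell")
        assert ew.condition_preset("np_inactivated").gain_coefficient \
            < control.gain_coefficient
        assert ew.condition_preset("pet_inactivated").gain_coefficient \
            > control.gain_coefficient

    def test_custom_passthrough(self):
        spec = ew.condition_preset("custom", baseline_rate=12.0,
                                   gain_coefficient=3.0, gain_exponent=-0.2,
                                   seed=9)
        assert (spec.baseline_rate, spec.gain_coefficient,
                spec.gain_exponent, spec.seed) == (12.0, 3.0, -0.2, 9)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown condition"):
            ew.condition_preset("cerebellum")


def test_identical_spec_and_seed_reproduce_everything():
    spec = _spec(duration=50.0, seed=77)
    a, b = ew.make_stimulus(spec), ew.make_stimulus(spec)
    assert np.array_equal(a.am, b.am) and np.array_equal(a.envelope, b.envelope)
    neuron = ew.condition_preset("control_ell", seed=5)
    sa = ew.simulate_neuron(a, neuron)
    sb = ew.simulate_neuron(b, neuron)
    assert np.array_equal(sa.times, sb.times)
    bs = ew.BehaviorSpec(seed=3)
    spec_hi = _spec(duration=30.0, sample_rate=20000.0, seed=77)
    stim_hi = ew.make_stimulus(spec_hi)
    assert np.array_equal(ew.simulate_behavior(stim_hi, bs),
                          ew.simulate_behavior(stim_hi, bs))


def test_default_trial_duration_policy():
    assert default_trial_duration(0.05) == 3200.0
    assert default_trial_duration(1.0) == 800.0
    assert default_trial_duration(0.1) == 1600.0
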