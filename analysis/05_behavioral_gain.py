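#!/usr/bin/env python
"""Behavioral (EOD frequency) envelope tracking and its power-law gain.

Synthesizes an EOD whose frequency tracks the stimulus envelope with a
low-pass power-law gain (exponent -0.5), extracts the time-varying EOD
frequency from the raw signal via zero crossings and a 0.05 Hz low-pass,
and recovers the behavioral gain at each envelope frequency.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import envwhiten as ew
from envwhiten.behavior import behavioral_gain, eod_frequency
from envwhiten.io import write_json_summary, write_tidy_table

FS = 10000.0


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)

    bspec = ew.BehaviorSpec(seed=int(rng.integers(2 ** 31)))
    freqs = np.asarray(ew.SINUSOIDAL_ENVELOPE_FREQUENCIES)
    rows = []
    for f_env in freqs:
        dur = 120.0 + max(3.0 / f_env, 40.0)
        stim = ew.make_stimulus(ew.StimulusSpec(
            duration=dur, sample_rate=FS, envelope_frequency=f_env,
            seed=int(rng.integers(2 ** 31))))
        trace = eod_frequency(ew.simulate_behavior(stim, bspec), FS)
        g = behavioral_gain(trace, f_env, stim.envelope_amplitude)
        rows.append({"frequency_hz": f_env,
                     "behavioral_gain": g,
                     "gain_programmed":
                         bspec.behavior_gain_coefficient
                         * f_env ** bspec.behavior_gain_exponent})

    df = pd.DataFrame(rows)
    fit = ew.fit_power_law(ew.TuningCurve(
        frequencies=freqs, gains=df["behavioral_gain"].to_numpy()))
    args.outdir.mkdir(parents=True, exist_ok=True)
    write_tidy_table(df, args.outdir / "behavioral_gain.csv")
    write_json_summary({"behavioral_exponent": fit.exponent,
                        "behavioral_exponent_programmed":
                            bspec.behavior_gain_exponent,
                        "r_squared": fit.r_squared},
                       args.outdir / "behavioral_gain_summary.json")

    print(df.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print(f"behavioral power-law exponent: {fit.exponent:.3f} "
          f"(programmed {bspec.behavior_gain_exponent}); EOD-frequency "
          f"tracking is strongest for slow envelopes, as in freely "
          f"behaving fish.")


if __name__ == "__main__":
    main()
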