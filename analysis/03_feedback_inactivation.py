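#!/usr/bin/env python
"""Paired feedback-inactivation contrasts on simulated populations.

Simulates a control pyramidal-cell population (high-pass envelope tuning,
exponent 0.4) and the same units after (a) complete feedback inactivation
(gain scaled down, flat tuning) and (b) indirect-pathway inactivation (gain
scaled up at low frequencies, flat tuning).  Reports population tuning
exponents, whitening indices, sensitivity changes and paired signed-rank
statistics, mirroring a within-cell pre/post drug design.
"""

import argparse
from pathlib import Path

import envwhiten as ew


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-units", type=int, default=8)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = ew.ExperimentConfig(
        condition_pairs=(("control_ell", "np_inactivated", "paired"),
                         ("control_ell", "pet_inactivated", "paired")),
        n_units=args.n_units, base_seed=args.seed,
        output_dir=str(args.outdir / "feedback_inactivation"))
    res = ew.run_experiment(cfg)

    pop = res.population.set_index("condition")
    print("Population summary (mean +- SEM):")
    for cond in cfg.conditions:
        r = pop.loc[cond]
        print(f"  {cond:16s} exponent {r['exponent_mean']:+.3f} "
              f"+- {r['exponent_sem']:.3f}   white index "
              f"{r['white_index_mean']:.3f} +- {r['white_index_sem']:.3f}")
    print("\nPaired statistics:")
    print(res.stats.to_string(index=False))

    np_wi = pop.loc["np_inactivated", "white_index_mean"]
    ctl_wi = pop.loc["control_ell", "white_index_mean"]
    print(f"\nComplete feedback inactivation flattens tuning and lowers the "
          f"white index ({ctl_wi:.3f} -> {np_wi:.3f}): whitening depends on "
          f"descending input.")
    g_lo = pop.loc["pet_inactivated", "gain_0.05_mean"]
    g_lo_ctl = pop.loc["control_ell", "gain_0.05_mean"]
    print(f"Indirect-pathway inactivation raises low-frequency gain "
          f"({g_lo_ctl:.1f} -> {g_lo:.1f} Hz/contrast at 0.05 Hz) while also "
          f"flattening tuning: the indirect pathway selectively attenuates "
          f"low-frequency envelope responses.")


if __name__ == "__main__":
    main()
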