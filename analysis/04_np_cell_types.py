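#!/usr/bin/env python
"""Unpaired comparison of the two feedback-projecting cell types.

Simulates stellate-like units (flat envelope tuning) and multipolar-like
units (high-pass tuning, exponent 0.4) and compares tuning exponents and
whitening indices with the Kruskal-Wallis test.  Multipolar cells, which
feed the indirect pathway, are expected to transmit an already-whitened
envelope signal; stellate cells are not.
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
        condition_pairs=(("stellate", "multipolar", "unpaired"),),
        n_units=args.n_units, base_seed=args.seed,
        output_dir=str(args.outdir / "np_cell_types"))
    res = ew.run_experiment(cfg)

    pop = res.population.set_index("condition")
    for cond in ("stellate", "multipolar"):
        r = pop.loc[cond]
        print(f"{cond:10s} exponent {r['exponent_mean']:+.3f} "
              f"+- {r['exponent_sem']:.3f}   white index "
              f"{r['white_index_mean']:.3f} +- {r['white_index_sem']:.3f}")
    print(res.stats.to_string(index=False))
    print("\nOnly the multipolar (indirect-projecting) population whitens "
          "natural envelopes; stellate (direct-projecting) cells respond "
          "strongly but without frequency-dependent gain.")


if __name__ == "__main__":
    main()
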