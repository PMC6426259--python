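#!/usr/bin/env python
"""Replicate grids of the case-only bias across models and error distributions.

Scaled-down version of the replicate-grid figures: per model and residual
distribution (normal, exponential, uniform), runs replicates of a common
disease with sizeable effects and tabulates the median population and
case-only coefficients and their difference.
"""

import argparse
from pathlib import Path

from casebias.experiments import run_bias_experiment
from casebias.models import CausalModelSpec


def specs_for(dist):
    common = {"prevalence": 0.3, "maf": 0.2, "error_dist": dist}
    return [
        CausalModelSpec("a", beta=-0.3, omega_b=-0.5, **common),
        CausalModelSpec("b", beta=-0.3, omega_g=0.4, **common),
        CausalModelSpec("c", omega_g=0.4, omega_b=-0.4, **common),
        CausalModelSpec("d", gamma=-0.3, omega_g=0.4, **common),
    ]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--reps", type=int, default=100)
    ap.add_argument("--n", type=int, default=20_000)
    ap.add_argument("--out", type=Path, default=Path("results/bias_grid.tsv"))
    args = ap.parse_args()

    frames = []
    for i, dist in enumerate(("normal", "exponential", "uniform")):
        frames.append(run_bias_experiment(specs_for(dist), reps=args.reps,
                                          n=args.n, seed=args.seed + i))
    import pandas as pd
    df = pd.concat(frames, ignore_index=True)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False)

    summary = df.groupby(["model", "error_dist"]).agg(
        beta_pop=("beta_pop", "median"), beta_case=("beta_case", "median"),
        delta=("delta", "median")).round(4)
    print(summary)
    print("\nexpected signs: a -> delta > 0 (attenuation), b -> delta ~ 0, "
          "c -> delta > 0 (collider), d -> case-only ~ 0")
    print(f"wrote {len(df)} replicate rows to {args.out}")


if __name__ == "__main__":
    main()
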