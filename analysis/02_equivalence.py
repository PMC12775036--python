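#!/usr/bin/env python
"""Stage 2 — bootstrap equivalence test of fit quality between systems.

Reads the per-subject full-recording R^2 and MAE values produced by stage
1 and tests, per metric and channel, whether the consumer-minus-research
mean difference is statistically equivalent to zero against the
pre-declared bounds (+/-0.0075 for MAE, +/-0.0102 / +/-0.0091 for R^2 at
F3/F4), using 10,000 bootstrap resamples and the 90% percentile-CI
containment rule. A Shapiro-Wilk column documents the normality gate that
motivates the nonparametric route.
"""

import argparse
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from aperio.equivalence import DEFAULT_BOUNDS, equivalence_test, shapiro_wilk

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--boot", type=int, default=10_000)
    args = parser.parse_args()

    fits = {
        label: pd.read_csv(OUT / f"fits_{label}.tsv", sep="\t")
        for label in ("consumer", "research")
    }
    rows = []
    for metric, col, ch in (("r2_F3", "r2", "F3"), ("r2_F4", "r2", "F4"),
                            ("mae_F3", "mae", "F3"), ("mae_F4", "mae", "F4")):
        bound = DEFAULT_BOUNDS.get(metric, DEFAULT_BOUNDS["mae"])
        x = {}
        for label, table in fits.items():
            full = table[(table.half == "full") & (table.channel == ch)]
            x[label] = full[col].to_numpy()
        res = equivalence_test(x["consumer"], x["research"], bound,
                               metric=metric, n_boot=args.boot,
                               seed=args.seed)
        w, p = shapiro_wilk(np.concatenate(list(x.values())))
        rows.append({**asdict(res), "shapiro_w": w, "shapiro_p": p})
        print(f"{metric}: diff {res.mean_diff:+.4f} "
              f"90% CI [{res.ci_low:+.4f}, {res.ci_high:+.4f}] "
              f"bound +/-{bound} -> {res.outcome}")

    pd.DataFrame(rows).to_csv(OUT / "equivalence.tsv", sep="\t",
                              index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
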