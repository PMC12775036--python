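#!/usr/bin/env python
"""Stage 3 — split-half reliability of the aperiodic parameters.

Reads the half-wise fits from stage 1, computes ICC(2,1) with F-based 95%
CIs per system, channel, and parameter, and bootstraps the between-system
difference Delta-ICC = ICC_consumer - ICC_research (10,000 resamples,
percentile CI and two-sided p).
"""

import argparse
from pathlib import Path

import pandas as pd

from aperio.reliability import delta_icc_bootstrap, icc_2_1

OUT = Path(__file__).resolve().parents[1] / "results"


def paired(table: pd.DataFrame, channel: str, param: str):
    halves = table[table.half.isin(["1", "2", 1, 2])].copy()
    halves["half"] = halves.half.astype(str)
    wide = halves[halves.channel == channel].pivot(
        index="subject", columns="half", values=param).dropna()
    return wide[["1", "2"]].to_numpy()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--boot", type=int, default=10_000)
    args = parser.parse_args()

    fits = {
        label: pd.read_csv(OUT / f"fits_{label}.tsv", sep="\t",
                           dtype={"half": str})
        for label in ("consumer", "research")
    }
    icc_rows, delta_rows = [], []
    for ch in ("F3", "F4"):
        for param in ("offset", "exponent"):
            pm = {label: paired(t, ch, param) for label, t in fits.items()}
            for label, y in pm.items():
                res = icc_2_1(y)
                icc_rows.append(dict(system=label, channel=ch,
                                     parameter=param, icc=res.icc,
                                     ci_low=res.ci_low, ci_high=res.ci_high,
                                     n=res.n))
                print(f"{label:<9} {ch} {param:<9} ICC = {res.icc:.3f} "
                      f"[{res.ci_low:.3f}, {res.ci_high:.3f}] (n={res.n})")
            d = delta_icc_bootstrap(pm["consumer"], pm["research"],
                                    n_boot=args.boot, seed=args.seed)
            delta_rows.append(dict(channel=ch, parameter=param,
                                   delta_icc=d.delta, ci_low=d.ci_low,
                                   ci_high=d.ci_high, p=d.p))
            print(f"          {ch} {param:<9} dICC = {d.delta:+.3f} "
                  f"[{d.ci_low:+.3f}, {d.ci_high:+.3f}] p = {d.p:.3f}")

    pd.DataFrame(icc_rows).to_csv(OUT / "reliability.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    pd.DataFrame(delta_rows).to_csv(OUT / "delta_icc.tsv", sep="\t",
                                    index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
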