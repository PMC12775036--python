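#!/usr/bin/env python
"""Stage 6 — aperiodic activity and mathematical ability.

Builds the frontal aperiodic composite (mean of offset and exponent at
F3/F4) per subject, correlates it with the arithmetic-fluency score and
the two working-memory proportions (all z-standardized), compares the
composite-math correlation between cohorts with Fisher's Z, and runs the
supplementary simple mediation with mean working memory as mediator.
"""

import argparse
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from aperio.association import (
    correlation_report,
    fisher_z_compare,
    simple_mediation,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def composites(fits: pd.DataFrame) -> pd.Series:
    full = fits[fits.half == "full"]
    per = full.pivot_table(index="subject", columns="channel",
                           values=["offset", "exponent"])
    return per.mean(axis=1).rename("composite")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--boot", type=int, default=5000)
    args = parser.parse_args()

    reports, headline = {}, {}
    for label in ("consumer", "research"):
        fits = pd.read_csv(OUT / f"fits_{label}.tsv", sep="\t",
                           dtype={"half": str})
        behavior = pd.read_csv(OUT / f"behavior_{label}.tsv", sep="\t")
        comp = composites(fits)
        rep = correlation_report(comp, behavior)
        reports[label] = rep
        rep.to_csv(OUT / f"association_{label}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        head = rep[(rep.x == "composite") & (rep.y == "math")].iloc[0]
        headline[label] = head
        print(f"{label}: composite-math r = {head.r:.3f} "
              f"[{head.ci_low:.3f}, {head.ci_high:.3f}], p = {head.p:.3f}, "
              f"n = {int(head.n)}")

        if label == "consumer":
            merged = behavior.set_index("subject").join(comp, how="inner")
            wm = merged[["wm_verbal", "wm_visuospatial"]].mean(axis=1)
            med = simple_mediation(merged.composite.to_numpy(),
                                   wm.to_numpy(),
                                   merged.math.to_numpy().astype(float),
                                   n_boot=args.boot, seed=args.seed)
            pd.DataFrame([asdict(med)]).to_csv(OUT / "mediation.tsv",
                                               sep="\t", index=False,
                                               float_format="%.6g")
            print(f"  mediation: indirect = {med.indirect:+.3f} "
                  f"[{med.ci_low:+.3f}, {med.ci_high:+.3f}]")

    z, p = fisher_z_compare(headline["consumer"].r,
                            int(headline["consumer"].n),
                            headline["research"].r,
                            int(headline["research"].n))
    print(f"Fisher Z comparing cohorts: Z = {z:.2f}, p = {p:.3f}")
    pd.DataFrame([dict(z=z, p=p)]).to_csv(OUT / "fisher_z.tsv", sep="\t",
                                          index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
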