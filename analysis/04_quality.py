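#!/usr/bin/env python
"""Stage 4 — general data quality and within-session stability.

Reads the band-power and retention tables from stage 1 and summarizes,
per system: mean and range of 49-51 Hz (line noise) and 0.1-1 Hz (drift)
log10 band power, segment retention, and exclusion counts; then tests
whether band powers change between the first and second recording halves
with paired Wilcoxon signed-rank tests.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from aperio.quality import halfwise_stability

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()

    summary_rows, stability_rows = [], []
    for label in ("consumer", "research"):
        band = pd.read_csv(OUT / f"bandpower_{label}.tsv", sep="\t",
                           dtype={"half": str})
        ret = pd.read_csv(OUT / f"retention_{label}.tsv", sep="\t")
        full = band[band.half == "full"]
        row = dict(system=label)
        for metric in ("line_noise", "drift"):
            row[f"{metric}_mean"] = full[metric].mean()
            row[f"{metric}_min"] = full[metric].min()
            row[f"{metric}_max"] = full[metric].max()
        row["retention_mean"] = ret.retention.mean()
        row["n_excluded"] = int(ret.excluded.sum())
        row["n_total"] = len(ret)
        summary_rows.append(row)
        print(f"{label}: line noise {row['line_noise_mean']:.2f} "
              f"log10(uV^2/Hz), drift {row['drift_mean']:.2f}, "
              f"retention {row['retention_mean']:.3f}, "
              f"excluded {row['n_excluded']}/{row['n_total']}")

        for metric in ("line_noise", "drift"):
            h = band[band.half.isin(["1", "2"])].pivot_table(
                index=["subject", "channel"], columns="half", values=metric)
            res = halfwise_stability(h["1"].to_numpy(), h["2"].to_numpy())
            stability_rows.append(dict(system=label, band=metric,
                                       W=res.statistic, p=res.p,
                                       median_change=res.median_change,
                                       n=res.n))
            print(f"  {metric} half 1 -> 2: median change "
                  f"{res.median_change:+.3f}, Wilcoxon p = {res.p:.3f}")

    pd.DataFrame(summary_rows).to_csv(OUT / "quality_summary.tsv", sep="\t",
                                      index=False, float_format="%.6g")
    pd.DataFrame(stability_rows).to_csv(OUT / "stability.tsv", sep="\t",
                                        index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
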