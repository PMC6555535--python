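#!/usr/bin/env python
"""Topography of the two landscapes: peaks, ruggedness, epistasis.

Quantifies how different the two landscapes are in shape — the number of
local fitness peaks, the average number of peaks per 4-position
sub-hypercube (ruggedness), the distribution of pairwise epistasis
magnitudes, and the escape-trajectory counts of every peak (stasis
genotype candidates).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from riboland import io
from riboland import landscape_metrics as lm

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    df = io.read_fitness_table(RESULTS / "synthetic_truth.fitness.tsv")
    rugged, smooth = io.landscapes_from_table(df)
    summary = {}
    for label, land in (("rugged_hdv_like", rugged), ("smooth_ligase_like", smooth)):
        m = lm.summarize_landscape(land, delta_rule="strict")
        summary[label] = {
            "n_peaks": m.n_peaks,
            "ruggedness_k4": round(m.ruggedness, 4),
            "epistasis_median": round(float(np.median(m.epistasis_magnitudes)), 4),
            "epistasis_q95": round(float(np.quantile(m.epistasis_magnitudes, 0.95)), 4),
            "n_epistasis_skipped": m.n_epistasis_skipped,
        }
        rows = []
        for g in sorted(m.peaks):
            n2, p2 = lm.escape_trajectories(land, g, 2)
            rows.append({"genotype": g, "fitness": land[g], "n_escape_2": n2, "n_possible_2": p2})
        pd.DataFrame(rows).to_csv(RESULTS / f"peaks_{label}.tsv", sep="\t", index=False)
        print(f"{label}: {m.n_peaks} peaks, ruggedness {m.ruggedness:.3f}, "
              f"median |epistasis| {summary[label]['epistasis_median']}")
    ratio = summary["rugged_hdv_like"]["n_peaks"] / max(summary["smooth_ligase_like"]["n_peaks"], 1)
    print(f"the rugged landscape has {ratio:.0f}x more peaks than the smooth one")
    (RESULTS / "topography_summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
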