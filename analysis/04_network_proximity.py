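#!/usr/bin/env python
"""Proximity and overlap of the two genotype networks.

Sweeps the fitness cutoff that defines network membership and measures
the nearest cross-network distance in both directions, the count of
dual-function intersection sequences, and per-genotype same-/cross-
network connection counts at a representative cutoff.
"""

from pathlib import Path

import pandas as pd

from riboland import io
from riboland import network_proximity as npx

RESULTS = Path(__file__).resolve().parents[1] / "results"
CUTOFFS = [0.05, 0.1, 0.25, 0.5, 0.75, 0.9]


def main() -> None:
    df = io.read_fitness_table(RESULTS / "synthetic_truth.fitness.tsv")
    rugged, smooth = io.landscapes_from_table(df)

    sweep = npx.cutoff_sweep(rugged, smooth, CUTOFFS)
    sweep.to_csv(RESULTS / "proximity_sweep.tsv", sep="\t", index=False)
    for c in (CUTOFFS[0], CUTOFFS[-1]):
        sub = sweep[sweep["cutoff"] == c]
        print(f"cutoff {c}: mean cross-network distance "
              f"{sub['mean_distance'].mean():.2f} over {int(sub['n'].sum())} genotypes")

    inter = npx.intersection_set(
        df.rename(columns={"hdv_fitness": "fitness"})[["genotype", "fitness"]],
        df.rename(columns={"ligase_fitness": "fitness"})[["genotype", "fitness"]],
    )
    inter.to_csv(RESULTS / "intersection_sequences.tsv", sep="\t", index=False)
    print(f"{len(inter)} of {len(df)} genotypes are active for both functions")

    conn = npx.connection_counts(rugged, smooth, cutoff=0.25)
    conn.to_csv(RESULTS / "connection_counts_cutoff_0.25.tsv", sep="\t", index=False)
    print(f"connection counts at cutoff 0.25 written for {len(conn)} active genotypes")


if __name__ == "__main__":
    main()
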