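#!/usr/bin/env python
"""Precision-weighted cluster probabilities and district prevalences.

Turns each wave's posterior draws into cluster-level predicted LBW
probabilities and averages them (unweighted) to district prevalence in
percent. Writes cluster and district CSVs per wave.
"""

import pickle
from pathlib import Path

from lbwsae import cluster_probabilities, district_prevalence

OUT = Path("results/analysis")
SCRATCH = Path("scratch/analysis")


def main() -> None:
    for pkl in sorted(SCRATCH.glob("draws_*.pkl")):
        slug = pkl.stem.removeprefix("draws_")
        with open(pkl, "rb") as fh:
            draws = pickle.load(fh)
        clusters = cluster_probabilities(draws)
        districts = district_prevalence(clusters)
        clusters.to_csv(OUT / f"clusters_{slug}.csv", index=False)
        districts.to_csv(OUT / f"districts_{slug}.csv", index=False)
        print(f"{draws.meta['wave']}: {len(clusters)} clusters -> "
              f"{len(districts)} districts; national mean prevalence "
              f"{districts['prevalence_pct'].mean():.2f}% "
              f"(cluster p_hat range {clusters['p_hat'].min():.3f}-"
              f"{clusters['p_hat'].max():.3f})")


if __name__ == "__main__":
    main()
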