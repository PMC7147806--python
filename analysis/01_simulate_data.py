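#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds the toy multi-arm genome (PCH blocks, mappability, repeat catalog,
H3K9me2 islands, TE insertions), simulates Hi-C read pairs with the planted
arm-pair preferences, strain-paired ChIP/input coverage, FISH distance
tables and the TE population-frequency table, and writes everything as
plain-text files under results/synthetic/.
"""

from pathlib import Path

import pandas as pd

from pchic import io
from pchic.simulate import (
    SyntheticConfig,
    make_toy_genome,
    simulate_chip_profiles,
    simulate_fish_distances,
    simulate_hic_pairs,
    simulate_population_frequencies,
)

SEED = 7
N_PAIRS = 300_000
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=SEED)
    toy = make_toy_genome(cfg)

    arms = pd.DataFrame(
        [(a.name, a.chromosome, a.length) for a in cfg.arms],
        columns=["name", "chromosome", "length"],
    )
    arms.to_csv(OUT / "arms.tsv", sep="\t", header=False, index=False)
    io.write_bed(io.intervals_to_bed(toy.annotation.pch), OUT / "pch_boundaries.bed")
    io.write_bed(toy.islands, OUT / "islands.bed")
    io.write_bed(toy.tes, OUT / "tes.bed")
    io.write_bedgraph(
        {a: pd.DataFrame({"start": iv.starts, "end": iv.ends, "value": 1})
         for a, iv in toy.mappability.ones.items()},
        OUT / "mappability.bg",
    )

    pairs = simulate_hic_pairs(toy, N_PAIRS, seed=SEED + 1)
    io.write_pairs_tsv(pairs, OUT / "hic_pairs.tsv")
    print(f"wrote {N_PAIRS} Hi-C pairs, {len(toy.islands)} islands, "
          f"{len(toy.tes)} TEs")

    prof = simulate_chip_profiles(toy, seed=SEED + 2)
    for strain, tracks in prof.items():
        io.write_bedgraph(tracks["chip"], OUT / f"chip_{strain}.bg")
        io.write_bedgraph(tracks["input"], OUT / f"input_{strain}.bg")

    fish = pd.concat([
        simulate_fish_distances(cfg, 200, seed=SEED + 3, group="focal"),
        simulate_fish_distances(cfg, 200, seed=SEED + 4, pi=0.0, group="control"),
    ])
    fish.to_csv(OUT / "fish_distances.tsv", sep="\t", index=False)

    simulate_population_frequencies(cfg, seed=SEED + 5).to_csv(
        OUT / "te_frequencies.tsv", sep="\t", index=False
    )
    print(f"synthetic inputs written to {OUT}")


if __name__ == "__main__":
    main()
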