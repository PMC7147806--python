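#!/usr/bin/env python
"""Euchromatin-PCH contact enrichment at H3K9me2 islands.

Scores each island window (feature +/- 1 kb) for the fraction of its Hi-C
pairs whose other end is heterochromatic, against 200 matched random-region
null sets, then runs the cohort-level binomial test against the nominal 5%.
"""

from pathlib import Path

import pandas as pd

from pchic import io
from pchic.eupch import (
    EuPchScorer,
    enrichment_binomial,
    make_query_windows,
    sample_null_regions,
    score_queries,
)
from pchic.genome import merge_intervals
from pchic.simulate import SyntheticConfig, make_toy_genome

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 7
MIN_PAIRS = 100  # floor scaled to the 300k-pair simulated depth


def main() -> None:
    toy = make_toy_genome(SyntheticConfig(seed=SEED))
    ann = toy.annotation
    classified = pd.read_csv(
        ROOT / "classify" / "classified_pairs.tsv", sep="\t",
        dtype={"arm1": object, "arm2": object},
    )
    regions, rejected = make_query_windows(toy.islands, "island", ann)
    if len(rejected):
        print(f"rejected {len(rejected)} features outside euchromatin")

    scorer = EuPchScorer(classified, ann.arm_names)
    exclusions = {
        arm: merge_intervals(g["start"].to_numpy(), g["end"].to_numpy())
        for arm, g in toy.islands.groupby("arm")
    }
    ensemble = sample_null_regions(ann, exclusions, regions, scorer,
                                   n_sets=200, seed=SEED, min_pairs=MIN_PAIRS)
    scored = score_queries(scorer, regions, ensemble, min_pairs=MIN_PAIRS)

    out = ROOT / "eu_pch"
    out.mkdir(parents=True, exist_ok=True)
    io.write_report(scored, out / "island_scores.tsv",
                    {"seed": SEED, "n_sets": 200, "min_pairs": MIN_PAIRS})

    tested = scored[~scored["excluded"]]
    k, n = int(tested["significant"].sum()), len(tested)
    p = enrichment_binomial(k, n, 0.05) if n else float("nan")
    io.write_report(
        pd.DataFrame([{"k_significant": k, "n_tested": n, "binomial_p": p}]),
        out / "cohort_binomial.tsv", {"seed": SEED},
    )
    print(f"{k}/{n} islands significant at empirical p < 0.05 "
          f"(binomial p = {p:.3g}); no enrichment is expected in this "
          f"unperturbed simulation")
    print(f"EU-PCH reports written to {out}")


if __name__ == "__main__":
    main()
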