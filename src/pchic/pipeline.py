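"""End-to-end orchestration: simulate -> classify -> contacts -> EU-PCH.

`run_pipeline` executes the stages in order on synthetic inputs, writes all
reports as commented TSVs, and maintains a conservation audit: every filter
records (input count, surviving count) and the audit asserts that end
categories and pair classes always account for every read pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io
from .classify import EndCategory, PairClass, category_counts, classify_frame
from .contacts import (
    LEVELS,
    build_contact_matrix,
    expected_proportions,
    extract_arm_pairs,
    partition_interactions,
    permutation_test,
    separation_filter,
)
from .eupch import (
    EuPchScorer,
    enrichment_binomial,
    make_query_windows,
    sample_null_regions,
    score_queries,
)
from .genome import Intervals, arm_marginals, bin_pch_windows, merge_intervals
from .simulate import SyntheticConfig, ToyGenome, make_toy_genome, simulate_hic_pairs


class AuditError(AssertionError):
    """A conservation audit failed: counts do not reconcile."""


@dataclass
class ConservationAudit:
    """Input/surviving counts for every filter step of a run."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if not (0 <= n_out <= n_in):
            raise AuditError(f"step {name}: surviving {n_out} not in [0, {n_in}]")
        self.steps.append((name, n_in, n_out))

    def check_partition(self, name: str, total: int, parts: dict[str, int]) -> None:
        s = sum(parts.values())
        if s != total:
            raise AuditError(
                f"partition {name}: parts sum to {s}, expected {total}"
            )
        self.steps.append((name, total, s))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_in", "n_out"])


@dataclass
class PipelineResult:
    toy: ToyGenome
    classified: pd.DataFrame
    partitions: dict
    permutations: pd.DataFrame
    eu_pch: Optional[pd.DataFrame]
    cohort: Optional[dict]
    audit: ConservationAudit
    out_dir: Optional[Path]


def run_pipeline(
    config: SyntheticConfig,
    n_pairs: int = 200_000,
    n_perm: int = 1_000,
    n_sets: int = 50,
    min_pairs: int = 100,
    permutation_targets: tuple[tuple[str, str], ...] = (("3L-4", "no_intra_chromosome"),),
    boost_islands: float | None = None,
    out_dir: str | Path | None = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run the full synthetic analysis and write its reports.

    ``boost_islands`` plants a euchromatin-PCH contact multiplier on every
    island window (None leaves the genome unperturbed for null calibration).
    Reports are deterministic given (config, seed).
    """
    seed = config.seed if seed is None else seed
    toy = make_toy_genome(config, seed=seed)
    annotation = toy.annotation
    audit = ConservationAudit()

    # -- stage: simulate + classify ---------------------------------------
    regions, _ = make_query_windows(toy.islands, "island", annotation)
    boosted = None
    if boost_islands is not None:
        boosted = pd.DataFrame(
            [(r.arm, r.start, r.end, boost_islands) for r in regions],
            columns=["arm", "start", "end", "mult"],
        )
    pairs = simulate_hic_pairs(toy, n_pairs, seed=seed, boosted_windows=boosted)
    classified = classify_frame(pairs, annotation, toy.catalog)
    counts = category_counts(classified)
    audit.check_partition(
        "end_categories", 2 * len(classified),
        dict(counts[counts["kind"] == "end"][["category", "count"]].itertuples(
            index=False, name=None)),
    )
    audit.check_partition(
        "pair_classes", len(classified),
        dict(counts[counts["kind"] == "pair"][["category", "count"]].itertuples(
            index=False, name=None)),
    )

    # -- stage: PCH-PCH contacts ------------------------------------------
    windows = bin_pch_windows(annotation, config.window_bp)
    pch_pairs = classified[
        classified["pair_class"] == PairClass.PCH_PCH_UNIQUE.value
    ]
    surv, n_close = separation_filter(pch_pairs, 10_000)
    audit.record("separation_filter", len(pch_pairs), len(surv))
    matrix = build_contact_matrix(classified, windows, 10_000)
    if matrix.total_pairs + matrix.n_outside != len(surv):
        raise AuditError("contact matrix mass does not match filtered pairs")

    partitions = {lvl: partition_interactions(matrix, lvl) for lvl in LEVELS}
    for lvl in ("no_intra_arm", "no_intra_chromosome"):
        if partitions[lvl].retained > partitions["all"].retained:
            raise AuditError("retained counts increased across exclusion levels")

    chrom = annotation.chromosome_of
    perm_rows = []
    for target, level in permutation_targets:
        a1, a2 = extract_arm_pairs(classified, level, chrom)
        res = permutation_test(a1, a2, target, level, chrom,
                               n_perm=n_perm, seed=seed)
        perm_rows.append({
            "target": target, "level": level, "observed": res.observed,
            "n_perm": res.n_perm, "p_one_sided": res.p_one_sided,
        })
    permutations = pd.DataFrame(perm_rows)

    # -- stage: EU-PCH ------------------------------------------------------
    scorer = EuPchScorer(classified, annotation.arm_names)
    exclusions = {
        arm: merge_intervals(g["start"].to_numpy(), g["end"].to_numpy())
        for arm, g in toy.islands.groupby("arm")
    }
    eu_df = cohort = None
    if regions:
        ensemble = sample_null_regions(
            annotation, exclusions, regions, scorer,
            n_sets=n_sets, seed=seed, min_pairs=min_pairs,
        )
        eu_df = score_queries(scorer, regions, ensemble, min_pairs=min_pairs)
        tested = eu_df[~eu_df["excluded"]]
        k = int(tested["significant"].sum())
        n = len(tested)
        cohort = {
            "k_significant": k, "n_tested": n,
            "binomial_p": enrichment_binomial(k, n, 0.05) if n else float("nan"),
        }

    # -- reports ------------------------------------------------------------
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        meta = {"seed": seed, "n_pairs": n_pairs, "n_perm": n_perm,
                "n_sets": n_sets, "alpha": config.alpha}
        io.write_report(counts, out_path / "category_counts.tsv", meta)
        win_tsv = matrix.windows.copy()
        io.write_report(win_tsv, out_path / "pch_windows.tsv", meta)
        np.savetxt(out_path / "contact_matrix.tsv", matrix.counts,
                   fmt="%d", delimiter="\t")
        part_rows = [
            {"level": lvl, "class": k, "proportion": v,
             "retained": p.retained}
            for lvl, p in partitions.items()
            for k, v in sorted(p.proportions.items())
        ]
        io.write_report(pd.DataFrame(part_rows),
                        out_path / "pch_partition.tsv", meta)
        io.write_report(permutations, out_path / "permutation_tests.tsv", meta)
        if eu_df is not None:
            io.write_report(eu_df, out_path / "eu_pch_regions.tsv", meta)
            io.write_report(pd.DataFrame([cohort]),
                            out_path / "eu_pch_cohort.tsv", meta)
        io.write_report(audit.frame(), out_path / "audit.tsv", meta)

    return PipelineResult(
        toy=toy, classified=classified, partitions=partitions,
        permutations=permutations, eu_pch=eu_df, cohort=cohort,
        audit=audit, out_dir=out_path,
    )
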