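"""Euchromatin-PCH contact enrichment with a matched-resampling null.

For each euchromatic query window (an H3K9me2 island padded by 1 kb, or a
TE insertion padded by 2 kb), the statistic is the fraction of Hi-C pairs
with one end mapped uniquely inside the window whose other end is
heterochromatic (unique-PCH, multi-PCH, or repeat). Windows supported by
fewer than 1,000 such pairs are excluded. The null is built from sets of
random euchromatic regions without H3K9me2 enrichment, matched to the query
set in count, chromosome arm, and size; the empirical p-value for a query
pools null fractions from the same (arm, size-quantile) stratum. A
cohort-level exact binomial test then asks whether more queries than the
nominal 5% reach significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import EndCategory, PairClass, PCH_CATEGORIES
from .genome import (
    ComputationError,
    GenomeAnnotation,
    InputError,
    Intervals,
    merge_intervals,
)

PAD_BP = {"island": 1_000, "te": 2_000, "control": 0}
MIN_PAIRS_DEFAULT = 1_000
N_NULL_SETS_DEFAULT = 200


@dataclass
class QueryRegion:
    region_id: str
    arm: str
    start: int
    end: int
    kind: str  # island | te | control
    feature_start: int | None = None
    feature_end: int | None = None
    h3k9me2_enriched: bool = True

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class EuPchResult:
    region_id: str
    arm: str
    size: int
    n_pairs: int
    frac_pch: float
    per_arm_frac: dict[str, float]
    excluded: bool
    exclusion_reason: str | None = None
    empirical_p: float | None = None


def make_query_windows(
    features: pd.DataFrame,
    kind: str,
    annotation: GenomeAnnotation,
) -> tuple[list[QueryRegion], pd.DataFrame]:
    """Pad features into query windows, clipped to arm bounds.

    ``features`` columns: arm, start, end, optional name. Islands are padded
    by +/-1 kb, TE insertion sites/intervals by +/-2 kb. Features touching
    PCH or falling outside derived euchromatin are rejected and reported.
    """
    if kind not in PAD_BP:
        raise InputError(f"unknown query kind {kind!r}")
    pad = PAD_BP[kind]
    eu = annotation.euchromatin()
    regions: list[QueryRegion] = []
    rejected = []
    for i, row in enumerate(features.itertuples(index=False)):
        arm, fs, fe = row.arm, int(row.start), int(row.end)
        name = getattr(row, "name", None) or f"{kind}_{i}"
        length = annotation.arm_length(arm)
        ws, we = max(0, fs - pad), min(length, fe + pad)
        pch = annotation.pch.get(arm, Intervals.empty())
        overlaps_pch = len(pch) and bool(
            np.any((pch.starts < fe) & (pch.ends > fs))
        )
        in_eu = eu.get(arm, Intervals.empty())
        if overlaps_pch:
            rejected.append((name, arm, fs, fe, "inside PCH"))
            continue
        if not (len(in_eu) and in_eu.contains(np.array([fs, fe - 1])).all()):
            rejected.append((name, arm, fs, fe, "outside derived euchromatin"))
            continue
        regions.append(QueryRegion(
            region_id=str(name), arm=arm, start=ws, end=we, kind=kind,
            feature_start=fs, feature_end=fe,
        ))
    rej = pd.DataFrame(rejected, columns=["name", "arm", "start", "end", "reason"])
    return regions, rej


# ---------------------------------------------------------------------------
# fast scorer over a classified pairs table


class EuPchScorer:
    """Indexes classified pairs for O(log n) euchromatin-PCH window scoring.

    A pair qualifies for a window through any end that is UNIQUE_EU and lies
    inside the window, provided its partner end is not TE-filtered (pairs
    touching a canonical-TE read are removed genome-wide before analysis).
    Both ends of an EU-EU pair qualify independently.
    """

    def __init__(self, classified: pd.DataFrame, arm_order: Sequence[str]):
        self.arm_order = list(arm_order)
        pch_vals = [c.value for c in PCH_CATEGORIES]

        frames = []
        for e, o in ((1, 2), (2, 1)):
            cat_e = classified[f"cat{e}"].to_numpy(dtype=object)
            cat_o = classified[f"cat{o}"].to_numpy(dtype=object)
            qual = (cat_e == EndCategory.UNIQUE_EU.value) & (
                cat_o != EndCategory.TE_FILTERED.value
            )
            if not qual.any():
                continue
            sub = pd.DataFrame({
                "arm": classified[f"arm{e}"].to_numpy(dtype=object)[qual],
                "pos": classified[f"pos{e}"].to_numpy()[qual].astype(np.int64),
                "other_pch": np.isin(cat_o[qual], pch_vals),
                "other_arm": np.where(
                    cat_o[qual] == EndCategory.UNIQUE_PCH.value,
                    classified[f"arm{o}"].to_numpy(dtype=object)[qual],
                    None,
                ),
            })
            frames.append(sub)
        ends = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["arm", "pos", "other_pch", "other_arm"])
        )

        # per-arm sorted positions with prefix sums of the numerators
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for arm in self.arm_order:
            sub = ends[ends["arm"] == arm]
            pos = sub["pos"].to_numpy(dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            pch_flag = sub["other_pch"].to_numpy(dtype=np.int64)[order]
            other = sub["other_arm"].to_numpy(dtype=object)[order]
            cum_pch = np.concatenate([[0], np.cumsum(pch_flag)])
            cum_arm = np.zeros((pos.size + 1, len(self.arm_order)), dtype=np.int64)
            for j, a in enumerate(self.arm_order):
                cum_arm[1:, j] = np.cumsum(other == a)
            self._index[arm] = (pos, cum_pch, cum_arm)

    def counts(self, arm: str, start: int, end: int):
        """(n_pairs, n_pch, per-arm unique-PCH counts) for one window."""
        if arm not in self._index:
            return 0, 0, np.zeros(len(self.arm_order), dtype=np.int64)
        pos, cum_pch, cum_arm = self._index[arm]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return int(hi - lo), int(cum_pch[hi] - cum_pch[lo]), cum_arm[hi] - cum_arm[lo]

    def counts_many(self, arms: np.ndarray, starts: np.ndarray, ends: np.ndarray):
        """Vectorized (n_pairs, n_pch) for many windows; no per-arm breakdown."""
        n = len(arms)
        n_pairs = np.zeros(n, dtype=np.int64)
        n_pch = np.zeros(n, dtype=np.int64)
        arms = np.asarray(arms, dtype=object)
        for arm, (pos, cum_pch, _) in self._index.items():
            m = arms == arm
            if not m.any():
                continue
            lo = np.searchsorted(pos, starts[m], side="left")
            hi = np.searchsorted(pos, ends[m], side="left")
            n_pairs[m] = hi - lo
            n_pch[m] = cum_pch[hi] - cum_pch[lo]
        return n_pairs, n_pch


def eu_pch_fraction(
    scorer: EuPchScorer,
    region: QueryRegion,
    min_pairs: int = MIN_PAIRS_DEFAULT,
) -> EuPchResult:
    """Fraction of a window's informative pairs whose other end is PCH.

    All three heterochromatic end categories count toward the numerator;
    the per-arm breakdown uses uniquely-located PCH partners only. Windows
    below the informative-pair floor are excluded (a result state, not an
    error).
    """
    n_pairs, n_pch, per_arm = scorer.counts(region.arm, region.start, region.end)
    if n_pairs < min_pairs:
        return EuPchResult(
            region_id=region.region_id, arm=region.arm, size=region.size,
            n_pairs=n_pairs, frac_pch=float("nan"), per_arm_frac={},
            excluded=True, exclusion_reason=f"n_pairs {n_pairs} < {min_pairs}",
        )
    return EuPchResult(
        region_id=region.region_id, arm=region.arm, size=region.size,
        n_pairs=n_pairs, frac_pch=n_pch / n_pairs,
        per_arm_frac={
            a: c / n_pairs for a, c in zip(scorer.arm_order, per_arm) if c
        },
        excluded=False,
    )


# ---------------------------------------------------------------------------
# matched null ensemble


def size_quantile_bins(sizes: Sequence[int], n_bins: int = 4) -> np.ndarray:
    """Quartile bin index (0..n_bins-1) of each size within the query set."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        return np.zeros(0, dtype=int)
    qs = np.quantile(sizes, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.digitize(sizes, qs, right=True)


@dataclass
class NullEnsemble:
    """Matched random-region null sets, scored like the queries."""

    regions: pd.DataFrame  # set_id, template_id, arm, start, end, size,
    #                        size_bin, n_pairs, frac_pch, excluded
    n_sets: int
    seed: int | None

    def stratum(self, arm: str, size_bin: int) -> np.ndarray:
        sub = self.regions
        ok = (sub["arm"] == arm) & (sub["size_bin"] == size_bin) & (~sub["excluded"])
        return sub.loc[ok, "frac_pch"].to_numpy()


def _placement_space(
    annotation: GenomeAnnotation,
    exclusions: dict[str, Intervals],
) -> dict[str, Intervals]:
    eu = annotation.euchromatin()
    out = {}
    for arm, iv in eu.items():
        excl = exclusions.get(arm, Intervals.empty())
        out[arm] = iv.subtract(excl) if len(excl) else iv
    return out


def random_control_regions(
    annotation: GenomeAnnotation,
    exclusions: dict[str, Intervals],
    n: int,
    size_bp: int,
    seed: int | None = None,
) -> list[QueryRegion]:
    """Random fixed-size euchromatic regions avoiding the exclusions.

    Used for control cohorts and calibration runs; arms are drawn with
    probability proportional to their available placement space.
    """
    rng = np.random.default_rng(seed)
    space = {
        arm: iv for arm, iv in _placement_space(annotation, exclusions).items()
        if iv.total > size_bp
    }
    if not space:
        raise ComputationError("no euchromatic space for control regions")
    arms = list(space)
    arm_room = np.array(
        [np.maximum(space[a].ends - space[a].starts - size_bp + 1, 0).sum()
         for a in arms],
        dtype=float,
    )
    regions = []
    for i in range(n):
        a = arms[int(rng.choice(len(arms), p=arm_room / arm_room.sum()))]
        iv = space[a]
        room = np.maximum(iv.ends - iv.starts - size_bp + 1, 0)
        ok = room > 0
        k = int(rng.choice(np.flatnonzero(ok), p=room[ok] / room[ok].sum()))
        start = int(iv.starts[k] + rng.integers(0, room[k]))
        regions.append(
            QueryRegion(f"ctrl_{i}", a, start, start + size_bp, "control",
                        h3k9me2_enriched=False)
        )
    return regions


def sample_null_regions(
    annotation: GenomeAnnotation,
    exclusions: dict[str, Intervals],
    template: Sequence[QueryRegion],
    scorer: EuPchScorer,
    n_sets: int = N_NULL_SETS_DEFAULT,
    seed: int | None = None,
    min_pairs: int = MIN_PAIRS_DEFAULT,
    n_size_bins: int = 4,
) -> NullEnsemble:
    """Draw and score ``n_sets`` null sets matched to the template regions.

    Every set contains one random region per template region, on the same
    arm, avoiding the exclusion intervals (all H3K9me2-enriched intervals,
    not only the queries). Island templates are matched at their exact size;
    TE templates at a size drawn from templates in the same size-quantile
    bin. Null regions are scored with the same statistic and pair floor.
    """
    if not template:
        raise InputError("empty template")
    rng = np.random.default_rng(seed)
    space = _placement_space(annotation, exclusions)
    sizes = np.array([t.size for t in template])
    bins = size_quantile_bins(sizes, n_size_bins)

    rows = []
    for ti, (t, b) in enumerate(zip(template, bins)):
        iv = space.get(t.arm, Intervals.empty())
        if t.kind == "te":
            peers = sizes[bins == b]
            draw_sizes = rng.choice(peers, size=n_sets)
        else:
            draw_sizes = np.full(n_sets, t.size)
        for si in range(n_sets):
            size = int(draw_sizes[si])
            lens = iv.ends - iv.starts
            room = lens - size + 1
            ok = room > 0
            if not ok.any():
                raise ComputationError(
                    f"insufficient euchromatic space on arm {t.arm} "
                    f"for a {size}-bp null region"
                )
            p = room[ok] / room[ok].sum()
            k = rng.choice(np.flatnonzero(ok), p=p)
            start = int(iv.starts[k] + rng.integers(0, room[k]))
            rows.append((si, t.region_id, t.arm, start, start + size, size, int(b)))

    df = pd.DataFrame(
        rows,
        columns=["set_id", "template_id", "arm", "start", "end", "size", "size_bin"],
    )
    n_pairs, n_pch = scorer.counts_many(
        df["arm"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()
    )
    df["n_pairs"] = n_pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        df["frac_pch"] = np.where(n_pairs > 0, n_pch / np.maximum(n_pairs, 1), np.nan)
    df["excluded"] = n_pairs < min_pairs
    return NullEnsemble(regions=df, n_sets=n_sets, seed=seed)


def empirical_pvalue(
    result: EuPchResult,
    ensemble: NullEnsemble,
    size_bin: int,
) -> float | None:
    """Empirical p from the pooled (arm, size-quantile) null stratum.

    p = (1 + #{null >= observed}) / (1 + #null); None when the stratum is
    empty after the pair floor.
    """
    if result.excluded:
        raise InputError("cannot compute a p-value for an excluded region")
    nulls = ensemble.stratum(result.arm, size_bin)
    if nulls.size == 0:
        return None
    exceed = int(np.sum(nulls >= result.frac_pch))
    return (1 + exceed) / (1 + nulls.size)


def score_queries(
    scorer: EuPchScorer,
    regions: Sequence[QueryRegion],
    ensemble: NullEnsemble,
    min_pairs: int = MIN_PAIRS_DEFAULT,
    n_size_bins: int = 4,
) -> pd.DataFrame:
    """Score every query region and attach its empirical p-value."""
    bins = size_quantile_bins([r.size for r in regions], n_size_bins)
    rows = []
    for region, b in zip(regions, bins):
        res = eu_pch_fraction(scorer, region, min_pairs=min_pairs)
        p = None if res.excluded else empirical_pvalue(res, ensemble, int(b))
        rows.append({
            "region_id": res.region_id, "arm": res.arm, "size": res.size,
            "size_bin": int(b), "n_pairs": res.n_pairs, "frac_pch": res.frac_pch,
            "excluded": res.excluded, "empirical_p": p,
            "significant": (p is not None and p < 0.05),
            **{f"frac_{a}": res.per_arm_frac.get(a, 0.0) for a in scorer.arm_order},
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort-level binomial enrichment


def enrichment_binomial(k: int, n: int, p0: float = 0.05) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood convention).

    Probability mass of all outcomes j with P(X = j) <= P(X = k) under
    X ~ Binomial(n, p0). This is the convention that reproduces classical
    two-sided binomial tests on enrichment counts.
    """
    if not (0 <= k <= n) or n <= 0:
        raise InputError("require 0 <= k <= n, n > 0")
    if not (0.0 < p0 < 1.0):
        raise InputError("require 0 < p0 < 1")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
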