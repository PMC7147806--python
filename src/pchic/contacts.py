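"""PCH-PCH contact matrix and the sequential-exclusion interaction analysis.

Uniquely-locatable PCH pair ends are binned into fixed-size PCH windows
(100 kb by default) after removing short-range same-arm pairs (< 10 kb
separation), which reflect local polymer contacts rather than domain
organization. Interactions are then classified at three sequential levels:

* ``all`` — every retained pair; classes are the intra-arm aggregate plus
  each distinct arm pair;
* ``no_intra_arm`` — intra-arm cells excluded; classes are inter-arm (same
  chromosome) and inter-chromosome arm pairs;
* ``no_intra_chromosome`` — only arm pairs on different chromosomes remain.

Observed class proportions are compared against expectations built from
per-arm marginal weights (mappability-based or empirical), and against an
empirical null in which second-end arm labels are randomly permuted across
pairs, preserving both marginal arm distributions. One-sided p-values use
the (1 + exceed) / (1 + n_perm) convention and so never return zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import PairClass
from .genome import ArmWeights, ComputationError, InputError

LEVELS = ("all", "no_intra_arm", "no_intra_chromosome")

INTRA_ARM = "intra_arm"


def class_label(arm_a: str, arm_b: str, arm_order: Sequence[str]) -> str:
    """Canonical label for the interaction class of an (unordered) arm pair."""
    if arm_a == arm_b:
        return INTRA_ARM
    rank = {a: i for i, a in enumerate(arm_order)}
    a, b = sorted((arm_a, arm_b), key=rank.__getitem__)
    return f"{a}-{b}"


def _pair_allowed(arm_a, arm_b, level: str, chrom: Mapping[str, str]) -> bool:
    if level == "all":
        return True
    if level == "no_intra_arm":
        return arm_a != arm_b
    if level == "no_intra_chromosome":
        return chrom[arm_a] != chrom[arm_b]
    raise InputError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# contact matrix


@dataclass
class ContactMatrix:
    """Symmetric window-by-window contact counts over the PCH windows."""

    windows: pd.DataFrame  # columns arm, chromosome, index, start, end
    counts: np.ndarray
    n_dropped_close: int = 0
    n_outside: int = 0

    def __post_init__(self):
        n = len(self.windows)
        if self.counts.shape != (n, n):
            raise InputError("counts shape does not match window count")
        if not np.array_equal(self.counts, self.counts.T):
            raise InputError("contact matrix must be symmetric")

    @property
    def total_pairs(self) -> int:
        """Number of pairs represented (diagonal counted once)."""
        return int((self.counts.sum() + np.trace(self.counts)) // 2)

    def arm_pair_counts(self) -> pd.DataFrame:
        """Aggregate window counts into per-arm-pair totals (pairs, not cells)."""
        arms = self.windows["arm"].to_numpy()
        labels = pd.unique(arms)
        rows = []
        for i, a in enumerate(labels):
            ia = arms == a
            for b in labels[i:]:
                ib = arms == b
                block = self.counts[np.ix_(ia, ib)]
                if a == b:
                    n = int((block.sum() + np.trace(block)) // 2)
                else:
                    n = int(block.sum())
                rows.append((a, b, n))
        return pd.DataFrame(rows, columns=["arm_a", "arm_b", "count"])


def separation_filter(
    pairs: pd.DataFrame, min_separation_bp: int = 10_000
) -> tuple[pd.DataFrame, int]:
    """Drop same-arm pairs mapped within ``min_separation_bp`` of each other.

    Separation is undefined across arms, so cross-arm pairs always survive.
    Uses 5' mapping positions. Returns (surviving pairs, number dropped).
    """
    same = pairs["arm1"].to_numpy(dtype=object) == pairs["arm2"].to_numpy(dtype=object)
    dist = np.abs(pairs["pos1"].to_numpy() - pairs["pos2"].to_numpy())
    close = same & (dist < min_separation_bp)
    return pairs.loc[~close], int(close.sum())


def build_contact_matrix(
    pairs: pd.DataFrame,
    windows: pd.DataFrame,
    min_separation_bp: int = 10_000,
) -> ContactMatrix:
    """Tally PCH_PCH_UNIQUE pairs into the symmetric window matrix.

    Pairs are first restricted to the uniquely-locatable PCH class and the
    minimum-separation filter; each survivor increments its (window1,
    window2) cell symmetrically (diagonal allowed). Ends falling outside all
    windows are counted and the pair dropped.
    """
    sel = pairs[pairs["pair_class"] == PairClass.PCH_PCH_UNIQUE.value]
    sel, n_close = separation_filter(sel, min_separation_bp)

    nwin = len(windows)
    counts = np.zeros((nwin, nwin), dtype=np.int64)

    # per-arm sorted window lookup
    lookup = {}
    for arm, grp in windows.groupby("arm", sort=False):
        grp = grp.sort_values("start")
        lookup[arm] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["index"].to_numpy(),
        )

    def window_of(arm_col, pos_col):
        arms = sel[arm_col].to_numpy(dtype=object)
        poss = sel[pos_col].to_numpy()
        out = np.full(len(sel), -1, dtype=np.int64)
        for arm, (ws, we, wi) in lookup.items():
            m = arms == arm
            if not m.any():
                continue
            p = poss[m].astype(np.int64)
            k = np.searchsorted(ws, p, side="right") - 1
            ok = (k >= 0) & (p < we[np.clip(k, 0, len(we) - 1)])
            res = np.full(p.size, -1, dtype=np.int64)
            res[ok] = wi[k[ok]]
            out[m] = res
        return out

    w1 = window_of("arm1", "pos1")
    w2 = window_of("arm2", "pos2")
    ok = (w1 >= 0) & (w2 >= 0)
    n_outside = int((~ok).sum())
    # symmetric entry: each pair adds 1 to [i,j] and 1 to [j,i]; same-window
    # pairs therefore add 2 to the diagonal, halved below
    np.add.at(counts, (w1[ok], w2[ok]), 1)
    np.add.at(counts, (w2[ok], w1[ok]), 1)
    diag = np.arange(nwin)
    counts[diag, diag] //= 2
    return ContactMatrix(windows=windows, counts=counts,
                         n_dropped_close=n_close, n_outside=n_outside)


# ---------------------------------------------------------------------------
# sequential-exclusion partition


@dataclass
class InteractionPartition:
    level: str
    proportions: dict[str, float]
    retained: int


def partition_interactions(matrix: ContactMatrix, level: str) -> InteractionPartition:
    """Observed interaction-class proportions at one exclusion level."""
    if level not in LEVELS:
        raise InputError(f"unknown level {level!r}")
    arm_order = list(dict.fromkeys(matrix.windows["arm"]))
    chrom = dict(zip(matrix.windows["arm"], matrix.windows["chromosome"]))
    tall = matrix.arm_pair_counts()

    counts: dict[str, int] = {}
    for arm_a, arm_b, n in tall.itertuples(index=False):
        if not _pair_allowed(arm_a, arm_b, level, chrom):
            continue
        lab = class_label(arm_a, arm_b, arm_order)
        counts[lab] = counts.get(lab, 0) + int(n)
    total = sum(counts.values())
    if total == 0:
        raise ComputationError(f"no read pairs remain at level {level!r}")
    return InteractionPartition(
        level=level,
        proportions={k: v / total for k, v in counts.items()},
        retained=total,
    )


@dataclass
class ExpectationModel:
    level: str
    proportions: dict[str, float]
    source: str


def expected_proportions(
    weights: ArmWeights,
    level: str,
    chromosome_of: Mapping[str, str],
    arm_order: Sequence[str] | None = None,
) -> ExpectationModel:
    """Expected class proportions from per-arm marginal weights.

    Under independent end placement, an unordered arm pair (a, b) has mass
    w_a * w_b (a == b) or 2 * w_a * w_b (a != b); proportions are normalized
    over the classes allowed at the level. Invariant to rescaling weights.
    """
    if arm_order is None:
        arm_order = list(weights.weights)
    w = weights.weights
    mass: dict[str, float] = {}
    for i, a in enumerate(arm_order):
        for b in arm_order[i:]:
            if not _pair_allowed(a, b, level, chromosome_of):
                continue
            lab = class_label(a, b, arm_order)
            m = w[a] * w[b] if a == b else 2.0 * w[a] * w[b]
            mass[lab] = mass.get(lab, 0.0) + m
    total = sum(mass.values())
    if total <= 0:
        raise ComputationError(f"level {level!r} excludes all classes")
    return ExpectationModel(
        level=level,
        proportions={k: v / total for k, v in mass.items()},
        source=weights.source,
    )


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class PermutationResult:
    target_class: str
    level: str
    observed: float
    n_perm: int
    p_one_sided: float
    seed: int | None = None
    perm_proportions: np.ndarray | None = field(default=None, repr=False)


def _class_proportion_codes(
    c1: np.ndarray,
    c2: np.ndarray,
    chrom_codes: np.ndarray,
    target: tuple[int, int] | None,
    level: str,
) -> float:
    """Proportion of pairs in the target class among pairs allowed at level.

    Arms are integer codes; ``target`` is an unordered code pair, or None
    for the intra-arm aggregate. NaN when no pair is allowed.
    """
    if level == "all":
        allowed = np.ones(c1.size, dtype=bool)
    elif level == "no_intra_arm":
        allowed = c1 != c2
    else:
        allowed = chrom_codes[c1] != chrom_codes[c2]
    n = int(allowed.sum())
    if n == 0:
        return math.nan
    a1, a2 = c1[allowed], c2[allowed]
    if target is None:
        hit = a1 == a2
    else:
        ta, tb = target
        hit = ((a1 == ta) & (a2 == tb)) | ((a1 == tb) & (a2 == ta))
    return float(hit.sum()) / n


def permutation_test(
    arm1: Sequence[str] | np.ndarray,
    arm2: Sequence[str] | np.ndarray,
    target_class: str,
    level: str,
    chromosome_of: Mapping[str, str],
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationResult:
    """One-sided permutation test for a class proportion exceeding its null.

    The input pair list must already be restricted to the level's retained
    set. Each permutation shuffles the second-end arm labels across pairs;
    pairs falling into level-excluded classes after shuffling are dropped
    from that permutation's denominator. ``exhaustive=True`` enumerates all
    n! second-end orderings (n <= 9) instead of sampling.
    """
    arm1 = np.asarray(arm1, dtype=object)
    arm2 = np.asarray(arm2, dtype=object)
    if arm1.size == 0:
        raise ComputationError("no pairs supplied")
    if level not in LEVELS:
        raise InputError(f"unknown level {level!r}")

    arm_order = sorted(set(arm1) | set(arm2))
    code = {a: i for i, a in enumerate(arm_order)}
    c1 = np.fromiter((code[a] for a in arm1), np.int64, arm1.size)
    c2 = np.fromiter((code[a] for a in arm2), np.int64, arm2.size)
    chroms = sorted({chromosome_of[a] for a in arm_order})
    ccode = {c: i for i, c in enumerate(chroms)}
    chrom_codes = np.array([ccode[chromosome_of[a]] for a in arm_order])

    if target_class != INTRA_ARM:
        parts = target_class.split("-")
        if not set(parts) <= set(arm_order):
            raise InputError(f"target class {target_class!r} absent from pairs")
        if level == "no_intra_chromosome":
            ca, cb = (chromosome_of[p] for p in parts)
            if ca == cb:
                raise InputError(
                    f"target class {target_class!r} is excluded at level {level!r}"
                )
        target = (code[parts[0]], code[parts[1]])
    elif level != "all":
        raise InputError("intra_arm class is excluded at this level")
    else:
        target = None

    observed = _class_proportion_codes(c1, c2, chrom_codes, target, level)
    if math.isnan(observed):
        raise ComputationError("no pairs allowed at this level")

    if exhaustive:
        if arm1.size > 9:
            raise InputError("exhaustive enumeration limited to <= 9 pairs")
        props = np.array([
            _class_proportion_codes(
                c1, np.asarray(perm, dtype=np.int64), chrom_codes, target, level
            )
            for perm in itertools.permutations(c2)
        ])
        n_used = props.size
    else:
        rng = np.random.default_rng(seed)
        props = np.empty(n_perm)
        for i in range(n_perm):
            props[i] = _class_proportion_codes(
                c1, rng.permutation(c2), chrom_codes, target, level
            )
        n_used = n_perm

    valid = ~np.isnan(props)
    exceed = int(np.sum(props[valid] >= observed))
    # permutations with an empty denominator carry no evidence against the
    # null; they count toward n_perm but not toward exceedance
    p = (1 + exceed) / (1 + n_used)
    return PermutationResult(
        target_class=target_class, level=level, observed=observed,
        n_perm=n_used, p_one_sided=p, seed=seed, perm_proportions=props,
    )


def extract_arm_pairs(
    pairs: pd.DataFrame,
    level: str,
    chromosome_of: Mapping[str, str],
    min_separation_bp: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Arm-label arrays of PCH_PCH_UNIQUE pairs retained at a level."""
    sel = pairs[pairs["pair_class"] == PairClass.PCH_PCH_UNIQUE.value]
    sel, _ = separation_filter(sel, min_separation_bp)
    a1 = sel["arm1"].to_numpy(dtype=object)
    a2 = sel["arm2"].to_numpy(dtype=object)
    if level == "all":
        keep = np.ones(a1.size, dtype=bool)
    elif level == "no_intra_arm":
        keep = a1 != a2
    elif level == "no_intra_chromosome":
        c = np.vectorize(chromosome_of.__getitem__, otypes=[object])
        keep = c(a1) != c(a2)
    else:
        raise InputError(f"unknown level {level!r}")
    return a1[keep], a2[keep]
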