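"""Annotated-genome model: chromosome arms, the PCH/euchromatin partition,
repeat catalog, mappability, and the marginal arm weights used by the
contact statistics.

Coordinates are 0-based, half-open throughout. Pericentromeric
heterochromatin (PCH) is given as per-arm interval sets; "euchromatin" is
derived from it by removing an additional conservative buffer
(``eu_offset_bp``, default 0.5 Mb) adjacent to every PCH boundary, so that
nothing within 0.5 Mb of a PCH block is ever called euchromatic.
Chromosomes listed as fully heterochromatic (e.g. the Drosophila 4th and Y)
are PCH end to end and contribute no euchromatin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class ComputationError(RuntimeError):
    """A computation cannot proceed (e.g. empty class set, all-zero weights)."""


# ---------------------------------------------------------------------------
# interval primitives


class Intervals:
    """An immutable set of disjoint, sorted, half-open intervals on one arm."""

    __slots__ = ("starts", "ends")

    def __init__(self, starts: np.ndarray, ends: np.ndarray, *, validate: bool = True):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if validate:
            if starts.shape != ends.shape or starts.ndim != 1:
                raise InputError("starts/ends must be 1-D arrays of equal length")
            if np.any(ends <= starts):
                bad = int(np.argmax(ends <= starts))
                raise InputError(
                    f"malformed interval [{starts[bad]}, {ends[bad]}): end <= start"
                )
            if starts.size > 1:
                order = np.argsort(starts, kind="stable")
                starts, ends = starts[order], ends[order]
                if np.any(starts[1:] < ends[:-1]):
                    raise InputError("overlapping intervals")
        self.starts = starts
        self.ends = ends

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "Intervals":
        pairs = list(pairs)
        if not pairs:
            return cls(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        s, e = zip(*pairs)
        return cls(np.asarray(s), np.asarray(e))

    @classmethod
    def empty(cls) -> "Intervals":
        return cls(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return self.starts.size

    def __iter__(self):
        return iter(zip(self.starts.tolist(), self.ends.tolist()))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Intervals)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def __repr__(self) -> str:
        return f"Intervals({list(self)})"

    @property
    def total(self) -> int:
        """Total covered length in bp."""
        return int(np.sum(self.ends - self.starts))

    def contains(self, pos) -> np.ndarray:
        """Vectorized point membership for 0-based positions."""
        pos = np.asarray(pos)
        if self.starts.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self.starts, pos, side="right") - 1
        inside = idx >= 0
        idx = np.clip(idx, 0, self.starts.size - 1)
        return inside & (pos < self.ends[idx])

    def pad(self, flank: int, lo: int = 0, hi: int | None = None) -> "Intervals":
        """Expand every interval by ``flank`` on both sides, clip, and merge."""
        if self.starts.size == 0:
            return Intervals.empty()
        s = np.maximum(self.starts - flank, lo)
        e = self.ends + flank
        if hi is not None:
            e = np.minimum(e, hi)
        return merge_intervals(s, e)

    def complement(self, length: int) -> "Intervals":
        """Gaps of [0, length) not covered by this set."""
        edges_s, edges_e = [], []
        prev = 0
        for s, e in zip(self.starts, self.ends):
            if s > prev:
                edges_s.append(prev)
                edges_e.append(min(s, length))
            prev = max(prev, e)
        if prev < length:
            edges_s.append(prev)
            edges_e.append(length)
        return Intervals(np.asarray(edges_s, dtype=np.int64),
                         np.asarray(edges_e, dtype=np.int64), validate=False)

    def subtract(self, other: "Intervals", length: int | None = None) -> "Intervals":
        """Set difference self \\ other."""
        if length is None:
            length = int(self.ends[-1]) if self.ends.size else 0
        keep_s, keep_e = [], []
        for s, e in zip(self.starts, self.ends):
            cur = s
            # other intervals overlapping [s, e)
            lo = np.searchsorted(other.ends, s, side="right")
            hi = np.searchsorted(other.starts, e, side="left")
            for os_, oe_ in zip(other.starts[lo:hi], other.ends[lo:hi]):
                if os_ > cur:
                    keep_s.append(cur)
                    keep_e.append(min(os_, e))
                cur = max(cur, oe_)
            if cur < e:
                keep_s.append(cur)
                keep_e.append(e)
        return Intervals(np.asarray(keep_s, dtype=np.int64),
                         np.asarray(keep_e, dtype=np.int64), validate=False)

    def intersect(self, other: "Intervals") -> "Intervals":
        return self.subtract(other.complement(max(self._span(), other._span())))

    def _span(self) -> int:
        return int(self.ends[-1]) if self.ends.size else 0


def merge_intervals(starts, ends) -> Intervals:
    """Sort and merge possibly-overlapping intervals into a disjoint set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return Intervals.empty()
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return Intervals(np.asarray(out_s), np.asarray(out_e), validate=False)


# ---------------------------------------------------------------------------
# genome annotation


@dataclass(frozen=True)
class Arm:
    name: str
    chromosome: str
    length: int


@dataclass
class GenomeAnnotation:
    """Chromosome arms with their PCH intervals and the derived euchromatin.

    ``arms`` order is the input order and fixes the deterministic layout of
    every downstream matrix and report.
    """

    arms: list[Arm]
    pch: dict[str, Intervals]
    het_chromosomes: set[str] = field(default_factory=set)
    eu_offset_bp: int = 500_000

    def __post_init__(self):
        self.validate()

    # -- lookups ----------------------------------------------------------
    @property
    def arm_names(self) -> list[str]:
        return [a.name for a in self.arms]

    @property
    def chromosome_of(self) -> dict[str, str]:
        return {a.name: a.chromosome for a in self.arms}

    def arm_length(self, name: str) -> int:
        for a in self.arms:
            if a.name == name:
                return a.length
        raise InputError(f"unknown arm {name!r}")

    def validate(self) -> None:
        if self.eu_offset_bp < 0:
            raise InputError("eu_offset_bp must be >= 0")
        names = self.arm_names
        if len(set(names)) != len(names):
            raise InputError("duplicate arm names")
        for arm in self.arms:
            iv = self.pch.get(arm.name, Intervals.empty())
            if len(iv) and (iv.starts[0] < 0 or iv.ends[-1] > arm.length):
                raise InputError(f"PCH interval outside arm {arm.name}")
            if arm.chromosome in self.het_chromosomes:
                if iv.total != arm.length:
                    raise InputError(
                        f"arm {arm.name} of heterochromatic chromosome "
                        f"{arm.chromosome} is not fully covered by PCH"
                    )
        for name in self.pch:
            if name not in names:
                raise InputError(f"PCH record names unknown arm {name!r}")

    # -- derived ----------------------------------------------------------
    def euchromatin(self) -> dict[str, Intervals]:
        return derive_euchromatin(self)

    def total_pch_bp(self) -> int:
        return sum(self.pch.get(a.name, Intervals.empty()).total for a in self.arms)


def load_annotation(
    boundary_records: Iterable[tuple[str, int, int]] | pd.DataFrame,
    arms: Sequence[Arm] | Sequence[tuple[str, str, int]],
    het_chromosomes: Iterable[str] = (),
    eu_offset_bp: int = 500_000,
) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from BED-like PCH boundary records.

    Arms of a heterochromatic chromosome need no record: a full-arm PCH
    interval is created for them automatically.
    """
    arm_objs = [a if isinstance(a, Arm) else Arm(*a) for a in arms]
    known = {a.name for a in arm_objs}
    het = set(het_chromosomes)

    if isinstance(boundary_records, pd.DataFrame):
        records = list(
            boundary_records[["arm", "start", "end"]].itertuples(index=False, name=None)
        )
    else:
        records = list(boundary_records)

    by_arm: dict[str, list[tuple[int, int]]] = {}
    for arm_name, start, end in records:
        if arm_name not in known:
            raise InputError(f"unknown arm name {arm_name!r} in boundary records")
        by_arm.setdefault(arm_name, []).append((int(start), int(end)))

    pch: dict[str, Intervals] = {}
    for arm in arm_objs:
        if arm.chromosome in het and arm.name not in by_arm:
            pch[arm.name] = Intervals.from_pairs([(0, arm.length)])
        else:
            pch[arm.name] = Intervals.from_pairs(by_arm.get(arm.name, []))
    return GenomeAnnotation(arms=arm_objs, pch=pch,
                            het_chromosomes=het, eu_offset_bp=eu_offset_bp)


def derive_euchromatin(annotation: GenomeAnnotation) -> dict[str, Intervals]:
    """Per-arm euchromatin: arm minus PCH minus the conservative buffer.

    A buffer of ``eu_offset_bp`` adjacent to every PCH boundary is excluded,
    so euchromatin is always > eu_offset_bp away from PCH. Arms of fully
    heterochromatic chromosomes yield an empty set.
    """
    out: dict[str, Intervals] = {}
    for arm in annotation.arms:
        if arm.chromosome in annotation.het_chromosomes:
            out[arm.name] = Intervals.empty()
            continue
        pch = annotation.pch.get(arm.name, Intervals.empty())
        buffered = pch.pad(annotation.eu_offset_bp, lo=0, hi=arm.length)
        out[arm.name] = buffered.complement(arm.length)
    return out


def bin_pch_windows(annotation: GenomeAnnotation, window_bp: int = 100_000) -> pd.DataFrame:
    """Tile every PCH interval into fixed-size windows.

    Each interval is tiled left to right; a final partial window is retained.
    Returns a DataFrame with columns (arm, chromosome, index, start, end) in
    the annotation's fixed arm order; ``index`` is the global window index.
    """
    if window_bp <= 0:
        raise InputError("window_bp must be positive")
    rows = []
    chrom = annotation.chromosome_of
    for arm in annotation.arms:
        for s, e in annotation.pch.get(arm.name, Intervals.empty()):
            for ws in range(s, e, window_bp):
                rows.append((arm.name, chrom[arm.name], ws, min(ws + window_bp, e)))
    df = pd.DataFrame(rows, columns=["arm", "chromosome", "start", "end"])
    df.insert(2, "index", np.arange(len(df)))
    return df


# ---------------------------------------------------------------------------
# repeat catalog and mappability


@dataclass
class RepeatCatalog:
    """Catalog of heterochromatic simple/complex repeats by alignment-target name."""

    names: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise InputError("repeat names must be unique")
        self._set = frozenset(self.names)

    def is_repeat(self, target: str | None) -> bool:
        return target is not None and target in self._set

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class MappabilityTrack:
    """Per-arm intervals with mappability exactly 1; everything else is 0."""

    ones: dict[str, Intervals]

    def mappable_in(self, arm: str, region: Intervals) -> int:
        """Number of mappability-1 bases of ``arm`` falling inside ``region``."""
        track = self.ones.get(arm)
        if track is None or len(track) == 0 or len(region) == 0:
            return 0
        span = max(int(track.ends[-1]), int(region.ends[-1]))
        return track.subtract(region.complement(span)).total


@dataclass
class ArmWeights:
    """Nonnegative per-arm weights with provenance for expectation models."""

    weights: dict[str, float]
    source: str  # "mappability" | "empirical_reads"
    sex_adjusted: bool = False

    def __post_init__(self):
        vals = np.array(list(self.weights.values()), dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise InputError("weights must be finite and nonnegative")
        if not np.any(vals > 0):
            raise ComputationError("all arm weights are zero")

    def proportions(self) -> dict[str, float]:
        tot = sum(self.weights.values())
        return {k: v / tot for k, v in self.weights.items()}


#: mean copy number per nucleus under a 1:1 sex ratio
_COPY_NUMBER = {"autosome": 2.0, "X": 1.5, "Y": 0.5}


def _copy_number(chromosome: str) -> float:
    return _COPY_NUMBER.get(chromosome, _COPY_NUMBER["autosome"])


def arm_marginals(
    source: MappabilityTrack | pd.Series | Mapping[str, int],
    annotation: GenomeAnnotation,
    sex_adjust: bool = False,
) -> ArmWeights:
    """Marginal PCH weight per arm, from mappability or from read counts.

    Mappability mode: weight = mappability-1 bases within the arm's PCH,
    optionally multiplied by mean copy number under a 1:1 sex ratio
    (autosomes 2, X 1.5, Y 0.5). Empirical mode (a per-arm count of
    uniquely-mapped PCH read ends): counts are used as-is — ploidy is
    already reflected in the reads, so ``sex_adjust`` is ignored.
    """
    weights: dict[str, float] = {}
    if isinstance(source, MappabilityTrack):
        for arm in annotation.arms:
            w = float(source.mappable_in(arm.name, annotation.pch.get(arm.name, Intervals.empty())))
            if sex_adjust:
                w *= _copy_number(arm.chromosome)
            weights[arm.name] = w
        return ArmWeights(weights, source="mappability", sex_adjusted=sex_adjust)

    counts = dict(source)
    for arm in annotation.arms:
        weights[arm.name] = float(counts.get(arm.name, 0))
    return ArmWeights(weights, source="empirical_reads", sex_adjusted=False)
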