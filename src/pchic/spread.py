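"""TE-induced H3K9me2 spread from between-strain ChIP enrichment contrasts.

A TE insertion present in the focal strain but absent from wildtype strains
can nucleate H3K9me2 that spreads into flanking single-copy DNA. Because
homologous flanks exist in all strains, the spread is measured as the
per-bin excess of the focal strain's ChIP/input log-ratio over the wildtype
mean — a shape-free contrast that captures broad or shallow enrichment that
peak callers miss. The spread extent per side is the maximal contiguous run
of 1-kb bins (from the insertion outward) exceeding a log2 threshold; a TE
"spreads" when the total extent reaches 1 kb. The magnitude is the mean
percent increase over the spread bins.

Population frequencies of TEs with vs without PCH contact are compared with
a Welch two-sample t-test on the raw frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import InputError, Intervals

BIN_BP_DEFAULT = 1_000
MAX_EXTENT_BP_DEFAULT = 20_000
DELTA_DEFAULT = 0.5  # log2 excess over wildtype


Coverage = Mapping[str, pd.DataFrame]  # arm -> DataFrame(start, end, value)


def _bin_means(cov: pd.DataFrame, edges: np.ndarray) -> np.ndarray:
    """Length-weighted mean coverage in each [edges[i], edges[i+1]) bin."""
    starts = cov["start"].to_numpy(dtype=np.int64)
    ends = cov["end"].to_numpy(dtype=np.int64)
    vals = cov["value"].to_numpy(dtype=float)
    out = np.zeros(edges.size - 1)
    for i in range(edges.size - 1):
        lo, hi = edges[i], edges[i + 1]
        s = np.maximum(starts, lo)
        e = np.minimum(ends, hi)
        w = np.maximum(e - s, 0)
        tot = w.sum()
        out[i] = float((vals * w).sum() / tot) if tot > 0 else 0.0
    return out


def _total_mass(cov: Coverage) -> float:
    tot = 0.0
    for df in cov.values():
        tot += float(
            (df["value"].to_numpy() * (df["end"] - df["start"]).to_numpy()).sum()
        )
    return tot


@dataclass
class EnrichmentProfile:
    """Binned log2 ChIP/input enrichment around one TE insertion."""

    anchor_arm: str
    anchor_pos: int
    bin_bp: int
    offsets: np.ndarray  # signed bin indices, -K..-1, 1..K (no zero bin)
    values: np.ndarray  # log2 enrichment per bin; NaN where masked
    strain: str = ""

    def side(self, sign: int) -> np.ndarray:
        """Values ordered outward from the anchor on one side (sign = +/-1)."""
        if sign > 0:
            idx = np.argsort(self.offsets[self.offsets > 0])
            return self.values[self.offsets > 0][idx]
        idx = np.argsort(-self.offsets[self.offsets < 0])
        return self.values[self.offsets < 0][idx]


def enrichment_profile(
    chip_cov: Coverage,
    input_cov: Coverage,
    anchor: tuple[str, int],
    bin_bp: int = BIN_BP_DEFAULT,
    max_extent_bp: int = MAX_EXTENT_BP_DEFAULT,
    pseudocount: float = 1.0,
    normalize: bool = True,
    mask: Mapping[str, Intervals] | None = None,
    strain: str = "",
) -> EnrichmentProfile:
    """Per-bin log2((ChIP + pc) / (input + pc)) around an anchor position.

    Tracks are depth-normalized to reads-per-million equivalents before the
    ratio when ``normalize`` is set (skip it for tracks already on a common
    depth scale). Bins overlapping ``mask`` intervals (other TEs, islands)
    are set to NaN.
    """
    arm, pos = anchor
    if bin_bp <= 0:
        raise InputError("bin_bp must be positive")
    if arm not in chip_cov or arm not in input_cov:
        raise InputError(f"anchor arm {arm!r} not covered")

    k = max_extent_bp // bin_bp
    edges = pos + np.arange(-k, k + 1) * bin_bp
    offsets = np.concatenate([np.arange(-k, 0), np.arange(1, k + 1)])

    chip = _bin_means(chip_cov[arm], edges)
    inp = _bin_means(input_cov[arm], edges)
    if normalize:
        chip = chip * 1e6 / _total_mass(chip_cov)
        inp = inp * 1e6 / _total_mass(input_cov)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2((chip + pseudocount) / (inp + pseudocount))
    values[~np.isfinite(values)] = np.nan

    if mask is not None and arm in mask and len(mask[arm]):
        miv = mask[arm]
        for i in range(edges.size - 1):
            lo, hi = edges[i], edges[i + 1]
            if np.any((miv.starts < hi) & (miv.ends > lo)):
                values[i] = np.nan
    return EnrichmentProfile(
        anchor_arm=arm, anchor_pos=pos, bin_bp=bin_bp,
        offsets=offsets, values=values, strain=strain,
    )


@dataclass
class SpreadEstimate:
    te_id: str
    extent_left_kb: float
    extent_right_kb: float
    extent_total_kb: float
    magnitude_pct: float
    spreading: bool


def spread_extent(
    focal: EnrichmentProfile,
    wildtypes: Sequence[EnrichmentProfile],
    delta: float = DELTA_DEFAULT,
    min_extent_bp: int = 1_000,
    te_id: str = "",
) -> SpreadEstimate:
    """Extent and magnitude of focal-over-wildtype enrichment around a TE.

    Per side, the extent is the length of the maximal contiguous run of bins
    (starting at the bin adjacent to the insertion) in which the focal
    enrichment exceeds the wildtype mean by more than ``delta`` (log2). A
    masked (NaN) bin terminates the run. The magnitude is the mean percent
    increase, 100 * (2^(focal - wt) - 1), over the spread bins.
    """
    if not wildtypes:
        raise InputError("at least one wildtype profile required")
    for wt in wildtypes:
        if not np.array_equal(wt.offsets, focal.offsets) or wt.bin_bp != focal.bin_bp:
            raise InputError("profiles must share the same bin grid")
    wt_mean = np.nanmean(np.vstack([wt.values for wt in wildtypes]), axis=0)
    diff_all = focal.values - wt_mean

    def run_length(sign: int) -> tuple[int, list[float]]:
        order = np.argsort(sign * focal.offsets[sign * focal.offsets > 0])
        diffs = diff_all[sign * focal.offsets > 0][order]
        run, vals = 0, []
        for d in diffs:
            if np.isnan(d) or d <= delta:
                break
            run += 1
            vals.append(float(d))
        return run, vals

    nl, vl = run_length(-1)
    nr, vr = run_length(+1)
    spread_vals = vl + vr
    total_bp = (nl + nr) * focal.bin_bp
    magnitude = (
        float(np.mean([100.0 * (2.0 ** d - 1.0) for d in spread_vals]))
        if spread_vals
        else 0.0
    )
    return SpreadEstimate(
        te_id=te_id or f"{focal.anchor_arm}:{focal.anchor_pos}",
        extent_left_kb=nl * focal.bin_bp / 1_000,
        extent_right_kb=nr * focal.bin_bp / 1_000,
        extent_total_kb=total_bp / 1_000,
        magnitude_pct=magnitude,
        spreading=total_bp >= min_extent_bp,
    )


# ---------------------------------------------------------------------------
# population-frequency contrast


@dataclass
class FrequencyComparison:
    mean_with: float
    mean_without: float
    t_statistic: float
    p_value: float
    with_pch: np.ndarray
    without_pch: np.ndarray


def compare_population_frequencies(
    with_pch: Sequence[float],
    without_pch: Sequence[float],
) -> FrequencyComparison:
    """Welch two-sample t-test on TE population frequencies by PCH contact.

    Frequencies must lie in [0, 1]. With a group of size < 2 the test is
    undefined (NaN statistics) but group means are still returned.
    """
    a = np.asarray(with_pch, dtype=float)
    b = np.asarray(without_pch, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    for v in (a, b):
        if np.any((v < 0) | (v > 1)):
            raise InputError("frequencies must lie in [0, 1]")
    if a.size < 2 or b.size < 2:
        t = p = math.nan
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return FrequencyComparison(
        mean_with=float(a.mean()), mean_without=float(b.mean()),
        t_statistic=float(t), p_value=float(p),
        with_pch=a, without_pch=b,
    )
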