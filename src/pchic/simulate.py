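"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a small multi-arm genome in which every pipeline
stage is exercisable and planted parameters are recoverable:

* five euchromatic arms (2L/2R/3L/3R, 1.5 Mb each) carrying a 300 kb PCH
  block at the centromeric end, plus a fully heterochromatic 300 kb 4th
  chromosome — a desk-scale cartoon of the Drosophila karyotype;
* Hi-C pairs with power-law intra-arm distance decay (exponent alpha,
  default 1, the polymer-physics regime), a uniform cross-arm background,
  planted arm-pair contact multipliers (inter-arm 2L-2R/3L-3R and the
  exceptional 3L-4 association), and optional planted euchromatin-PCH
  multipliers inside designated query windows;
* a MAPQ model: a configurable slice of each PCH block is multi-copy
  (mappability 0, emitting MAPQ-0 ends), PCH ends also emit repeat-library
  alignments at a configurable rate, and a small mid-MAPQ fraction
  exercises the ambiguous category; a low rate of canonical-TE reads
  exercises the TE pre-filter;
* strain-paired ChIP/input coverage with islands enriched in all strains
  and TE-adjacent spread in the focal strain only;
* bimodal FISH distance mixtures and a two-group TE population-frequency
  table.

All randomness flows from the config seed (or an explicit per-call seed);
identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    Arm,
    GenomeAnnotation,
    InputError,
    Intervals,
    MappabilityTrack,
    RepeatCatalog,
    merge_intervals,
)

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ArmSpec:
    name: str
    chromosome: str
    length: int
    pch_start: int
    pch_end: int


DEFAULT_ARMS: tuple[ArmSpec, ...] = (
    ArmSpec("2L", "2", 1_500_000, 1_200_000, 1_500_000),
    ArmSpec("2R", "2", 1_500_000, 0, 300_000),
    ArmSpec("3L", "3", 1_500_000, 1_200_000, 1_500_000),
    ArmSpec("3R", "3", 1_500_000, 0, 300_000),
    ArmSpec("4", "4", 300_000, 0, 300_000),
)

#: planted arm-pair contact multipliers: pericentric inter-arm preferences
#: and the exceptional 3rd-4th chromosome association
DEFAULT_PAIR_MULTIPLIERS: tuple[tuple[frozenset, float], ...] = (
    (frozenset({"2L", "2R"}), 3.0),
    (frozenset({"3L", "3R"}), 3.0),
    (frozenset({"3L", "4"}), 10.0),
    (frozenset({"3R", "4"}), 4.0),
)

REPEAT_NAMES = ("AAGAG", "AACAC", "AATAT", "dodeca", "Rsp")


@dataclass
class SyntheticConfig:
    """Seeds and generative parameters for all simulators."""

    seed: int = 0
    arms: tuple[ArmSpec, ...] = DEFAULT_ARMS
    het_chromosomes: frozenset = frozenset({"4"})
    eu_offset_bp: int = 500_000
    window_bp: int = 100_000

    # Hi-C contact model
    alpha: float = 1.0  # intra-arm decay exponent, P(s) ~ s^-alpha
    min_decay_bp: int = 1_000  # lower cutoff; pairs below the 10 kb
    #                            separation filter are still emitted
    intra_arm_weight: float = 0.96  # probability the partner stays on the arm
    pair_multipliers: tuple = DEFAULT_PAIR_MULTIPLIERS
    # chromocenter coalescence: a cross-arm partner of a PCH end lands inside
    # the target arm's PCH block with this probability (uniform otherwise);
    # arm-pair multipliers likewise act on PCH-origin ends only
    pch_cross_affinity: float = 0.6

    # MAPQ / read-category model
    multi_frac: float = 0.20  # fraction of each PCH block that is multi-copy
    repeat_rate: float = 0.10  # PCH ends re-emitted as repeat-library hits
    midq_rate: float = 0.02  # ends with 0 < MAPQ < 30 (ambiguous)
    te_rate: float = 0.01  # ends flagged as canonical-TE alignments

    # feature placement
    n_islands: int = 12
    island_size_bp: int = 2_000
    n_tes: int = 8
    feature_gap_bp: int = 50_000  # min spacing so ChIP masks never collide

    # ChIP model
    chip_bin_bp: int = 1_000
    chip_background_depth: float = 100.0
    island_fold: float = 4.0  # islands enriched in every strain
    te_spread_bp: int = 4_000  # total planted spread (split across sides)
    te_fold: float = 2.0
    chip_sigma: float = 0.1  # per-bin log2 noise on the ChIP track

    # FISH mixture: pi * |N(0, sigma0)| + (1 - pi) * N(mu1, sigma1), >= 0
    fish_pi: float = 0.4
    fish_sigma0: float = 0.1
    fish_mu1: float = 1.5
    fish_sigma1: float = 0.3
    fish_radius_mu: float = 2.5
    fish_radius_sigma: float = 0.3

    # population-frequency model (zero-inflated exponential per group)
    popfreq_n_with: int = 14
    popfreq_n_without: int = 92
    popfreq_zero_with: float = 0.80
    popfreq_zero_without: float = 0.55
    popfreq_scale_with: float = 5e-3
    popfreq_scale_without: float = 2.1e-2

    def __post_init__(self):
        if self.alpha <= 0:
            raise InputError("alpha must be positive")
        if not 0.0 <= self.fish_pi <= 1.0:
            raise InputError("fish_pi must lie in [0, 1]")
        for key, mult in self.pair_multipliers:
            if mult <= 0:
                raise InputError("pair multipliers must be positive")

    def multiplier(self, arm_a: str, arm_b: str) -> float:
        key = frozenset({arm_a, arm_b})
        for k, m in self.pair_multipliers:
            if k == key:
                return m
        return 1.0


@dataclass
class ToyGenome:
    """All genome-side artifacts for one synthetic run."""

    annotation: GenomeAnnotation
    mappability: MappabilityTrack
    catalog: RepeatCatalog
    islands: pd.DataFrame  # arm, start, end, name
    tes: pd.DataFrame  # arm, start, end, name, spreading
    multi_segments: dict[str, Intervals]
    config: SyntheticConfig


def _derive_seed(seed: int, stream: int) -> int:
    """Independent child seed < 2**31 for a named random stream."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def make_toy_genome(config: SyntheticConfig, seed: Optional[int] = None) -> ToyGenome:
    """Build annotation, mappability, repeat catalog and feature BEDs.

    Mappability is 1 everywhere except a configured multi-copy slice in the
    middle of each PCH block (the source of MAPQ-0 reads). Islands and TE
    insertions are placed in derived euchromatin only — hence always more
    than ``eu_offset_bp`` from a PCH boundary — at ChIP-bin-aligned,
    well-separated positions.
    """
    rng = np.random.default_rng(
        _derive_seed(config.seed if seed is None else seed, 1)
    )
    arms = [Arm(a.name, a.chromosome, a.length) for a in config.arms]
    pch = {
        a.name: Intervals.from_pairs([(a.pch_start, a.pch_end)]) for a in config.arms
    }
    annotation = GenomeAnnotation(
        arms=arms, pch=pch, het_chromosomes=set(config.het_chromosomes),
        eu_offset_bp=config.eu_offset_bp,
    )

    multi_segments: dict[str, Intervals] = {}
    ones: dict[str, Intervals] = {}
    for a in config.arms:
        block = a.pch_end - a.pch_start
        mlen = int(round(config.multi_frac * block))
        ms = a.pch_start + (block - mlen) // 2
        seg = Intervals.from_pairs([(ms, ms + mlen)]) if mlen else Intervals.empty()
        multi_segments[a.name] = seg
        ones[a.name] = seg.complement(a.length)
    mappability = MappabilityTrack(ones=ones)

    eu = annotation.euchromatin()
    islands = _place_features(
        rng, eu, n=config.n_islands, size=config.island_size_bp,
        gap=config.feature_gap_bp, prefix="island",
        chip_bin=config.chip_bin_bp, taken=None,
    )
    taken = {
        arm: merge_intervals(g["start"].to_numpy(), g["end"].to_numpy()).pad(
            config.feature_gap_bp
        )
        for arm, g in islands.groupby("arm")
    }
    tes = _place_features(
        rng, eu, n=config.n_tes, size=0, gap=config.feature_gap_bp,
        prefix="te", chip_bin=config.chip_bin_bp, taken=taken,
    )
    # roughly two thirds of euchromatic TEs nucleate H3K9me2 spread
    spreading = np.zeros(len(tes), dtype=bool)
    spreading[: max(1, int(round(0.65 * len(tes))))] = True
    tes["spreading"] = spreading

    catalog = RepeatCatalog(names=REPEAT_NAMES)
    return ToyGenome(
        annotation=annotation, mappability=mappability, catalog=catalog,
        islands=islands, tes=tes, multi_segments=multi_segments, config=config,
    )


def _place_features(
    rng: np.random.Generator,
    euchromatin: Mapping[str, Intervals],
    n: int,
    size: int,
    gap: int,
    prefix: str,
    chip_bin: int,
    taken: Optional[dict[str, Intervals]] = None,
) -> pd.DataFrame:
    """Place ``n`` features of ``size`` bp in euchromatin, >= gap apart."""
    arms = [a for a, iv in euchromatin.items() if iv.total > size + 2 * gap]
    if not arms:
        raise InputError("no euchromatic arm can host the requested features")
    placed: dict[str, list[tuple[int, int]]] = {a: [] for a in arms}
    if taken:
        for a in arms:
            placed[a].extend(list(taken.get(a, Intervals.empty())))
    rows = []
    attempts = 0
    i = 0
    while i < n:
        attempts += 1
        if attempts > 200 * n:
            raise InputError(
                f"cannot place {n} features of {size} bp with {gap} bp spacing"
            )
        arm = arms[int(rng.integers(0, len(arms)))]
        iv = euchromatin[arm]
        lens = iv.ends - iv.starts
        room = lens - size - 2 * gap
        ok = room > 0
        if not ok.any():
            continue
        k = int(rng.choice(np.flatnonzero(ok), p=room[ok] / room[ok].sum()))
        start = int(iv.starts[k] + gap + rng.integers(0, room[k]))
        start = (start // chip_bin) * chip_bin  # bin-aligned for exact ChIP bins
        end = start + max(size, 1)
        if any(s < end + gap and e + gap > start for s, e in placed[arm]):
            continue
        placed[arm].append((start, end))
        rows.append((arm, start, end, f"{prefix}_{i}"))
        i += 1
    df = pd.DataFrame(rows, columns=["arm", "start", "end", "name"])
    return df.sort_values(["arm", "start"], ignore_index=True)


# ---------------------------------------------------------------------------
# Hi-C pair simulation


def _power_law_sample(rng, u, s_min: float, s_max: float, alpha: float) -> np.ndarray:
    """Inverse-CDF draw from a density ~ s^-alpha on [s_min, s_max]."""
    if abs(alpha - 1.0) < 1e-12:
        return s_min * (s_max / s_min) ** u
    a1 = 1.0 - alpha
    return (s_min**a1 + u * (s_max**a1 - s_min**a1)) ** (1.0 / a1)


def _power_law_cdf(s, s_min: float, s_max: float, alpha: float):
    s = np.clip(np.asarray(s, dtype=float), s_min, s_max)
    if abs(alpha - 1.0) < 1e-12:
        return np.log(s / s_min) / np.log(s_max / s_min)
    a1 = 1.0 - alpha
    return (s**a1 - s_min**a1) / (s_max**a1 - s_min**a1)


def pch_partner_probability(
    toy: ToyGenome, arm: str, position: int
) -> float:
    """Model probability that the partner of an end at (arm, position) is PCH.

    Sums the cross-arm background mass landing in PCH blocks and the
    intra-arm decay mass overlapping the arm's own PCH. Used to calibrate
    planted euchromatin-PCH multipliers.
    """
    cfg = toy.config
    specs = {a.name: a for a in cfg.arms}
    me = specs[arm]
    others = [a for a in cfg.arms if a.name != arm]
    # euchromatic origin: plain length-weighted destinations, uniform landing
    raw = np.array([a.length for a in others], dtype=float)
    cross_prob = (1.0 - cfg.intra_arm_weight) * raw / raw.sum()
    cross = sum(
        p * (a.pch_end - a.pch_start) / a.length for p, a in zip(cross_prob, others)
    )

    # intra-arm decay mass overlapping the arm's own PCH block. Distance
    # signs are symmetric, but a draw falling off the arm edge is reflected
    # to the other side, so distances longer than the shorter flank land on
    # the longer flank with full (not half) probability.
    s_min, s_max = cfg.min_decay_bp, me.length
    lo, hi = me.pch_start, me.pch_end
    intra = 0.0
    if not (lo <= position < hi):

        def F(s):
            return float(_power_law_cdf(s, s_min, s_max, cfg.alpha))

        if position < lo:  # PCH on the right flank
            a, b = lo - position, hi - position
            flank = position  # reflected when s exceeds the left flank
        else:  # PCH on the left flank
            a, b = position - hi + 1, position - lo
            flank = me.length - position
        m_full = F(b) - F(a)
        m_reflected = max(0.0, F(b) - F(max(a, flank)))
        intra = 0.5 * m_full + 0.5 * m_reflected
    return float(cross + cfg.intra_arm_weight * intra)


def simulate_hic_pairs(
    toy: ToyGenome,
    n_pairs: int,
    seed: Optional[int] = None,
    boosted_windows: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Draw aligned Hi-C read pairs from the synthetic contact model.

    End 1 is uniform over the genome; end 2 stays on the same arm with the
    intra-arm weight (distance then follows the power-law decay, reflected
    at arm edges) or moves to another arm with probability proportional to
    arm length — times the planted arm-pair multiplier when end 1 lies in
    PCH. Cross-arm partners of PCH ends land inside the target arm's PCH
    with the chromocenter-coalescence affinity, uniformly otherwise.
    ``boosted_windows`` (columns arm, start, end, mult) plants
    euchromatin-PCH enrichment: ends inside a window redirect their partner
    to a uniform PCH position often enough to multiply the window's
    PCH-partner probability by ~mult. MAPQ, repeat-library and canonical-TE
    emissions are applied per end afterwards.

    Returns an unclassified pairs table (0-based positions; repeat ends have
    no arm/position).
    """
    if n_pairs <= 0:
        raise InputError("n_pairs must be positive")
    cfg = toy.config
    rng = np.random.default_rng(
        _derive_seed(cfg.seed if seed is None else seed, 2)
    )
    specs = list(cfg.arms)
    n_arms = len(specs)
    lengths = np.array([a.length for a in specs], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    total = int(cum[-1])

    # per-arm categorical over destination arms; PCH-origin ends carry the
    # planted arm-pair multipliers (chromocenter preferences), euchromatic
    # origins use plain length weighting
    def dest_table(with_multipliers: bool) -> np.ndarray:
        table = np.zeros((n_arms, n_arms))
        for i, a in enumerate(specs):
            w = np.zeros(n_arms)
            for j, b in enumerate(specs):
                if i == j:
                    w[j] = cfg.intra_arm_weight
                else:
                    w[j] = lengths[j] * (
                        cfg.multiplier(a.name, b.name) if with_multipliers else 1.0
                    )
            others = np.arange(n_arms) != i
            w[others] *= (1.0 - cfg.intra_arm_weight) / w[others].sum()
            table[i] = np.cumsum(w)
        return table

    dest_cum_pch = dest_table(True)
    dest_cum_eu = dest_table(False)
    pch_starts_arr = np.array([a.pch_start for a in specs], dtype=np.int64)
    pch_ends_arr = np.array([a.pch_end for a in specs], dtype=np.int64)
    pch_lens_arr = (pch_ends_arr - pch_starts_arr).astype(np.int64)

    g1 = rng.integers(0, total, n_pairs)
    arm1 = np.searchsorted(cum, g1, side="right") - 1
    pos1 = g1 - cum[arm1]
    origin_pch = (pos1 >= pch_starts_arr[arm1]) & (pos1 < pch_ends_arr[arm1])

    u = rng.random(n_pairs)
    arm2 = np.where(
        origin_pch,
        (u[:, None] > dest_cum_pch[arm1]).sum(axis=1),
        (u[:, None] > dest_cum_eu[arm1]).sum(axis=1),
    )

    pos2 = np.empty(n_pairs, dtype=np.int64)
    same = arm2 == arm1
    if same.any():
        la = lengths[arm1[same]].astype(float)
        s = _power_law_sample(
            rng, rng.random(int(same.sum())), cfg.min_decay_bp, la, cfg.alpha
        ).astype(np.int64)
        sign = rng.choice([-1, 1], size=int(same.sum()))
        cand = pos1[same] + sign * s
        # reflect at the arm edge; rare doubly-out cases fall back to uniform
        out = (cand < 0) | (cand >= lengths[arm1[same]])
        cand[out] = pos1[same][out] - sign[out] * s[out]
        still = (cand < 0) | (cand >= lengths[arm1[same]])
        if still.any():
            cand[still] = rng.integers(0, lengths[arm1[same]][still])
        pos2[same] = cand
    if (~same).any():
        cross = ~same
        pos2[cross] = rng.integers(0, lengths[arm2[cross]])
        # chromocenter coalescence: cross-arm partners of PCH ends land in
        # the target arm's PCH with the configured affinity
        coalesce = cross & origin_pch & (
            rng.random(n_pairs) < cfg.pch_cross_affinity
        )
        if coalesce.any():
            tgt = arm2[coalesce]
            pos2[coalesce] = pch_starts_arr[tgt] + rng.integers(
                0, pch_lens_arr[tgt]
            )

    arm_names = np.array([a.name for a in specs], dtype=object)

    # planted euchromatin-PCH multipliers
    if boosted_windows is not None and len(boosted_windows):
        pch_lens = np.array([a.pch_end - a.pch_start for a in specs], dtype=float)
        pch_p = pch_lens / pch_lens.sum()
        pch_starts = np.array([a.pch_start for a in specs])
        name_to_idx = {a.name: i for i, a in enumerate(specs)}
        for row in boosted_windows.itertuples(index=False):
            ai = name_to_idx[row.arm]
            center = (int(row.start) + int(row.end)) // 2
            q_hat = pch_partner_probability(toy, row.arm, center)
            r = min(0.9, (float(row.mult) - 1.0) * q_hat)
            if r <= 0:
                continue
            for (arm_e, pos_e, arm_o, pos_o) in (
                (arm1, pos1, arm2, pos2),
                (arm2, pos2, arm1, pos1),
            ):
                inwin = (
                    (arm_e == ai) & (pos_e >= int(row.start)) & (pos_e < int(row.end))
                )
                redir = inwin & (rng.random(n_pairs) < r)
                k = int(redir.sum())
                if not k:
                    continue
                tgt = rng.choice(n_arms, size=k, p=pch_p)
                arm_o[redir] = tgt
                pos_o[redir] = pch_starts[tgt] + rng.integers(
                    0, pch_lens[tgt].astype(np.int64)
                )

    # per-end read-category emissions
    def finalize(arm_idx, pos):
        names = arm_names[arm_idx].copy()
        pos = pos.copy()
        mapq = np.full(n_pairs, 60, dtype=np.int64)
        repeat = np.full(n_pairs, None, dtype=object)
        te = rng.random(n_pairs) < cfg.te_rate

        in_pch = np.zeros(n_pairs, dtype=bool)
        in_multi = np.zeros(n_pairs, dtype=bool)
        for i, a in enumerate(specs):
            m = arm_idx == i
            if not m.any():
                continue
            in_pch[m] = (pos[m] >= a.pch_start) & (pos[m] < a.pch_end)
            seg = toy.multi_segments[a.name]
            if len(seg):
                in_multi[m] = seg.contains(pos[m])
        mapq[in_multi] = 0
        as_repeat = in_pch & ~in_multi & (rng.random(n_pairs) < cfg.repeat_rate)
        midq = (rng.random(n_pairs) < cfg.midq_rate) & ~in_multi & ~as_repeat
        mapq[midq] = 15
        rep_choice = rng.integers(0, len(REPEAT_NAMES), n_pairs)
        repeat[as_repeat] = np.array(REPEAT_NAMES, dtype=object)[
            rep_choice[as_repeat]
        ]
        names = names.astype(object)
        names[as_repeat] = None
        pos[as_repeat] = -1  # repeat ends carry no genomic coordinate
        return names, pos, mapq, repeat, te

    a1n, p1, q1, r1, t1 = finalize(arm1, pos1)
    a2n, p2, q2, r2, t2 = finalize(arm2, pos2)

    return pd.DataFrame({
        "read_id": np.arange(n_pairs),
        "arm1": a1n, "pos1": p1, "mapq1": q1, "repeat1": r1, "te1": t1,
        "arm2": a2n, "pos2": p2, "mapq2": q2, "repeat2": r2, "te2": t2,
    })


# ---------------------------------------------------------------------------
# ChIP coverage simulation


def simulate_chip_profiles(
    toy: ToyGenome,
    seed: Optional[int] = None,
    strains: Sequence[str] = ("focal", "wt1", "wt2"),
) -> dict[str, dict[str, "pd.DataFrame"]]:
    """Per-strain ChIP and input coverage (bedGraph-style frames per arm).

    Input tracks are flat at the background depth. ChIP tracks carry island
    enrichment in every strain (islands are shared, non-TE features) and the
    planted TE-adjacent spread in the focal strain only, plus per-bin log2
    noise of width ``chip_sigma``. Values are on a common depth scale.
    """
    cfg = toy.config
    rng = np.random.default_rng(
        _derive_seed(cfg.seed if seed is None else seed, 3)
    )
    bin_bp = cfg.chip_bin_bp
    out: dict[str, dict[str, pd.DataFrame]] = {}

    half = (cfg.te_spread_bp // 2 // bin_bp) * bin_bp  # per-side extent

    for strain in strains:
        chip_frames: dict[str, pd.DataFrame] = {}
        input_frames: dict[str, pd.DataFrame] = {}
        for a in cfg.arms:
            nbins = a.length // bin_bp
            edges = np.arange(nbins + 1) * bin_bp
            log_e = np.zeros(nbins)
            for row in toy.islands[toy.islands["arm"] == a.name].itertuples():
                b0, b1 = row.start // bin_bp, -(-row.end // bin_bp)
                log_e[b0:b1] += np.log2(cfg.island_fold)
            if strain == "focal":
                sub = toy.tes[(toy.tes["arm"] == a.name) & toy.tes["spreading"]]
                for row in sub.itertuples():
                    # symmetric footprint about the (bin-aligned) insertion
                    b0 = max(0, (row.start - half) // bin_bp)
                    b1 = min(nbins, (row.start + half) // bin_bp)
                    log_e[b0:b1] += np.log2(cfg.te_fold)
            noise = (
                rng.normal(0.0, cfg.chip_sigma, nbins) if cfg.chip_sigma > 0 else 0.0
            )
            chip = cfg.chip_background_depth * 2.0 ** (log_e + noise)
            inp = np.full(nbins, cfg.chip_background_depth)
            chip_frames[a.name] = pd.DataFrame(
                {"start": edges[:-1], "end": edges[1:], "value": chip}
            )
            input_frames[a.name] = pd.DataFrame(
                {"start": edges[:-1], "end": edges[1:], "value": inp}
            )
        out[strain] = {"chip": chip_frames, "input": input_frames}
    return out


# ---------------------------------------------------------------------------
# FISH and population-frequency simulation


def simulate_fish_distances(
    config: SyntheticConfig,
    n_nuclei: int,
    seed: Optional[int] = None,
    pi: Optional[float] = None,
    group: str = "synthetic",
) -> pd.DataFrame:
    """Per-nucleus focus distances from the bimodal mixture (um).

    distance ~ pi * |N(0, sigma0)| + (1 - pi) * N(mu1, sigma1) truncated at
    zero; nuclear radii from a truncated normal. pi = 0 yields the unimodal
    (no near-zero peak) case.
    """
    if n_nuclei < 1:
        raise InputError("n_nuclei must be >= 1")
    pi = config.fish_pi if pi is None else pi
    rng = np.random.default_rng(
        _derive_seed(config.seed if seed is None else seed, 4)
    )
    near = rng.random(n_nuclei) < pi
    d = np.empty(n_nuclei)
    d[near] = np.abs(rng.normal(0.0, config.fish_sigma0, int(near.sum())))
    a = (0.0 - config.fish_mu1) / config.fish_sigma1
    d[~near] = stats.truncnorm.rvs(
        a, np.inf, loc=config.fish_mu1, scale=config.fish_sigma1,
        size=int((~near).sum()), random_state=rng,
    )
    ra = (0.0 - config.fish_radius_mu) / config.fish_radius_sigma
    radii = stats.truncnorm.rvs(
        ra, np.inf, loc=config.fish_radius_mu, scale=config.fish_radius_sigma,
        size=n_nuclei, random_state=rng,
    )
    return pd.DataFrame({
        "nucleus_id": np.arange(n_nuclei),
        "group": group,
        "distance_um": d,
        "radius_um": radii,
    })


def simulate_population_frequencies(
    config: SyntheticConfig, seed: Optional[int] = None
) -> pd.DataFrame:
    """TE population-frequency table with the with-PCH group skewed rare.

    Each group is zero-inflated (most euchromatic TE insertions are absent
    from the population sample) with an exponential tail; the with-PCH group
    has both more zeros and a smaller tail scale.
    """
    rng = np.random.default_rng(
        _derive_seed(config.seed if seed is None else seed, 5)
    )

    def draw(n, zero_p, scale):
        f = rng.exponential(scale, n)
        f[rng.random(n) < zero_p] = 0.0
        return np.clip(f, 0.0, 1.0)

    fw = draw(config.popfreq_n_with, config.popfreq_zero_with,
              config.popfreq_scale_with)
    fo = draw(config.popfreq_n_without, config.popfreq_zero_without,
              config.popfreq_scale_without)
    return pd.DataFrame({
        "te_id": [f"te_{i}" for i in range(fw.size + fo.size)],
        "frequency": np.concatenate([fw, fo]),
        "group": ["with_pch"] * fw.size + ["without_pch"] * fo.size,
    })
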