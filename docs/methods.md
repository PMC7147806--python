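# Methods

This note documents the models, conventions and numerical choices behind
`pchic`, and what the synthetic-data tests do and do not establish.

## Coordinates and genome model

All coordinates are 0-based, half-open. BED and bedGraph are read/written
natively in that convention; the pairs TSV carries 1-based positions on
disk (converted at the I/O layer), with repeat-only ends stored as `.`/0.
A genome is a fixed-order list of arms with per-arm PCH interval sets;
chromosomes declared fully heterochromatic (the Drosophila 4th and Y) are
PCH end to end. Euchromatin is *derived*: the arm minus PCH minus a
conservative buffer (`eu_offset_bp`, default 500 kb) adjacent to every PCH
boundary, so no "euchromatic" feature ever sits within 0.5 Mb of PCH. PCH
windows tile each PCH interval left to right at `window_bp` (default
100 kb); a partial terminal window is retained rather than dropped or
merged, so total window length always equals total PCH length. Arm order is
input order and fixes all matrix/report layouts.

## Read-end classification

Precedence: canonical-TE hit → TE_FILTERED; repeat-library hit →
REPEAT_PCH (repeat alignments target a separate reference and carry no
genomic coordinate, so they are resolved before position); then position:
in PCH with MAPQ ≥ 30 → UNIQUE_PCH, MAPQ = 0 → MULTI_PCH (the value `bwa`
assigns to multi-mapped reads), 0 < MAPQ < 30 → OTHER (ambiguous, *not*
multi); in derived euchromatin with MAPQ ≥ 30 → UNIQUE_EU; anything else →
OTHER. A read hitting both a TE and a heterochromatic repeat is
TE-filtered: TE reads are abundant in both compartments and cannot be
attributed to either, so the filter wins. Classification is a pure function
of the end; the vectorized table classifier is property-tested against the
scalar one, and category counts are asserted to conserve mass (the
conservation audit).

Pair classes: both ends UNIQUE_PCH → PCH_PCH_UNIQUE; one UNIQUE_EU and the
other any heterochromatic category → EU_PCH; both UNIQUE_EU → EU_EU; pairs
touching a TE_FILTERED or OTHER end, or joining two non-unique PCH ends (no
locatable end), are discarded.

## PCH–PCH territory analysis

Same-arm pairs closer than 10 kb (5′ mapping positions; separation is
undefined across arms) are removed as local-polymer contacts. Surviving
PCH_PCH_UNIQUE pairs increment a symmetric window matrix (same-window pairs
allowed, counted once). Interaction classes are aggregated per arm pair,
with all same-arm cells pooled into one intra-arm class, and analyzed at
three sequential exclusion levels (all / no intra-arm / no
intra-chromosome); retained counts are checked to be non-increasing.

Expected class proportions come from per-arm weights: *e(a,b) ∝ w_a w_b*
(with the factor 2 for a ≠ b applied consistently inside the
normalization). Weights are either mappability-one bases within PCH —
multiplied, when sex-adjusted, by mean copy number under a 1:1 sex ratio
(autosomes 2, X 1.5, Y 0.5) — or empirical unique-PCH end counts per arm,
never sex-adjusted because read counts already reflect ploidy. The two
models agree within Monte-Carlo error on uniform synthetic reads, which is
tested.

The permutation null shuffles second-end arm labels across the level's
retained pairs, preserving both marginal arm distributions. Pairs landing
in level-excluded classes after a shuffle are dropped from that
permutation's denominator; a permutation with an empty denominator counts
toward `n_perm` but not toward exceedance. One-sided
*p = (1 + exceed)/(1 + n_perm)* never returns zero. An exhaustive mode
enumerates all n! orderings for ≤ 9 pairs and is tested against an
independent brute-force enumeration. The permutation unit (second-end arm
labels rather than window labels) is isolated in one function so an
alternative null can be substituted.

## Euchromatin–PCH enrichment

A query window is an island feature ± 1 kb or a TE insertion site/interval
± 2 kb, clipped to the arm; features overlapping PCH or leaving derived
euchromatin are rejected with a report. A pair is informative for a window
through any end that is UNIQUE_EU inside it, provided the partner is not
TE-filtered (TE pairs are removed genome-wide before any analysis); both
ends of an EU–EU pair qualify independently and ends are treated
symmetrically. The fraction of informative pairs with a heterochromatic
partner (all three PCH categories) is the statistic; the per-arm breakdown
uses uniquely-located partners only. Windows under the informative-pair
floor (default 1,000) are excluded as a result state.

Null ensembles contain `n_sets` (default 200) sets, each with one random
region per template region on the same arm, avoiding *all*
H3K9me2-enriched intervals (not only the queries). Island templates are
matched at exact size; TE templates draw a size from templates in the same
size-quantile bin. Size quantiles are quartiles of the query set's window
sizes, computed per analysis; the (arm, quartile) pair is the p-value
pooling key for both kinds. Null fractions are pooled across sets (the
null is "random regions", not set-level summaries) and
*p = (1 + #{null ≥ obs})/(1 + #null)*, significant at p < 0.05 with no
multiple-testing correction — the cohort-level check is instead an exact
binomial test of the significant count against the nominal 5%, two-sided
under the minimum-likelihood convention (sum of all outcome probabilities
≤ the observed outcome's), which reproduces classical printed values where
a plain one-sided tail does not. When two replicates are analyzed, each
draws an independent null ensemble. No minimum-separation filter applies to
EU–PCH pairs (it is a PCH–PCH concern).

## TE-induced H3K9me2 spread

Enrichment profiles are per-1-kb-bin log2((ChIP + pc)/(input + pc)) around
the insertion, length-weighted within bins, with bins overlapping other
annotated features maskable as NaN. Two normalization parameters matter:
`normalize` rescales each track to reads-per-million equivalents (default
on; turn off for tracks already on a common depth scale) and `pseudocount`
(default 1.0) guards empty bins. Exact noise-free recovery of a planted
fold (100% magnitude for a 2-fold spread) is only defined at
pseudocount 0 with depth-matched tracks, which is how the recovery analysis
runs; with the defaults the same estimate is attenuated by O(pc/depth).

Spread per side is the maximal contiguous run of bins, outward from the
insertion, where focal − mean(wildtypes) > δ (default 0.5 log2); a masked
bin terminates the run (conservative). Magnitude is the mean of
100·(2^diff − 1) over the spread bins; a TE spreads when the total extent
is ≥ 1 kb. Extent is monotonically non-increasing in δ (tested). Defaults
(δ = 0.5, 1-kb bins, 20-kb max extent) bracket the observed kb-scale
spreads (typical ~4 kb, maxima under 20 kb); wildtype strains are averaged,
and a per-strain-minimum variant would be a one-line substitution.
Population frequencies enter as a table (estimation from panel genomes is
out of scope) and are compared with a Welch two-sample t-test on the raw
frequencies; groups of size < 2 return NaN statistics with means intact.

## FISH statistics

The natural threshold is the density minimum between the first two modes of
a Gaussian KDE (Silverman bandwidth) evaluated on 512 points over
[0, max]. Mode detection requires prominence ≥ 5% of the density maximum;
the density is mirror-padded at both ends before peak finding so the
near-zero mode — whose left flank is cut off by the domain boundary — keeps
its full prominence. Unimodal samples return no threshold. The estimator is
scale-equivariant up to the bandwidth rule (tested). A minimum of 30
nuclei is enforced (typical studies count ≥ 70 per group; 30 is the floor
at which the KDE remains meaningful). Overlap is strict (distance <
threshold; a distance exactly at the threshold is not overlapping). Group
comparisons use a shared threshold (per-group thresholds are reported but
not tested), two-sided Mann–Whitney on distances — divided by nuclear
radius when relative — and Fisher's exact test on overlap counts; the
Fisher table always uses absolute distances, matching how the threshold was
derived.

## Synthetic-data generator

The generator defines the study conditions for all recovery tests:

- **Genome**: arms 2L/2R/3L/3R (1.5 Mb, 300-kb PCH at the centromeric end)
  and a fully heterochromatic 300-kb chromosome 4; ~7 Mb total, sized so a
  full pipeline run takes seconds to minutes on one core. The central 20%
  of each PCH block is multi-copy (mappability 0).
- **Hi-C**: end 1 uniform over the genome; the partner stays on the arm
  with probability 0.96, at a distance from a power law *s^−α* (α = 1, the
  polymer regime; lower cutoff 1 kb so the 10-kb separation filter is
  exercised; draws falling off the arm are reflected to the other side,
  rare doubly-out draws fall back to uniform). Cross-arm partners pick a
  destination arm by length; when the origin lies in PCH the planted
  arm-pair multipliers apply ({2L-2R: 3, 3L-3R: 3, 3L-4: 10, 3R-4: 4},
  emulating pericentric inter-arm preference and an exceptional
  3rd–4th-chromosome association) and the partner lands inside the
  destination PCH with probability 0.6 (chromocenter coalescence),
  uniformly otherwise.
- **Planted EU–PCH multipliers** redirect the partner of a window-interior
  end to a uniform PCH position with probability (m − 1)·q̂, where q̂ is
  the analytic model probability that the partner is PCH (cross-arm mass
  plus reflection-aware intra-arm decay mass; validated against simulation
  in the tests), multiplying the window's PCH-contact rate by ≈ m.
- **Read categories**: PCH ends in multi-copy segments get MAPQ 0; other
  PCH ends are re-emitted as repeat-library hits (no coordinates) at rate
  0.10; 2% of all ends get MAPQ 15 (ambiguous) and 1% a canonical-TE flag —
  the unique/repeat/multi shares land in the low single-digit percent range
  seen in real repeat-aware pipelines.
- **ChIP**: flat input at depth 100; ChIP = input·2^(e + N(0, σ)) per bin
  with island enrichment (fold 4) in every strain (islands are shared
  features) and TE spread (fold 2, 4 kb split across sides, bin-aligned
  insertions) in the focal strain only, for the designated ~65% of TEs.
  Tracks are emitted on a common depth scale, so recovery analyses read
  them with `normalize=False, pseudocount=0`.
- **FISH**: π·|N(0, 0.1)| + (1 − π)·N(1.5, 0.3) µm, truncated at zero,
  π = 0.4 by default; radii N(2.5, 0.3) truncated positive.
- **Population frequencies**: zero-inflated exponentials; the with-contact
  group has more zeros (0.8 vs 0.55) and a smaller tail scale (5×10⁻³ vs
  2.1×10⁻²), emulating mostly-absent insertions with mean frequencies near
  10⁻³ vs 10⁻².

All randomness flows from a single seed through named `SeedSequence`
streams; identical seeds give byte-identical outputs (tested end to end).

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: restriction-fragment structure, ligation
artifacts and duplicates (assumed handled upstream); assembly gaps and the
true mappability landscape; distance-dependent EU–PCH contact beyond the
single power law; TAD structure; ChIP fragment-length effects and
peak-shape diversity; 3D-microscopy segmentation error. Recovery results
show the estimators are correct under their assumed generative structure,
not that the assumptions hold in any particular dataset.

## Numerical conventions

- Empirical and permutation p-values always use the +1 pseudocount and are
  never zero; significance is nominal p < 0.05.
- Same-window (diagonal) PCH pairs surviving the separation filter count as
  intra-arm.
- Degenerate inputs are result states where the analysis says so (window
  below the pair floor, group of one for Welch) and errors where it does
  not (empty level, all-zero weights, unplaceable null region, fewer than
  30 nuclei).
- Problem sizes in the test suite and acceptance script (2×10⁶ raw pairs ≈
  10⁵ uniquely-locatable PCH pairs for the permutation analysis; 400
  calibration regions × 200 null sets at 1.5×10⁶ pairs; 4.5×10⁶ pairs for
  ≥ 5,000 informative pairs per planted window) were chosen as the smallest
  scales at which the planted effects are unambiguous.

## Known limitations

- The spread operator reconstructs a between-strain contrast from first
  principles (threshold runs on binned log-ratios); it is deliberately
  simple and its δ/bin defaults are package choices, not published
  constants.
- The KDE-valley threshold replaces a by-eye choice; bandwidth and
  prominence are configurable and logged, but very unequal mixture
  components can push the detected valley toward the minor mode.
- The permutation null conditions on observed marginals; planted effects
  inflate the marginals too, so extremely strong signals partially launder
  into the null (the test is conservative in that regime).
- Interval arithmetic is plain sorted-array work (sufficient for a handful
  of arms); no attempt is made to scale to mammalian-genome interval
  volumes.
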