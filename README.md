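# pchic — repeat-aware Hi-C, ChIP and FISH analysis of pericentromeric heterochromatin

Pericentromeric heterochromatin (PCH) — the megabases of repeat-rich,
H3K9me2/3-marked DNA flanking centromeres — coalesces into nuclear
chromocenters, yet it is routinely dropped from Hi-C analyses because its
reads do not map uniquely. `pchic` implements a repeat-aware analysis of
PCH organization for genomes like *Drosophila melanogaster*'s: it keeps
three classes of heterochromatic read ends (unique, multi-mapped, and
repeat-library hits) instead of discarding them, and builds the statistics
needed to ask how PCH is organized in 3D and how the euchromatic genome
contacts it. It is written for genomicists analyzing Hi-C, H3K9me2 ChIP-seq
and quantitative FISH data around heterochromatin.

## What it computes

**Read classification.** Each aligned Hi-C end is assigned one of six
categories. Ends hitting canonical transposable elements (TEs) are filtered
(TE reads cannot be attributed to a compartment); repeat-library hits count
as PCH without coordinates; positioned ends are unique-PCH (MAPQ ≥ 30),
multi-PCH (MAPQ = 0, the multi-mapper convention of `bwa`), unique
euchromatic, or ambiguous. Pair classes (PCH–PCH, EU–PCH, EU–EU) follow
from the end categories.

**PCH territories.** Uniquely-locatable PCH pairs ≥ 10 kb apart are binned
into 100-kb PCH windows, and contacts are partitioned at three sequential
exclusion levels: all pairs → intra-arm share; excluding intra-arm →
inter-arm (e.g. 2L–2R); excluding intra-chromosome → inter-chromosomal arm
pairs. Observed class proportions *o_c* are compared with expectations
*e_c = w_a w_b / Σ w_x w_y* from per-arm marginal weights *w* (mappability
bases in PCH, optionally copy-number adjusted under a 1:1 sex ratio, or
empirical unique-PCH read counts), and with a permutation null that
shuffles second-end arm labels across pairs: one-sided
*p = (1 + #{perm ≥ obs}) / (1 + n_perm)*, *n_perm* = 10,000.

**Euchromatin–PCH contacts.** For a euchromatic query window (an H3K9me2
island ± 1 kb, or a TE insertion ± 2 kb) the statistic is the fraction of
Hi-C pairs anchored uniquely in the window whose other end is *any* PCH
category. Windows with < 1,000 informative pairs are excluded. The null is
200 sets of random non-enriched euchromatic regions matched in count, arm
and size; the empirical p pools nulls from the query's (arm, size-quantile)
stratum. A cohort-level exact binomial test (two-sided, minimum-likelihood
convention) asks whether more than the nominal 5% of queries are
significant.

**TE-induced H3K9me2 spread.** Around each euchromatic TE insertion, the
per-kb log2 ChIP/input enrichment of the TE-carrying strain is contrasted
with the mean of wildtype strains lacking the insertion. The spread extent
per side is the maximal contiguous run of bins exceeding the wildtype mean
by δ (default 0.5 log2); a TE "spreads" when the total reaches 1 kb; the
magnitude is the mean percent increase over those bins. Population
frequencies of TEs with vs without PCH contact are compared with a Welch
t-test.

**FISH distances.** Distance distributions between focus centers are often
bimodal (coalesced vs separate foci). The "natural threshold" is the
density valley between the first two modes of a Gaussian KDE (Silverman
bandwidth); nuclei below it have overlapping foci. Groups are compared with
two-sided Mann–Whitney on (optionally radius-normalized) distances and
Fisher's exact test on overlap counts.

**Synthetic data.** A seeded generator builds a desk-scale multi-arm genome
(four 1.5-Mb arms with 300-kb PCH blocks plus a fully heterochromatic 4th
chromosome), Hi-C pairs with power-law intra-arm decay (*P(s) ∝ s^−α*,
α = 1), planted arm-pair preferences and euchromatin–PCH multipliers, a
MAPQ/repeat/TE read model, strain-paired ChIP coverage with planted spread,
bimodal FISH mixtures and TE frequency tables — so every statistic above is
testable by planted-parameter recovery.

## Worked example

Run the numbered analysis scripts in order; each writes plain-text tables
under `results/`:

```bash
python analysis/01_simulate_data.py
python analysis/02_classify_reads.py
python analysis/03_pch_territories.py
python analysis/04_eu_pch_contacts.py
python analysis/05_te_spread_popfreq.py
python analysis/06_fish_distances.py
```

On the default seed this prints, among other things:

```
level=all: intra-arm territories hold 93.86% of contacts
  2L-2R (no_intra_arm): observed 0.207, permutation p = 1.00e-04
  3L-3R (no_intra_arm): observed 0.177, permutation p = 1.00e-04
  3L-4 (no_intra_chromosome): observed 0.334, permutation p = 1.00e-04
  2L-3L (no_intra_chromosome): observed 0.107, permutation p = 5.65e-01
```

Intra-arm contacts dominate (each PCH arm forms its own territory); the
planted pericentric inter-arm preferences (2L–2R, 3L–3R) and the planted
3L–4 association are recovered at the minimum attainable permutation p,
while an unplanted inter-chromosomal pair (2L–3L) is correctly
non-significant. Downstream scripts report that 0/12 unperturbed islands
show EU–PCH enrichment (cohort binomial p = 1, as expected under the null),
that exactly the five planted TEs spread H3K9me2 ≥ 1 kb, and that the focal
FISH group is bimodal with 40.5% overlapping nuclei at the detected 0.69 µm
threshold against a unimodal control.

The cohort-level binomial machinery reproduces textbook exact values; for
example 69 significant regions out of 496 at a 5% null:

```python
>>> from pchic import enrichment_binomial
>>> enrichment_binomial(69, 496, 0.05)
3.038334000811229e-14
```

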