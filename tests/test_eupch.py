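import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_pairs_frame
from pchic.classify import classify_frame
from pchic.eupch import (
    EuPchResult,
    EuPchScorer,
    NullEnsemble,
    QueryRegion,
    empirical_pvalue,
    enrichment_binomial,
    eu_pch_fraction,
    make_query_windows,
    sample_null_regions,
    size_quantile_bins,
)
from pchic.genome import (
    ComputationError,
    InputError,
    Intervals,
    RepeatCatalog,
    load_annotation,
)

CATALOG = RepeatCatalog(names=("AAGAG",))


def annotation_1mb():
    return load_annotation(
        [("2L", 800_000, 1_000_000)],
        arms=[("2L", "2", 1_000_000), ("3L", "3", 1_000_000)],
        eu_offset_bp=100_000,
    )


class TestMakeQueryWindows:
    def test_island_padding(self, simple_annotation):
        feats = pd.DataFrame([("2L", 10_000, 12_000)],
                             columns=["arm", "start", "end"])
        regions, rej = make_query_windows(feats, "island", simple_annotation)
        assert len(rej) == 0
        assert (regions[0].start, regions[0].end) == (9_000, 13_000)

    def test_te_point_padding(self, simple_annotation):
        feats = pd.DataFrame([("2L", 50_000, 50_001)],
                             columns=["arm", "start", "end"])
        regions, _ = make_query_windows(feats, "te", simple_annotation)
        assert (regions[0].start, regions[0].end) == (48_000, 52_001)

    def test_te_interval_padding(self, simple_annotation):
        feats = pd.DataFrame([("2L", 50_000, 50_100)],
                             columns=["arm", "start", "end"])
        regions, _ = make_query_windows(feats, "te", simple_annotation)
        assert (regions[0].start, regions[0].end) == (48_000, 52_100)

    def test_pch_feature_rejected(self, simple_annotation):
        feats = pd.DataFrame([("2L", 850_000, 852_000)],
                             columns=["arm", "start", "end"])
        regions, rej = make_query_windows(feats, "island", simple_annotation)
        assert not regions
        assert rej.iloc[0]["reason"] == "inside PCH"

    def test_boundary_buffer_feature_rejected(self, simple_annotation):
        feats = pd.DataFrame([("2L", 600_000, 602_000)],
                             columns=["arm", "start", "end"])
        regions, rej = make_query_windows(feats, "island", simple_annotation)
        assert not regions and len(rej) == 1


def scorer_from_rows(rows, annotation):
    cl = classify_frame(make_pairs_frame(rows), annotation, CATALOG)
    return EuPchScorer(cl, annotation.arm_names)


class TestEuPchFraction:
    def test_hand_tally(self):
        """10 qualifying pairs in the window: 2 unique-PCH-on-2L partners and
        1 repeat partner give fraction 0.3 with per-arm 2L share 0.2."""
        ann = annotation_1mb()
        rows = []
        # 10 pairs with end1 unique in window [100k, 104k) on 2L
        partners = (
            [("2L", 900_000, 60, None)] * 2       # unique PCH on 2L
            + [(None, None, 0, "AAGAG")]          # repeat
            + [("3L", 500_000, 60, None)] * 7     # unique EU elsewhere
        )
        for i, (a, p, q, r) in enumerate(partners):
            rows.append(("2L", 100_500 + i * 100, 60, None, False,
                         a, p, q, r, False))
        scorer = scorer_from_rows(rows, ann)
        region = QueryRegion("w", "2L", 100_000, 104_000, "island")
        res = eu_pch_fraction(scorer, region, min_pairs=10)
        assert res.n_pairs == 10
        assert res.frac_pch == pytest.approx(0.3)
        assert res.per_arm_frac == pytest.approx({"2L": 0.2})

    def test_pair_floor_exclusion(self):
        ann = annotation_1mb()
        rows = [("2L", 100_500, 60, None, False, "3L", 500_000, 60, None, False)]
        scorer = scorer_from_rows(rows, ann)
        region = QueryRegion("w", "2L", 100_000, 104_000, "island")
        res = eu_pch_fraction(scorer, region, min_pairs=2)
        assert res.excluded and res.n_pairs == 1

    def test_te_filtered_partner_not_counted(self):
        ann = annotation_1mb()
        rows = [
            ("2L", 100_500, 60, None, False, "2L", 900_000, 60, None, True),
            ("2L", 100_600, 60, None, False, "3L", 500_000, 60, None, False),
        ]
        scorer = scorer_from_rows(rows, ann)
        region = QueryRegion("w", "2L", 100_000, 104_000, "island")
        res = eu_pch_fraction(scorer, region, min_pairs=1)
        assert res.n_pairs == 1  # TE-filtered pair removed from denominator


class TestSampleNullRegions:
    def test_matched_arm_and_size_and_determinism(self, toy, classified_small):
        scorer = EuPchScorer(classified_small, toy.annotation.arm_names)
        template = [QueryRegion("q0", "2L", 100_000, 104_000, "island")]
        e1 = sample_null_regions(toy.annotation, {}, template, scorer,
                                 n_sets=20, seed=5, min_pairs=1)
        e2 = sample_null_regions(toy.annotation, {}, template, scorer,
                                 n_sets=20, seed=5, min_pairs=1)
        assert len(e1.regions) == 20
        assert (e1.regions["arm"] == "2L").all()
        assert (e1.regions["size"] == 4_000).all()
        pd.testing.assert_frame_equal(e1.regions, e2.regions)

    def test_exhaustive_placement_when_one_slot_remains(self):
        ann = load_annotation(
            [("2L", 90_000, 100_000)], arms=[("2L", "2", 100_000)],
            eu_offset_bp=0,
        )
        # exclusion leaves exactly one 4-kb slot, [86000, 90000)
        exclusions = {"2L": Intervals.from_pairs([(0, 86_000)])}
        rows = [("2L", 87_000, 60, None, False, "2L", 95_000, 60, None, False)]
        scorer = scorer_from_rows(rows, ann)
        template = [QueryRegion("q0", "2L", 0, 4_000, "island")]
        ens = sample_null_regions(ann, exclusions, template, scorer,
                                  n_sets=5, seed=0, min_pairs=0)
        assert (ens.regions["start"] == 86_000).all()

    def test_insufficient_space_is_error(self):
        ann = load_annotation(
            [("2L", 90_000, 100_000)], arms=[("2L", "2", 100_000)],
            eu_offset_bp=0,
        )
        exclusions = {"2L": Intervals.from_pairs([(0, 89_000)])}
        rows = [("2L", 10, 60, None, False, "2L", 95_000, 60, None, False)]
        scorer = scorer_from_rows(rows, ann)
        template = [QueryRegion("q0", "2L", 0, 4_000, "island")]
        with pytest.raises(ComputationError, match="2L"):
            sample_null_regions(ann, exclusions, template, scorer,
                                n_sets=2, seed=0)


def ensemble_from_fracs(arm, fracs, size_bin=0):
    df = pd.DataFrame({
        "set_id": range(len(fracs)), "template_id": "t", "arm": arm,
        "start": 0, "end": 1000, "size": 1000, "size_bin": size_bin,
        "n_pairs": 10_000, "frac_pch": fracs, "excluded": False,
    })
    return NullEnsemble(regions=df, n_sets=len(fracs), seed=0)


def result(frac, arm="2L"):
    return EuPchResult(region_id="q", arm=arm, size=1000, n_pairs=10_000,
                       frac_pch=frac, per_arm_frac={}, excluded=False)


class TestEmpiricalPvalue:
    def test_hand_counted(self):
        ens = ensemble_from_fracs("2L", [0.1, 0.2, 0.3, 0.4, 0.5])
        assert empirical_pvalue(result(0.35), ens, 0) == pytest.approx(0.5)

    def test_extreme_observation(self):
        ens = ensemble_from_fracs("2L", list(np.linspace(0, 0.1, 200)))
        assert empirical_pvalue(result(0.9), ens, 0) == pytest.approx(1 / 201)

    def test_median_observation(self):
        nulls = list(np.linspace(0, 1, 201))
        ens = ensemble_from_fracs("2L", nulls)
        p = empirical_pvalue(result(np.median(nulls) + 1e-9), ens, 0)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_monotone_in_observed_fraction(self):
        rng = np.random.default_rng(3)
        ens = ensemble_from_fracs("2L", rng.random(100).tolist())
        ps = [empirical_pvalue(result(f), ens, 0) for f in np.linspace(0, 1, 21)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_wrong_stratum_returns_none(self):
        ens = ensemble_from_fracs("2L", [0.1, 0.2])
        assert empirical_pvalue(result(0.5, arm="3L"), ens, 0) is None


class TestSizeQuantileBins:
    def test_quartiles(self):
        sizes = [1, 2, 3, 4, 5, 6, 7, 8]
        bins = size_quantile_bins(sizes, 4)
        assert bins.min() == 0 and bins.max() == 3
        assert (np.diff(bins) >= 0).all()


class TestEnrichmentBinomial:
    @pytest.mark.parametrize(
        "k,n,expected,rel",
        [
            (69, 496, 3.04e-14, 0.01),
            (43, 496, 0.00059, 0.01),
            (14, 106, 8.38e-4, 0.01),
            (8, 106, 0.26, 0.02),
        ],
    )
    def test_cohort_counts(self, k, n, expected, rel):
        assert enrichment_binomial(k, n, 0.05) == pytest.approx(expected, rel=rel)

    def test_single_trial(self):
        assert enrichment_binomial(1, 1, 0.5) == 1.0

    def test_derived_example(self):
        # sum of the 11 point probabilities <= P(X = 3), X ~ Bin(10, 0.2)
        assert enrichment_binomial(3, 10, 0.2) == pytest.approx(0.4296, abs=1e-4)

    def test_matches_enumeration_oracle(self):
        """Exhaustive minlike summation for all n <= 25 reproduces the test."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 26))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            pk = stats.binom.pmf(k, n, p0)
            oracle = sum(
                stats.binom.pmf(j, n, p0)
                for j in range(n + 1)
                if stats.binom.pmf(j, n, p0) <= pk * (1 + 1e-10)
            )
            assert enrichment_binomial(k, n, p0) == pytest.approx(
                min(1.0, oracle), rel=1e-8
            )

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            enrichment_binomial(5, 4, 0.05)
        with pytest.raises(InputError):
            enrichment_binomial(1, 10, 0.0)
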