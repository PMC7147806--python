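import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_pairs_frame
from pchic.classify import classify_frame
from pchic.contacts import (
    ContactMatrix,
    build_contact_matrix,
    expected_proportions,
    extract_arm_pairs,
    partition_interactions,
    permutation_test,
    separation_filter,
)
from pchic.genome import (
    ArmWeights,
    ComputationError,
    InputError,
    Intervals,
    MappabilityTrack,
    RepeatCatalog,
    arm_marginals,
    bin_pch_windows,
    load_annotation,
)

CATALOG = RepeatCatalog(names=("AAGAG",))
CHROM3 = {"2L": "2", "2R": "2", "3L": "3"}


def windows_frame(rows):
    """rows: list of (arm, chromosome, start, end)."""
    df = pd.DataFrame(rows, columns=["arm", "chromosome", "start", "end"])
    df.insert(2, "index", np.arange(len(df)))
    return df


def matrix_from_arm_tallies(tallies):
    """One window per arm; tallies: {(arm_a, arm_b): n_pairs}."""
    arms = sorted({a for k in tallies for a in k})
    win = windows_frame([(a, CHROM3[a], 0, 100_000) for a in arms])
    counts = np.zeros((len(arms), len(arms)), dtype=np.int64)
    idx = {a: i for i, a in enumerate(arms)}
    for (a, b), n in tallies.items():
        counts[idx[a], idx[b]] += n
        if a != b:
            counts[idx[b], idx[a]] += n
    return ContactMatrix(windows=win, counts=counts)


class TestBuildContactMatrix:
    def _annotation(self):
        return load_annotation(
            [("2L", 800_000, 1_000_000), ("2R", 0, 200_000)],
            arms=[("2L", "2", 1_000_000), ("2R", "2", 1_000_000)],
            eu_offset_bp=300_000,
        )

    def _classified(self, rows):
        frame = make_pairs_frame(rows)
        return classify_frame(frame, self._annotation(), CATALOG)

    def test_close_same_arm_pair_dropped(self):
        cl = self._classified([
            ("2L", 900_000, 60, None, False, "2L", 905_000, 60, None, False),
        ])
        win = bin_pch_windows(self._annotation(), 100_000)
        m = build_contact_matrix(cl, win, min_separation_bp=10_000)
        assert m.total_pairs == 0
        assert m.n_dropped_close == 1

    def test_inter_chromosome_pair_always_retained(self):
        cl = self._classified([
            ("2L", 900_000, 60, None, False, "2R", 100, 60, None, False),
        ])
        win = bin_pch_windows(self._annotation(), 100_000)
        m = build_contact_matrix(cl, win, min_separation_bp=10_000)
        assert m.total_pairs == 1

    def test_hand_tallied_toy_matrix(self):
        # six pairs over 4 windows (2L has 2 windows of 100 kb, 2R has 2)
        rows = [
            ("2L", 810_000, 60, None, False, "2L", 890_000, 60, None, False),  # w0-w0
            ("2L", 810_000, 60, None, False, "2L", 950_000, 60, None, False),  # w0-w1
            ("2L", 950_000, 60, None, False, "2L", 810_000, 60, None, False),  # w0-w1
            ("2L", 910_000, 60, None, False, "2R", 50_000, 60, None, False),   # w1-w2
            ("2R", 50_000, 60, None, False, "2R", 150_000, 60, None, False),   # w2-w3
            ("2R", 199_000, 60, None, False, "2R", 199_500, 60, None, False),  # dropped
        ]
        cl = self._classified(rows)
        win = bin_pch_windows(self._annotation(), 100_000)
        m = build_contact_matrix(cl, win, min_separation_bp=10_000)
        expected = np.array([
            [1, 2, 0, 0],
            [2, 0, 1, 0],
            [0, 1, 0, 1],
            [0, 0, 1, 0],
        ])
        assert np.array_equal(m.counts, expected)
        assert m.total_pairs == 5
        assert m.n_dropped_close == 1

    def test_separation_filter_counts(self):
        cl = self._classified([
            ("2L", 900_000, 60, None, False, "2L", 903_000, 60, None, False),
            ("2L", 900_000, 60, None, False, "2L", 990_000, 60, None, False),
        ])
        surv, dropped = separation_filter(cl, 10_000)
        assert len(surv) == 1 and dropped == 1


class TestPartition:
    def test_degenerate_all_intra(self):
        m = matrix_from_arm_tallies({("2L", "2L"): 6})
        p = partition_interactions(m, "all")
        assert p.proportions == {"intra_arm": 1.0}

    def test_hand_tallied_toy_counts_at_three_levels(self):
        tallies = {("2L", "2L"): 6, ("2L", "2R"): 2, ("2L", "3L"): 1,
                   ("2R", "3L"): 1}
        m = matrix_from_arm_tallies(tallies)
        p_all = partition_interactions(m, "all")
        assert p_all.proportions["intra_arm"] == pytest.approx(0.6)
        p1 = partition_interactions(m, "no_intra_arm")
        assert p1.proportions == pytest.approx(
            {"2L-2R": 0.5, "2L-3L": 0.25, "2R-3L": 0.25}
        )
        p2 = partition_interactions(m, "no_intra_chromosome")
        assert p2.proportions == pytest.approx({"2L-3L": 0.5, "2R-3L": 0.5})
        # retained counts non-increasing across the exclusion sequence
        assert p_all.retained >= p1.retained >= p2.retained

    def test_proportions_sum_to_one(self, toy, classified_small):
        win = bin_pch_windows(toy.annotation)
        m = build_contact_matrix(classified_small, win)
        for level in ("all", "no_intra_arm", "no_intra_chromosome"):
            p = partition_interactions(m, level)
            assert sum(p.proportions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_transpose_invariance(self):
        tallies = {("2L", "2R"): 3, ("2L", "3L"): 2, ("2R", "3L"): 5}
        m = matrix_from_arm_tallies(tallies)
        mt = ContactMatrix(windows=m.windows, counts=m.counts.T.copy())
        for level in ("all", "no_intra_arm"):
            assert (
                partition_interactions(m, level).proportions
                == partition_interactions(mt, level).proportions
            )

    def test_empty_after_exclusion_is_error(self):
        m = matrix_from_arm_tallies({("2L", "2L"): 6})
        with pytest.raises(ComputationError):
            partition_interactions(m, "no_intra_arm")


class TestExpectedProportions:
    def test_equal_weights_uniform_over_cross_pairs(self):
        w = ArmWeights({"2L": 1, "2R": 1, "3L": 1, "3R": 1}, source="mappability")
        chrom = {"2L": "2", "2R": "2", "3L": "3", "3R": "3"}
        exp = expected_proportions(w, "no_intra_chromosome", chrom)
        assert exp.proportions == pytest.approx(
            {"2L-3L": 0.25, "2L-3R": 0.25, "2R-3L": 0.25, "2R-3R": 0.25}
        )

    def test_hand_product_formula(self):
        w = ArmWeights({"2L": 2, "2R": 1, "3L": 1}, source="mappability")
        exp = expected_proportions(w, "no_intra_chromosome", CHROM3)
        assert exp.proportions == pytest.approx({"2L-3L": 2 / 3, "2R-3L": 1 / 3})

    def test_invariant_to_weight_rescaling(self):
        chrom = {"2L": "2", "2R": "2", "3L": "3"}
        w1 = ArmWeights({"2L": 2, "2R": 1, "3L": 3}, source="mappability")
        w2 = ArmWeights({"2L": 20, "2R": 10, "3L": 30}, source="mappability")
        for level in ("all", "no_intra_arm", "no_intra_chromosome"):
            assert expected_proportions(w1, level, chrom).proportions == pytest.approx(
                expected_proportions(w2, level, chrom).proportions
            )

    def test_empirical_marginals_match_mappability_monte_carlo(self, toy):
        """Reads drawn uniformly over mappable PCH bases reproduce the
        mappability-based expectation within Monte-Carlo error."""
        ann = toy.annotation
        rng = np.random.default_rng(7)
        # uniform reads over mappable PCH bases: multinomial per-arm counts
        bases = {
            arm: toy.mappability.mappable_in(arm, ann.pch[arm])
            for arm in ann.arm_names
        }
        tot = sum(bases.values())
        draws = rng.multinomial(
            100_000, [bases[a] / tot for a in ann.arm_names]
        )
        counts = dict(zip(ann.arm_names, draws))
        w_emp = arm_marginals(counts, ann)
        w_map = arm_marginals(toy.mappability, ann)
        exp_emp = expected_proportions(
            w_emp, "no_intra_chromosome", ann.chromosome_of, ann.arm_names
        )
        exp_map = expected_proportions(
            w_map, "no_intra_chromosome", ann.chromosome_of, ann.arm_names
        )
        for k in exp_map.proportions:
            assert exp_emp.proportions[k] == pytest.approx(
                exp_map.proportions[k], abs=0.01
            )


class TestPermutationTest:
    CHROM = {"A": "cA", "B": "cB", "C": "cC"}

    def test_one_sided_direction(self):
        # observed proportion far below the permutation mean -> p near 1
        rng = np.random.default_rng(0)
        arm1 = np.array(["A"] * 50, dtype=object)
        arm2 = np.array(["B"] * 48 + ["C"] * 2, dtype=object)
        res = permutation_test(arm1, arm2, "A-C", "all", self.CHROM,
                               n_perm=500, seed=1)
        assert res.p_one_sided > 0.9

    def test_exhaustive_enumeration_matches_independent_oracle(self):
        arm1 = np.array(["A", "A", "B"], dtype=object)
        arm2 = np.array(["B", "C", "C"], dtype=object)
        res = permutation_test(arm1, arm2, "A-B", "all", self.CHROM,
                               exhaustive=True)
        # independent oracle: enumerate all 3! pairings in plain python
        props = []
        for perm in itertools.permutations(arm2):
            hits = sum(
                1 for x, y in zip(arm1, perm)
                if {x, y} == {"A", "B"}
            )
            props.append(hits / 3)
        obs = sum(1 for x, y in zip(arm1, arm2) if {x, y} == {"A", "B"}) / 3
        expected_p = (1 + sum(1 for p in props if p >= obs)) / (1 + len(props))
        assert res.n_perm == 6
        assert res.p_one_sided == pytest.approx(expected_p)
        assert sorted(res.perm_proportions) == pytest.approx(sorted(props))

    def test_sampled_distribution_matches_enumeration_for_small_n(self):
        """With many sampled permutations the permutation distribution of a
        <= 8 pair input converges to the exhaustive one."""
        arm1 = np.array(["A", "A", "B", "B", "C"], dtype=object)
        arm2 = np.array(["B", "C", "C", "A", "A"], dtype=object)
        ex = permutation_test(arm1, arm2, "A-B", "all", self.CHROM,
                              exhaustive=True)
        sampled = permutation_test(arm1, arm2, "A-B", "all", self.CHROM,
                                   n_perm=20_000, seed=3)
        vals = np.unique(ex.perm_proportions)
        ef = np.array([(ex.perm_proportions == v).mean() for v in vals])
        sf = np.array([(sampled.perm_proportions == v).mean() for v in vals])
        assert np.abs(ef - sf).max() < 0.02
        assert sampled.p_one_sided == pytest.approx(ex.p_one_sided, abs=0.02)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        arm1 = rng.choice(["A", "B", "C"], 40).astype(object)
        arm2 = rng.choice(["A", "B", "C"], 40).astype(object)
        r1 = permutation_test(arm1, arm2, "A-B", "all", self.CHROM,
                              n_perm=200, seed=11)
        r2 = permutation_test(arm1, arm2, "A-B", "all", self.CHROM,
                              n_perm=200, seed=11)
        assert r1.p_one_sided == r2.p_one_sided

    def test_p_values_uniform_under_exchangeable_null(self):
        """Permutation p-values are uniform (up to grid discreteness) when
        arm labels are exchangeable."""
        rng = np.random.default_rng(2024)
        ps = []
        for _ in range(300):
            arm1 = rng.choice(["A", "B", "C"], 60).astype(object)
            arm2 = rng.choice(["A", "B", "C"], 60).astype(object)
            res = permutation_test(
                arm1, arm2, "A-B", "all", self.CHROM, n_perm=99,
                seed=int(rng.integers(0, 2**31)),
            )
            ps.append(res.p_one_sided)
        ps = np.asarray(ps)
        assert abs(ps.mean() - 0.5) < 0.06
        grid = np.linspace(0.05, 0.95, 19)
        ecdf = np.array([(ps <= g).mean() for g in grid])
        assert np.abs(ecdf - grid).max() < 0.1

    def test_never_returns_zero(self):
        arm1 = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        arm2 = np.array(["B"] * 20 + ["A"] * 20, dtype=object)
        res = permutation_test(arm1, arm2, "A-B", "all", self.CHROM,
                               n_perm=50, seed=0)
        assert res.p_one_sided > 0

    def test_absent_target_rejected(self):
        arm1 = np.array(["A", "A"], dtype=object)
        arm2 = np.array(["B", "B"], dtype=object)
        with pytest.raises(InputError):
            permutation_test(arm1, arm2, "A-Z", "all",
                             {**self.CHROM, "Z": "cZ"}, n_perm=10)

    def test_excluded_target_rejected(self):
        chrom = {"A": "c1", "B": "c1", "C": "c2"}
        arm1 = np.array(["A", "C"], dtype=object)
        arm2 = np.array(["B", "A"], dtype=object)
        with pytest.raises(InputError):
            permutation_test(arm1, arm2, "A-B", "no_intra_chromosome",
                             chrom, n_perm=10)


class TestExtractArmPairs:
    def test_levels_nest(self, toy, classified_small):
        chrom = toy.annotation.chromosome_of
        n_all = len(extract_arm_pairs(classified_small, "all", chrom)[0])
        n_noa = len(extract_arm_pairs(classified_small, "no_intra_arm", chrom)[0])
        n_noc = len(
            extract_arm_pairs(classified_small, "no_intra_chromosome", chrom)[0]
        )
        assert n_all >= n_noa >= n_noc > 0
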