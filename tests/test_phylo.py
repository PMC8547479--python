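import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assemblage.io import CountTable, ValidationError, read_newick
from assemblage.phylo import (
    TipDistanceMatrix,
    beta_mntd,
    beta_mntd_matrix,
    beta_nti_matrix,
    cophenetic_distances,
    mntd,
    nti,
)


class TestCopheneticDistances:
    def test_two_tip_sum(self):
        dist = cophenetic_distances(read_newick("(A:1,B:2);"))
        assert dist.select(("A", "B")).d[0, 1] == pytest.approx(3.0)

    def test_balanced_quartet_path_sums(self):
        dist = cophenetic_distances(read_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        d = dist.select(("A", "B", "C", "D")).d
        assert d[0, 1] == pytest.approx(2.0)  # A-B
        assert d[0, 2] == pytest.approx(4.0)  # A-C

    def test_zero_diagonal(self, five_tip_dist):
        np.testing.assert_array_equal(np.diag(five_tip_dist.d), 0.0)


class TestMNTD:
    def test_star_tree_forces_constant(self, star_dist):
        assert mntd({"a": 1.0, "b": 5.0, "c": 0.2}, star_dist) == pytest.approx(4.0)

    def test_hand_enumerated_nearest_neighbours(self):
        # d(A,B)=2, d(A,C)=4, d(B,C)=4: nearest distances are 2, 2, 4
        d = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        dist = TipDistanceMatrix(("A", "B", "C"), d)
        equal = {"A": 1.0, "B": 1.0, "C": 1.0}
        assert mntd(equal, dist) == pytest.approx(8.0 / 3.0)

    def test_single_taxon_is_error(self, star_dist):
        with pytest.raises(ValidationError):
            mntd({"a": 1.0}, star_dist)


class TestBetaMNTD:
    def test_identical_samples_zero(self, five_tip_dist):
        s = {"A": 0.3, "C": 0.7}
        assert beta_mntd(s, s, five_tip_dist) == pytest.approx(0.0)

    def test_single_pair_distance(self, star_dist):
        assert beta_mntd({"a": 1.0}, {"c": 1.0}, star_dist) == pytest.approx(4.0)

    def test_star_cross_distance(self, star_dist):
        assert beta_mntd(
            {"a": 0.5, "b": 0.5}, {"c": 0.5, "d": 0.5}, star_dist
        ) == pytest.approx(4.0)

    def test_symmetry_and_scaling_invariance(self, five_tip_dist):
        a = {"A": 2.0, "B": 1.0}
        b = {"C": 5.0, "E": 1.0}
        ab = beta_mntd(a, b, five_tip_dist)
        assert ab == pytest.approx(beta_mntd(b, a, five_tip_dist))
        scaled = {k: 17.5 * v for k, v in a.items()}
        assert beta_mntd(scaled, b, five_tip_dist) == pytest.approx(ab)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matrix_matches_pairwise_calls(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.5, 3.0, size=(6, 6))
        d = np.triu(d, 1)
        d = d + d.T
        dist = TipDistanceMatrix(tuple("pqrstu"), d)
        x = rng.integers(0, 5, size=(4, 6)).astype(float)
        x[x.sum(axis=1) == 0, 0] = 1.0
        ct = CountTable(
            pd.DataFrame(x, index=[f"s{i}" for i in range(4)], columns=list("pqrstu"))
        )
        full = beta_mntd_matrix(ct, dist)
        for i, j in itertools.combinations(range(4), 2):
            expected = beta_mntd(
                dict(zip("pqrstu", x[i])), dict(zip("pqrstu", x[j])), dist
            )
            assert full[i, j] == pytest.approx(expected, abs=1e-12)


def _exhaustive_null(ct, dist, weighted=True):
    """Exact tip-shuffle null: enumerate all taxon-label permutations."""
    n = dist.n
    values = []
    for perm in itertools.permutations(range(n)):
        perm = np.array(perm)
        shuffled = TipDistanceMatrix(dist.taxon_ids, dist.d[np.ix_(perm, perm)])
        values.append(beta_mntd_matrix(ct, shuffled, weighted=weighted))
    stack = np.array(values)
    return stack.mean(axis=0), stack.std(axis=0, ddof=0)


class TestBetaNTI:
    def test_identical_communities_never_positive(self, five_tip_dist):
        x = pd.DataFrame(
            [[1.0, 0, 2.0, 0, 1.0]] * 2 + [[0, 1.0, 0, 2.0, 0]],
            index=["s1", "s2", "s3"],
            columns=list("ABCDE"),
        )
        ct = CountTable(x)
        m = beta_nti_matrix(ct, five_tip_dist, reps=199, seed=0)
        assert np.isnan(m.values[0, 1]) or m.values[0, 1] <= 0

    def test_monte_carlo_matches_exhaustive_oracle(self, five_tip_dist):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 6, size=(3, 5)).astype(float)
        x[x.sum(axis=1) == 0, 0] = 2.0
        x[(x > 0).sum(axis=1) < 2, :2] = 1.0
        ct = CountTable(
            pd.DataFrame(x, index=["s1", "s2", "s3"], columns=list("ABCDE"))
        )
        mean_exact, sd_exact = _exhaustive_null(ct, five_tip_dist)
        reps = 4000
        m, nulls = beta_nti_matrix(
            ct, five_tip_dist, reps=reps, seed=11, return_null=True
        )
        obs = beta_mntd_matrix(ct, five_tip_dist)
        for i, j in itertools.combinations(range(3), 2):
            se_mean = sd_exact[i, j] / np.sqrt(reps)
            assert nulls[:, i, j].mean() == pytest.approx(
                mean_exact[i, j], abs=3 * se_mean + 1e-12
            )
            expected_score = (obs[i, j] - mean_exact[i, j]) / sd_exact[i, j]
            # MC score uses MC mean/sd; agree within Monte-Carlo tolerance
            assert m.values[i, j] == pytest.approx(expected_score, abs=0.2)

    def test_seed_fixes_every_bit(self, toy_counts, five_tip_dist):
        a = beta_nti_matrix(toy_counts, five_tip_dist, reps=99, seed=5)
        b = beta_nti_matrix(toy_counts, five_tip_dist, reps=99, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_diagonal_is_nan(self, toy_counts, five_tip_dist):
        m = beta_nti_matrix(toy_counts, five_tip_dist, reps=49, seed=1)
        assert np.isnan(np.diag(m.values)).all()


class TestNTI:
    def test_sample_with_every_tip_is_degenerate_unweighted(self, five_tip_dist):
        ct = CountTable(
            pd.DataFrame([[1.0] * 5, [1.0, 1.0, 0, 0, 0]],
                         index=["all", "pair"], columns=list("ABCDE"))
        )
        res = nti(ct, five_tip_dist, reps=99, seed=2, weighted=False)
        assert res["all"].degenerate
        assert np.isnan(res["all"].score)

    def test_sister_pair_on_caterpillar_is_clustered(self):
        tree = read_newick("(((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5);")
        dist = cophenetic_distances(tree)
        ct = CountTable(
            pd.DataFrame(
                [[1.0, 1.0, 0, 0, 0, 0], [1.0, 0, 0, 0, 0, 1.0]],
                index=["sisters", "far"],
                columns=[t for t in dist.taxon_ids],
            )
        )
        res = nti(ct, dist, reps=999, seed=3)
        # exhaustive oracle: null = distance between two random tips;
        # sisters are the closest pair so clustering must be positive
        assert res["sisters"].score > 0
        assert res["sisters"].observed <= res["sisters"].null_mean

    def test_score_zero_when_observed_equals_null_mean(self, five_tip_dist):
        ct = CountTable(
            pd.DataFrame([[1.0, 1.0, 1.0, 1.0, 1.0]], index=["s"], columns=list("ABCDE"))
        )
        res = nti(ct, five_tip_dist, reps=49, seed=0, weighted=False)
        # all tips present and unweighted: every shuffle is identical
        assert res["s"].degenerate or res["s"].score == pytest.approx(0.0)
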