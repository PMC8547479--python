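import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assemblage.io import CountTable, PairwiseMatrix, SampleMetadata, ValidationError
from assemblage.phylo import cophenetic_distances
from assemblage.simulate import evolve_trait, simulate_tree
from assemblage.stats import (
    NicheValueVector,
    bray_curtis_matrix,
    env_difference_matrix,
    mantel,
    mantel_correlogram,
    niche_values,
    permanova,
    pielou_evenness,
    richness,
    shannon,
)


def _counts(rows, ids=None, taxa=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    return CountTable(pd.DataFrame(rows, index=ids, columns=taxa))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        ct = _counts([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 1]])
        m = bray_curtis_matrix(ct)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert m.values[0, 2] == pytest.approx(1.0)

    def test_raw_count_formula(self):
        ct = _counts([[3, 1], [1, 3]])
        m = bray_curtis_matrix(ct, normalize=False)
        assert m.values[0, 1] == pytest.approx(0.5)  # (2+2)/(4+4)

    def test_depth_invariance_when_normalized(self):
        ct1 = _counts([[3, 1], [2, 6]])
        ct2 = _counts([[30, 10], [1, 3]])
        m1 = bray_curtis_matrix(ct1)
        m2 = bray_curtis_matrix(ct2)
        assert m1.values[0, 1] == pytest.approx(m2.values[0, 1])

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 20, size=(4, 6)).astype(float)
        x[x.sum(axis=1) == 0, 0] = 1.0
        m = bray_curtis_matrix(_counts(x))
        assert (m.values >= -1e-12).all() and (m.values <= 1 + 1e-12).all()
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 0.0, atol=1e-12)


class TestAlphaDiversity:
    def test_equal_abundances_are_maximally_even(self):
        ct = _counts([[5, 5, 5, 5]])
        assert pielou_evenness(ct).iloc[0] == pytest.approx(1.0)

    def test_direct_formula_75_25(self):
        ct = _counts([[75, 25]])
        assert shannon(ct).iloc[0] == pytest.approx(0.5623, abs=1e-4)
        assert pielou_evenness(ct).iloc[0] == pytest.approx(0.8113, abs=1e-4)

    def test_single_taxon_sample(self):
        ct = _counts([[7, 0]])
        assert richness(ct).iloc[0] == 1
        assert math.isnan(pielou_evenness(ct).iloc[0])


class TestEnvDifference:
    def test_absolute_difference_and_missing(self):
        meta = SampleMetadata(
            pd.DataFrame(
                {"well_id": list("wxyz"), "collection_day": [0] * 4,
                 "pH": [11.5, 8.1, 9.0, np.nan]},
                index=list("abcd"),
            )
        )
        m = env_difference_matrix(meta, "pH")
        assert m.loc("a", "b") == pytest.approx(3.4)
        assert math.isnan(m.loc("a", "d"))

    def test_constant_variable_gives_zero_matrix(self):
        meta = SampleMetadata(
            pd.DataFrame({"well_id": list("www"), "collection_day": [0, 1, 2],
                          "pH": [8.0, 8.0, 8.0]}, index=list("abc"))
        )
        m = env_difference_matrix(meta, "pH")
        np.testing.assert_allclose(m.values, 0.0)

    def test_all_missing_is_error(self):
        meta = SampleMetadata(
            pd.DataFrame({"well_id": list("www"), "collection_day": [0, 1, 2],
                          "DIC": [np.nan] * 3}, index=list("abc"))
        )
        with pytest.raises(ValidationError):
            env_difference_matrix(meta, "DIC")


def _symmetric(rng, n):
    a = rng.uniform(0.1, 1.0, size=(n, n))
    a = np.triu(a, 1)
    a = a + a.T
    return a


class TestMantel:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        a = _symmetric(rng, 5)
        ids = tuple(f"s{i}" for i in range(5))
        m = PairwiseMatrix(ids, a, kind="distance")
        r, p = mantel(m, m, permutations=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_anticorrelation(self):
        rng = np.random.default_rng(1)
        a = _symmetric(rng, 5)
        ids = tuple(f"s{i}" for i in range(5))
        m1 = PairwiseMatrix(ids, a, kind="distance")
        neg = a.max() - a
        np.fill_diagonal(neg, 0)
        m2 = PairwiseMatrix(ids, neg, kind="distance")
        r, _ = mantel(m1, m2, permutations=49, seed=0)
        assert r == pytest.approx(-1.0)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        n = 4
        a = _symmetric(rng, n)
        b = _symmetric(rng, n)
        ids = tuple(f"s{i}" for i in range(n))
        m1 = PairwiseMatrix(ids, a, kind="distance")
        m2 = PairwiseMatrix(ids, b, kind="distance")
        i, j = np.tril_indices(n, k=-1)
        va = a[i, j]
        r_obs = np.corrcoef(va, b[i, j])[0, 1]
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            perm = np.array(perm)
            r_perm = np.corrcoef(va, b[perm[i], perm[j]])[0, 1]
            total += 1
            if abs(r_perm) >= abs(r_obs) - 1e-12:
                count += 1
        p_exact = count / total
        r, p_mc = mantel(m1, m2, permutations=999, seed=3)
        assert r == pytest.approx(r_obs, abs=1e-12)
        assert p_mc == pytest.approx(p_exact, abs=0.08)

    def test_missing_samples_dropped_listwise(self):
        rng = np.random.default_rng(3)
        n = 6
        a = _symmetric(rng, n)
        b = _symmetric(rng, n)
        b[0, :] = b[:, 0] = np.nan
        ids = tuple(f"s{i}" for i in range(n))
        m1 = PairwiseMatrix(ids, a, kind="distance")
        m2 = PairwiseMatrix(ids, b, kind="env_difference")
        r_full, _ = mantel(m1, m2, permutations=9, seed=0)
        sub = list(ids[1:])
        r_sub, _ = mantel(m1.select(sub), PairwiseMatrix(tuple(sub), b[1:, 1:], "env_difference"),
                          permutations=9, seed=0)
        assert r_full == pytest.approx(r_sub)

    def test_cross_check_against_skbio(self):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        rng = np.random.default_rng(4)
        n = 8
        a = _symmetric(rng, n)
        b = _symmetric(rng, n)
        ids = [f"s{i}" for i in range(n)]
        r_ours, _ = mantel(
            PairwiseMatrix(tuple(ids), a, "distance"),
            PairwiseMatrix(tuple(ids), b, "distance"),
            permutations=0,
        )
        r_skbio = skbio_mantel(
            DistanceMatrix(a, ids), DistanceMatrix(b, ids), permutations=0
        )[0]
        assert r_ours == pytest.approx(r_skbio, abs=1e-12)


class TestNicheValues:
    def test_single_sample_and_midpoint(self):
        ct = _counts([[4, 2], [0, 2]], ids=["x", "y"])
        meta = SampleMetadata(
            pd.DataFrame({"well_id": ["w", "w"], "collection_day": [0, 1],
                          "pH": [11.0, 9.0]}, index=["x", "y"])
        )
        niche = niche_values(ct, meta, "pH")
        lookup = dict(zip(niche.taxon_ids, niche.values))
        assert lookup["t0"] == pytest.approx(11.0)  # only in sample x
        assert lookup["t1"] == pytest.approx(10.0)  # equal counts at 11 and 9

    def test_bounded_by_variable_range(self):
        rng = np.random.default_rng(5)
        ct = _counts(rng.integers(0, 9, size=(4, 6)) + 1)
        ph = [7.5, 9.0, 10.1, 11.8]
        meta = SampleMetadata(
            pd.DataFrame({"well_id": list("wxyz"), "collection_day": range(4), "pH": ph},
                         index=[f"s{i}" for i in range(4)])
        )
        niche = niche_values(ct, meta, "pH")
        assert niche.values.min() >= min(ph) - 1e-12
        assert niche.values.max() <= max(ph) + 1e-12


class TestCorrelogram:
    def test_equal_width_class_edges(self):
        tree = simulate_tree(12, seed=0)
        dist = cophenetic_distances(tree)
        trait = evolve_trait(tree, 1.0, seed=1)
        res = mantel_correlogram(dist, trait, n_classes=4, permutations=49, seed=0)
        edges = res.class_edges
        assert len(edges) == 5
        np.testing.assert_allclose(np.diff(edges), edges[1], rtol=1e-9)
        assert res.n_pairs.sum() == 12 * 11 // 2

    def test_constant_niche_reports_null_signal(self):
        tree = simulate_tree(10, seed=2)
        dist = cophenetic_distances(tree)
        ids = dist.taxon_ids
        flat = NicheValueVector(ids, np.full(len(ids), 8.0), "pH")
        res = mantel_correlogram(dist, flat, n_classes=3, permutations=49, seed=0)
        assert not res.significant.any()

    def test_brownian_trait_gives_class_one_signal(self):
        tree = simulate_tree(40, seed=3)
        dist = cophenetic_distances(tree)
        trait = evolve_trait(tree, 1.0, seed=4)
        res = mantel_correlogram(dist, trait, permutations=199, seed=5)
        assert res.significant[0]
        assert res.r[0] > 0  # positive = close relatives have close niches


class TestPermanova:
    def _meta(self, ids, **cols):
        frame = pd.DataFrame(cols, index=ids)
        if "well_id" not in frame:
            frame["well_id"] = "w"
        if "collection_day" not in frame:
            frame["collection_day"] = 0
        return SampleMetadata(frame)

    def test_perfect_binary_factor_explains_everything(self):
        ct = _counts([[5, 0], [5, 0], [0, 5], [0, 5]])
        bc = bray_curtis_matrix(ct)
        meta = self._meta(list(ct.sample_ids), group=["g1", "g1", "g2", "g2"])
        res = permanova(bc, meta, ["group"], permutations=99, seed=0)
        assert res.table.loc["group", "R2"] == pytest.approx(1.0)

    def test_constant_term_gets_zero_ss(self):
        rng = np.random.default_rng(6)
        ct = _counts(rng.integers(1, 9, size=(6, 5)))
        bc = bray_curtis_matrix(ct)
        meta = self._meta(list(ct.sample_ids), flat=[1.0] * 6)
        res = permanova(bc, meta, ["flat"], permutations=49, seed=0)
        assert res.table.loc["flat", "R2"] == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(res.table.loc["flat", "F"])

    def test_one_factor_partition_matches_group_sum_oracle(self):
        # classical identity: SS_within = sum over groups of mean pairwise d^2/2...
        rng = np.random.default_rng(7)
        ct = _counts(rng.integers(1, 30, size=(6, 8)))
        bc = bray_curtis_matrix(ct)
        groups = ["a", "a", "a", "b", "b", "b"]
        meta = self._meta(list(ct.sample_ids), group=groups)
        res = permanova(bc, meta, ["group"], permutations=9, seed=0)
        d = bc.values
        n = 6
        ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
        ss_within = 0.0
        for g in ("a", "b"):
            idx = [i for i, gg in enumerate(groups) if gg == g]
            sub = d[np.ix_(idx, idx)]
            ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
        assert res.table.loc["Total", "sum_sq"] == pytest.approx(ss_total, rel=1e-8)
        assert res.table.loc["Residuals", "sum_sq"] == pytest.approx(ss_within, rel=1e-8)
        assert res.table.loc["group", "sum_sq"] == pytest.approx(
            ss_total - ss_within, rel=1e-8
        )

    def test_sequential_partition_sums_and_r2(self):
        rng = np.random.default_rng(8)
        ct = _counts(rng.integers(1, 40, size=(10, 7)))
        bc = bray_curtis_matrix(ct)
        meta = self._meta(
            list(ct.sample_ids),
            well_id=["w1"] * 5 + ["w2"] * 5,
            collection_day=rng.integers(0, 100, 10),
            pH=rng.normal(9, 1, 10),
        )
        res = permanova(bc, meta, ["well_id", "collection_day", "pH"], permutations=49, seed=0)
        t = res.table
        terms_ss = t.drop(index=["Residuals", "Total"])["sum_sq"].sum()
        assert terms_ss + t.loc["Residuals", "sum_sq"] == pytest.approx(
            t.loc["Total", "sum_sq"], rel=1e-8
        )
        assert t.drop(index="Total")["R2"].sum() == pytest.approx(1.0, rel=1e-8)
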