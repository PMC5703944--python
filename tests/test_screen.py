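"""t-score computation, exhaustive pair scanning, and gene-set accounting."""

import numpy as np
import pytest
from scipy import stats

from synpair import (
    IndividualScreen,
    PairScreen,
    gene_union,
    overlap_matrix,
    rank_individual,
    scan_pairs,
    t_score,
    t_scores,
)
from synpair.io import ScreenEntry, ScreenResult
from synpair.transform import CONVERSION_FUNCS, rank_transform


def brute_force_scan(R, labels, conversion, top_n, t_variant="welch"):
    """Independent double-loop oracle over all canonical pairs."""
    m = R.shape[0]
    scored = []
    for p in range(m):
        for q in range(p + 1, m):
            z = CONVERSION_FUNCS[conversion](R[p], R[q])
            scored.append((p, q, t_score(z, labels, t_variant)))
    scored.sort(key=lambda r: (-abs(r[2]), r[0], r[1]))
    return scored[:top_n]


class TestTScore:
    def test_null_case_is_zero(self):
        z = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert t_score(z, labels) == 0.0

    def test_perfect_separation_gives_infinite_sentinel(self):
        z = np.array([0.0, 0, 0, 1, 1, 1])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert np.isinf(t_score(z, labels))

    def test_sign_convention_mean0_minus_mean1(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        high_in_0 = np.array([5.0, 6, 7, 1, 2, 3])
        assert t_score(high_in_0, labels) > 0
        assert t_score(-high_in_0, labels) < 0

    @pytest.mark.parametrize("variant", ["welch", "pooled"])
    def test_matches_direct_formula_oracle(self, variant):
        rng = np.random.default_rng(100)
        for _ in range(100):
            n0 = int(rng.integers(2, 15))
            n1 = int(rng.integers(2, 15))
            z = rng.normal(size=n0 + n1)
            labels = np.r_[np.zeros(n0, int), np.ones(n1, int)]
            g0, g1 = z[:n0], z[n0:]
            m0, m1 = g0.mean(), g1.mean()
            v0, v1 = g0.var(ddof=1), g1.var(ddof=1)
            if variant == "welch":
                expected = (m0 - m1) / np.sqrt(v0 / n0 + v1 / n1)
            else:
                sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
                expected = (m0 - m1) / np.sqrt(sp2 * (1 / n0 + 1 / n1))
            assert t_score(z, labels, variant) == pytest.approx(expected,
                                                                abs=1e-10)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=24)
        labels = np.tile([0, 1], 12)
        ref = stats.ttest_ind(z[labels == 0], z[labels == 1],
                              equal_var=False).statistic
        assert t_score(z, labels) == pytest.approx(ref, abs=1e-12)

    def test_abs_t_invariant_under_label_swap(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=20)
        labels = np.tile([0, 1], 10)
        assert t_score(z, labels) == pytest.approx(-t_score(z, 1 - labels))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            t_score(np.arange(5.0), np.array([0, 1, 1, 1, 1]))


class TestScanPairs:
    def test_m2_returns_single_pair(self, random_dataset):
        ds = random_dataset(m=2, n=20, seed=1)
        with pytest.warns(UserWarning, match="exceeds"):
            res = scan_pairs(ds, conversion="abs", top_n=10)
        assert len(res) == 1
        assert res.entries[0].gene_p == "G0" and res.entries[0].gene_q == "G1"

    @pytest.mark.parametrize("conversion", ["sum", "diff", "mul", "sign", "abs"])
    def test_matches_brute_force_oracle(self, random_dataset, conversion):
        ds = random_dataset(m=12, n=20, seed=2)
        rm = rank_transform(ds)
        expected = brute_force_scan(rm.ranks, ds.labels, conversion, 5)
        res = scan_pairs(ds, conversion=conversion, top_n=5)
        got = [(ds.gene_ids.index(e.gene_p), ds.gene_ids.index(e.gene_q),
                e.t_score) for e in res.entries]
        assert got == expected  # pairs, order and scores bit-identical

    def test_block_size_does_not_change_output(self, random_dataset):
        ds = random_dataset(m=15, n=24, seed=3)
        reference = scan_pairs(ds, conversion="abs", top_n=8, block_size=512)
        for bs in (1, 3, 7, 100):
            res = scan_pairs(ds, conversion="abs", top_n=8, block_size=bs)
            assert [(e.gene_p, e.gene_q, e.t_score) for e in res.entries] == \
                   [(e.gene_p, e.gene_q, e.t_score) for e in reference.entries]

    def test_planted_pair_ranks_first(self):
        from synpair import simulate_abs_pairs

        ds = simulate_abs_pairs(k=1, n=200, seed=5, n_noise=10)
        res = scan_pairs(ds.to_expression_dataset(), conversion="abs", top_n=3)
        assert {res.entries[0].gene_p, res.entries[0].gene_q} == {"X1", "X2"}

    def test_abs_scan_invariant_under_gene_reversal(self, random_dataset):
        ds = random_dataset(m=10, n=20, seed=4)
        res_fwd = scan_pairs(ds, conversion="abs", top_n=5)
        rev = random_dataset(m=10, n=20, seed=4)
        rev.values = rev.values[::-1].copy()
        rev.gene_ids = rev.gene_ids[::-1]
        res_rev = scan_pairs(rev, conversion="abs", top_n=5)
        fwd = [(frozenset((e.gene_p, e.gene_q)), e.t_score) for e in res_fwd.entries]
        bwd = [(frozenset((e.gene_p, e.gene_q)), e.t_score) for e in res_rev.entries]
        assert fwd == bwd

    def test_infinite_t_ranks_first(self):
        from synpair import ExpressionDataset

        labels = np.array([0, 0, 0, 1, 1, 1])
        # GA and GB rank-diff is exactly -3 in class 0 and +3 in class 1:
        # zero within-class variance, unequal means -> infinite sentinel
        values = np.array([
            [1.0, 2, 3, 4, 5, 6],
            [4.0, 5, 6, 1, 2, 3],
            [0.3, 0.1, 0.4, 0.15, 0.9, 0.2],
            [0.5, 0.05, 0.6, 0.35, 0.8, 0.1],
        ])
        ds = ExpressionDataset(values=values,
                               gene_ids=["GA", "GB", "GC", "GD"],
                               sample_ids=[f"S{i}" for i in range(6)],
                               labels=labels)
        res = scan_pairs(ds, conversion="diff", top_n=6)
        top = res.entries[0]
        assert {top.gene_p, top.gene_q} == {"GA", "GB"}
        assert np.isinf(top.t_score)

    def test_noise_data_max_t_is_not_extreme(self, random_dataset):
        # labels independent of X: the best pair |t| should behave like an
        # extreme order statistic, comparable to a permutation reference
        ds = random_dataset(m=10, n=40, seed=6)
        observed = abs(scan_pairs(ds, conversion="abs", top_n=1)
                       .entries[0].t_score)
        rng = np.random.default_rng(60)
        null_max = []
        for _ in range(20):
            perm = rng.permutation(ds.n_samples)
            shuffled = random_dataset(m=10, n=40, seed=6)
            shuffled.labels = shuffled.labels[perm]
            null_max.append(abs(scan_pairs(shuffled, conversion="abs",
                                           top_n=1).entries[0].t_score))
        lo, hi = np.quantile(null_max, [0.0, 1.0])
        assert lo / 2 < observed < hi * 2


class TestIndividualRanking:
    def test_perfectly_separated_gene_ranks_first(self, random_dataset):
        ds = random_dataset(m=8, n=20, seed=7)
        ds.values[3] = ds.labels * 10.0  # deterministic function of the class
        res = rank_individual(ds, top_n=3)
        assert res.entries[0].gene_p == "G3"
        assert np.isinf(res.entries[0].t_score)

    def test_scores_match_per_gene_oracle(self, random_dataset):
        ds = random_dataset(m=8, n=20, seed=8)
        res = rank_individual(ds, top_n=8)
        oracle = {ds.gene_ids[j]: t_score(ds.values[j], ds.labels)
                  for j in range(8)}
        for e in res.entries:
            assert e.t_score == oracle[e.gene_p]
        scores = [abs(e.t_score) for e in res.entries]
        assert scores == sorted(scores, reverse=True)

    def test_top_n_equal_m_returns_all(self, random_dataset):
        ds = random_dataset(m=6, n=20, seed=9)
        res = rank_individual(ds, top_n=6)
        assert [e.rank for e in res.entries] == [1, 2, 3, 4, 5, 6]
        assert sorted(res.gene_union) == sorted(ds.gene_ids)


class TestGeneUnion:
    def _result(self, pairs):
        entries = [ScreenEntry(rank=i + 1, gene_p=p, gene_q=q, t_score=10.0 - i)
                   for i, (p, q) in enumerate(pairs)]
        return ScreenResult(method="abs", entries=entries, top_n=len(pairs),
                            gene_universe=("A", "B", "C", "D", "E", "F"))

    def test_dedup_first_appearance_order(self):
        res = self._result([("A", "B"), ("A", "C")])
        assert gene_union(res) == ["A", "B", "C"]

    def test_all_distinct_gives_2n(self):
        res = self._result([("A", "B"), ("C", "D"), ("E", "F")])
        assert len(gene_union(res)) == 6

    def test_matches_set_oracle(self, random_dataset):
        ds = random_dataset(m=10, n=20, seed=10)
        res = scan_pairs(ds, conversion="sum", top_n=12)
        expected = set()
        for e in res.entries:
            expected |= {e.gene_p, e.gene_q}
        assert set(gene_union(res)) == expected
        assert len(gene_union(res)) <= 2 * res.top_n


class TestOverlapMatrix:
    def test_identical_results_full_overlap(self, random_dataset):
        ds = random_dataset(m=10, n=20, seed=11)
        r = scan_pairs(ds, conversion="abs", top_n=5)
        mat = overlap_matrix([r, r])
        u = len(gene_union(r))
        np.testing.assert_array_equal(mat, [[u, u], [u, u]])

    def test_disjoint_unions_zero(self):
        def res(pairs):
            entries = [ScreenEntry(rank=i + 1, gene_p=p, gene_q=q, t_score=5.0)
                       for i, (p, q) in enumerate(pairs)]
            return ScreenResult(method="abs", entries=entries,
                                top_n=len(pairs),
                                gene_universe=("A", "B", "C", "D"))
        mat = overlap_matrix([res([("A", "B")]), res([("C", "D")])])
        assert mat[0, 1] == 0 and mat[1, 0] == 0

    def test_counts_match_set_oracle(self, random_dataset):
        ds = random_dataset(m=12, n=20, seed=12)
        results = [scan_pairs(ds, conversion=c, top_n=6)
                   for c in ("sum", "abs", "mul")]
        mat = overlap_matrix(results)
        for i, ri in enumerate(results):
            for j, rj in enumerate(results):
                assert mat[i, j] == len(set(gene_union(ri)) & set(gene_union(rj)))

    def test_mismatched_universe_rejected(self, random_dataset):
        r1 = scan_pairs(random_dataset(m=6, n=20, seed=13), "abs", top_n=2)
        ds2 = random_dataset(m=6, n=20, seed=13)
        ds2.gene_ids = [f"H{j}" for j in range(6)]
        r2 = scan_pairs(ds2, "abs", top_n=2)
        with pytest.raises(ValueError, match="universe"):
            overlap_matrix([r1, r2])


class TestEstimatorInterface:
    def test_pair_screen_sklearn_contract(self, random_dataset):
        ds = random_dataset(m=8, n=24, seed=14)
        est = PairScreen(conversion="abs", top_n=4)
        assert est.get_params()["conversion"] == "abs"
        Z = est.fit(ds.X(), ds.labels).transform(ds.X())
        assert Z.shape == (24, 4)
        assert est.pairs_.shape == (4, 2)
        assert np.all(est.pairs_[:, 0] < est.pairs_[:, 1])
        names = est.get_feature_names_out(ds.gene_ids)
        assert names[0].startswith("abs(")

    def test_individual_screen_selects_columns(self, random_dataset):
        ds = random_dataset(m=8, n=24, seed=15)
        est = IndividualScreen(top_n=3).fit(ds.X(), ds.labels)
        X_sel = est.transform(ds.X())
        assert X_sel.shape == (24, 3)
        assert est.get_support().sum() == 3

    def test_vectorized_t_matches_scalar(self, random_dataset):
        ds = random_dataset(m=6, n=20, seed=16)
        ts = t_scores(ds.values, ds.labels)
        for j in range(6):
            assert ts[j] == t_score(ds.values[j], ds.labels)
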