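"""Ranking metrics, running-sum enrichment scores, permutation testing."""

import numpy as np
import pandas as pd
import pytest

import lncsig as L
from lncsig.lsea import PermutationMode, RankMetric, RankedList

from oracles import brute_running_sum


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


def _labels(samples, n0):
    return {s: (0 if i < n0 else 1) for i, s in enumerate(samples)}


def _random_profile(rng, n_genes=40, n0=5, n1=5):
    expr = _expr(rng.normal(7, 1, (n_genes, n0 + n1)))
    return expr, _labels(list(expr.columns), n0)


class TestRankGenes:
    @pytest.mark.parametrize("metric", list(RankMetric))
    def test_identical_classes_score_zero(self, metric):
        expr = _expr(np.tile([[1.0, 2.0, 1.0, 2.0]], (3, 1)))
        labels = _labels(list(expr.columns), 2)
        ranked = L.rank_genes(expr, labels, metric)
        np.testing.assert_allclose(ranked.scores, 0.0)

    def test_diff_of_means_arithmetic(self):
        expr = _expr([[1.0, 3.0, 4.0, 6.0]])
        labels = _labels(list(expr.columns), 2)  # class0 = (1,3), class1 = (4,6)
        ranked = L.rank_genes(expr, labels, RankMetric.DIFF_OF_MEANS)
        assert ranked.scores[0] == pytest.approx(3.0)

    def test_signal2noise_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        expr, labels = _random_profile(rng)
        ranked = L.rank_genes(expr, labels, RankMetric.SIGNAL2NOISE)
        scores = dict(zip(ranked.genes, ranked.scores))
        c0 = [s for s, v in labels.items() if v == 0]
        c1 = [s for s, v in labels.items() if v == 1]
        for g in expr.index:
            x0, x1 = expr.loc[g, c0].to_numpy(), expr.loc[g, c1].to_numpy()
            s0 = max(x0.std(ddof=1), 0.2 * abs(x0.mean()), 0.2)
            s1 = max(x1.std(ddof=1), 0.2 * abs(x1.mean()), 0.2)
            assert scores[g] == pytest.approx(
                (x1.mean() - x0.mean()) / (s1 + s0)
            )

    def test_t_stat_matches_welch(self):
        rng = np.random.default_rng(12)
        expr, labels = _random_profile(rng)
        ranked = L.rank_genes(expr, labels, RankMetric.T_STAT)
        scores = dict(zip(ranked.genes, ranked.scores))
        c0 = [s for s, v in labels.items() if v == 0]
        c1 = [s for s, v in labels.items() if v == 1]
        from scipy import stats

        for g in expr.index:
            t, _ = stats.ttest_ind(
                expr.loc[g, c1], expr.loc[g, c0], equal_var=False
            )
            assert scores[g] == pytest.approx(float(t))

    def test_sorted_descending_with_id_tiebreak(self):
        expr = _expr([[1, 1, 5, 5], [0, 0, 9, 9], [1, 1, 5, 5]],
                     genes=["b", "a", "c"])
        labels = _labels(list(expr.columns), 2)
        ranked = L.rank_genes(expr, labels, RankMetric.DIFF_OF_MEANS)
        assert ranked.genes == ["a", "b", "c"]

    def test_small_class_falls_back_to_diff_of_means(self, caplog):
        expr = _expr([[1.0, 4.0, 6.0]])
        labels = {"s0": 0, "s1": 1, "s2": 1}
        ranked = L.rank_genes(expr, labels, RankMetric.SIGNAL2NOISE)
        assert ranked.scores[0] == pytest.approx(5.0 - 1.0)

    def test_empty_class_rejected(self):
        expr = _expr([[1.0, 2.0]])
        with pytest.raises(ValueError):
            L.rank_genes(expr, {"s0": 1, "s1": 1}, RankMetric.DIFF_OF_MEANS)


class TestEnrichmentScore:
    def test_hits_at_1_5_9_of_10_unweighted(self):
        """Walk with hits at ranks 1, 5, 9 (1-based), verified step by step."""
        genes = [f"g{i}" for i in range(10)]
        ranked = RankedList(genes=genes, scores=np.linspace(2, -2, 10))
        members = {"g0", "g4", "g8"}
        es, run, _ = L.enrichment_score(ranked, members, weight_exponent=0)
        flags = [g in members for g in genes]
        es_oracle, run_oracle = brute_running_sum(ranked.scores, flags, 0)
        np.testing.assert_allclose(run, run_oracle, atol=1e-12)
        assert es == pytest.approx(es_oracle) == pytest.approx(1 / 3)
        np.testing.assert_allclose(
            run,
            [0.3333, 0.1905, 0.0476, -0.0952, 0.2381,
             0.0952, -0.0476, -0.1905, 0.1429, 0.0],
            atol=5e-5,
        )

    def test_contiguous_top_hits_reach_es_one(self):
        genes = [f"g{i}" for i in range(12)]
        ranked = RankedList(genes=genes, scores=np.linspace(3, -3, 12))
        es, _, le = L.enrichment_score(ranked, set(genes[:4]), weight_exponent=0)
        assert es == pytest.approx(1.0)
        assert le == frozenset(genes[:4])

    def test_equal_scores_collapse_weighted_to_unweighted(self):
        genes = [f"g{i}" for i in range(15)]
        ranked = RankedList(genes=genes, scores=np.full(15, 2.0))
        members = {"g2", "g7", "g11"}
        es0, run0, _ = L.enrichment_score(ranked, members, 0)
        es1, run1, _ = L.enrichment_score(ranked, members, 1)
        assert es1 == pytest.approx(es0)
        np.testing.assert_allclose(run0, run1)

    @pytest.mark.parametrize("weight", [0, 1])
    def test_matches_brute_force_oracle(self, weight):
        rng = np.random.default_rng(30 + weight)
        for _ in range(40):
            n = int(rng.integers(10, 200))
            nh = int(rng.integers(1, min(20, n - 1) + 1))
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            members = set(rng.choice(genes, size=nh, replace=False))
            ranked = RankedList(genes=genes, scores=scores)
            es, run, _ = L.enrichment_score(ranked, members, weight)
            flags = [g in members for g in genes]
            es_oracle, run_oracle = brute_running_sum(scores, flags, weight)
            assert es == pytest.approx(es_oracle, abs=1e-9)
            np.testing.assert_allclose(run, run_oracle, atol=1e-9)

    def test_unweighted_walk_terminates_at_zero(self):
        rng = np.random.default_rng(44)
        for _ in range(20):
            n = int(rng.integers(5, 100))
            nh = int(rng.integers(1, n))
            genes = [f"g{i}" for i in range(n)]
            ranked = RankedList(genes=genes, scores=rng.normal(0, 1, n))
            members = set(rng.choice(genes, size=nh, replace=False))
            if nh == n:
                continue
            _, run, _ = L.enrichment_score(ranked, members, 0)
            assert abs(run[-1]) < 1e-9

    def test_es_bounded_by_one(self):
        rng = np.random.default_rng(55)
        for _ in range(30):
            n = int(rng.integers(5, 80))
            nh = int(rng.integers(1, n))
            genes = [f"g{i}" for i in range(n)]
            ranked = RankedList(
                genes=genes, scores=np.sort(rng.normal(0, 2, n))[::-1]
            )
            members = set(rng.choice(genes, size=nh, replace=False))
            es, _, _ = L.enrichment_score(ranked, members, 1)
            assert -1 - 1e-12 <= es <= 1 + 1e-12

    def test_leading_edge_for_negative_es(self):
        genes = [f"g{i}" for i in range(10)]
        ranked = RankedList(genes=genes, scores=np.linspace(1, -1, 10))
        members = {"g8", "g9"}  # bottom of the list
        es, run, le = L.enrichment_score(ranked, members, 0)
        assert es < 0
        assert le == frozenset({"g8", "g9"})

    def test_degenerate_sets_rejected(self):
        genes = [f"g{i}" for i in range(5)]
        ranked = RankedList(genes=genes, scores=np.arange(5.0))
        with pytest.raises(ValueError):
            L.enrichment_score(ranked, {"absent"}, 0)
        with pytest.raises(ValueError):
            L.enrichment_score(ranked, set(genes), 0)


def _toy_sets(genes, rng, n_sets=4, size=5):
    return [
        L.DrugLncRNASet(
            drug_name=f"d{j}",
            members=frozenset(rng.choice(genes, size=size, replace=False)),
            n_instances=1,
        )
        for j in range(n_sets)
    ]


class TestPermutationNull:
    def test_same_seed_identical_null(self):
        rng = np.random.default_rng(1)
        expr, labels = _random_profile(rng, n_genes=25)
        sets = _toy_sets(list(expr.index), rng)
        params = L.LseaParams(n_permutations=30, seed=7,
                              permutation_mode=PermutationMode.PHENOTYPE)
        a = L.permutation_null(expr, labels, sets, params)
        b = L.permutation_null(expr, labels, sets, params)
        np.testing.assert_array_equal(a, b)

    def test_single_permutation_shape(self):
        rng = np.random.default_rng(2)
        expr, labels = _random_profile(rng, n_genes=15)
        sets = _toy_sets(list(expr.index), rng, n_sets=3)
        params = L.LseaParams(n_permutations=1, seed=0)
        null = L.permutation_null(expr, labels, sets, params)
        assert null.shape == (3, 1)

    def test_null_mean_near_zero_on_exchangeable_data(self):
        """Monte-Carlo: label-exchangeable data gives a centred ES null."""
        rng = np.random.default_rng(3)
        expr, labels = _random_profile(rng, n_genes=30, n0=6, n1=6)
        sets = _toy_sets(list(expr.index), rng, n_sets=1, size=6)
        params = L.LseaParams(n_permutations=2000, seed=5, weight_exponent=0,
                              permutation_mode=PermutationMode.PHENOTYPE)
        null = L.permutation_null(expr, labels, sets, params)
        se = null.std() / np.sqrt(null.size)
        assert abs(null.mean()) < 3 * se + 1e-3

    def test_phenotype_mode_needs_two_per_class(self):
        rng = np.random.default_rng(4)
        expr = _expr(rng.normal(7, 1, (10, 3)))
        labels = {"s0": 0, "s1": 1, "s2": 1}
        sets = _toy_sets(list(expr.index), rng, n_sets=2, size=3)
        params = L.LseaParams(n_permutations=5,
                              permutation_mode=PermutationMode.PHENOTYPE)
        with pytest.raises(ValueError, match="gene_set"):
            L.permutation_null(expr, labels, sets, params)


class TestNormalizeAndTest:
    def test_zero_es_reports_nes_zero_and_maximal_p(self):
        null = np.array([[0.4, -0.3, 0.2, -0.1]])
        res = L.normalize_and_test(["d"], np.array([0.0]), null, [frozenset()], [3])
        assert res[0].nes == 0.0
        assert res[0].p_nominal == 1.0

    def test_observed_above_all_null_hits_addone_floor(self):
        rng = np.random.default_rng(6)
        null = np.abs(rng.normal(0, 0.2, (1, 99)))
        res = L.normalize_and_test(
            ["d"], np.array([0.95]), null, [frozenset()], [4]
        )
        assert res[0].p_nominal == pytest.approx(1 / (1 + 99))

    def test_fwer_dominates_nominal(self):
        rng = np.random.default_rng(7)
        null = rng.normal(0, 0.3, (5, 200))
        obs = rng.uniform(-0.8, 0.8, 5)
        res = L.normalize_and_test(
            ["a", "b", "c", "d", "e"], obs, null,
            [frozenset()] * 5, [3] * 5,
        )
        for r in res:
            assert r.p_fwer >= r.p_nominal - 1e-12

    def test_missing_sign_flagged_and_ranked_last(self):
        null = np.array([[0.1, 0.2, 0.3], [0.1, -0.2, 0.3]])
        res = L.normalize_and_test(
            ["neg_set", "ok"], np.array([-0.5, -0.5]), null,
            [frozenset()] * 2, [3, 3],
        )
        assert res[-1].drug_name == "neg_set"
        assert not res[-1].nes_defined


class TestLsea:
    def test_planted_top_genes_rank_first(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(40)]
        base = rng.normal(7, 1, (40, 1))
        data = base + rng.normal(0, 0.2, (40, 10))
        data[:6, 5:] += 2.0  # plant g0..g5 up in class 1
        expr = _expr(data, genes=genes)
        labels = _labels(list(expr.columns), 5)
        sets = [
            L.DrugLncRNASet("planted", frozenset(genes[:6]), 1),
            L.DrugLncRNASet("other", frozenset(genes[20:26]), 1),
        ]
        res = L.lsea(expr, labels, sets, L.LseaParams(n_permutations=200, seed=2))
        assert res[0].drug_name == "planted"
        assert res[0].es > 0.8

    def test_label_swap_negates_es_and_nes(self):
        rng = np.random.default_rng(10)
        expr, labels = _random_profile(rng, n_genes=30, n0=5, n1=5)
        swapped = {s: 1 - v for s, v in labels.items()}
        sets = _toy_sets(list(expr.index), rng, n_sets=3, size=6)
        params = L.LseaParams(n_permutations=100, seed=3,
                              permutation_mode=PermutationMode.PHENOTYPE)
        a = {r.drug_name: r for r in L.lsea(expr, labels, sets, params)}
        b = {r.drug_name: r for r in L.lsea(expr, swapped, sets, params)}
        for name in a:
            assert a[name].es == pytest.approx(-b[name].es, abs=1e-9)
            assert a[name].nes == pytest.approx(-b[name].nes, rel=0.2)

    def test_same_seed_identical_results(self):
        rng = np.random.default_rng(11)
        expr, labels = _random_profile(rng, n_genes=25, n0=4, n1=4)
        sets = _toy_sets(list(expr.index), rng, n_sets=3, size=5)
        params = L.LseaParams(n_permutations=50, seed=13)
        a = L.lsea(expr, labels, sets, params)
        b = L.lsea(expr, labels, sets, params)
        assert [
            (r.drug_name, r.es, r.nes, r.p_nominal, r.q_fdr, r.p_fwer)
            for r in a
        ] == [
            (r.drug_name, r.es, r.nes, r.p_nominal, r.q_fdr, r.p_fwer)
            for r in b
        ]

    def test_no_surviving_set_lists_overlaps(self):
        rng = np.random.default_rng(12)
        expr, labels = _random_profile(rng, n_genes=10)
        sets = [L.DrugLncRNASet("d", frozenset({"absent1", "absent2", "absent3"}), 1)]
        with pytest.raises(ValueError, match="overlap"):
            L.lsea(expr, labels, sets, L.LseaParams(n_permutations=5))
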