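import math

import numpy as np
import pandas as pd
import pytest

from netconcord import association, mebe
from netconcord.network import WeightedNetwork
from netconcord.nulls import NullDistribution, ScoredModule


def oracle_two_proportion_z(a, A, b, B):
    """Independent textbook implementation of the pooled z statistic."""
    p1, p2 = a / A, b / B
    p = (a + b) / (A + B)
    se = math.sqrt(p * (1 - p) * (1 / A + 1 / B))
    return (p1 - p2) / se


class TestTwoProportionZ:
    def test_hand_example(self):
        z, degenerate = association.two_proportion_z(10, 100, 50, 1000)
        assert not degenerate
        assert z == pytest.approx(2.099, abs=1e-3)

    def test_equal_proportions_zero(self):
        z, _ = association.two_proportion_z(5, 50, 20, 200)
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_a(self):
        zs = [association.two_proportion_z(a, 50, 0, 1000)[0] for a in range(1, 51)]
        assert all(z2 > z1 for z1, z2 in zip(zs, zs[1:]))

    def test_degenerate_pools(self):
        assert association.two_proportion_z(0, 10, 0, 10) == (0.0, True)
        assert association.two_proportion_z(10, 10, 10, 10) == (0.0, True)

    def test_agrees_with_oracle_on_random_tuples(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            A = int(rng.integers(1, 500))
            B = int(rng.integers(1, 5000))
            a = int(rng.integers(0, A + 1))
            b = int(rng.integers(0, B + 1))
            z, degenerate = association.two_proportion_z(a, A, b, B)
            if degenerate:
                assert a + b in (0, A + B)
                continue
            assert z == pytest.approx(oracle_two_proportion_z(a, A, b, B), abs=1e-9)


class TestQ95:
    def test_integer_grid_type7(self):
        # type-7 linear interpolation on 1..100 gives 95.05
        assert association.empirical_q95(np.arange(1.0, 101.0)) == pytest.approx(95.05)

    def test_degenerate_pool(self):
        assert association.empirical_q95(np.full(25, 3.5)) == 3.5

    def test_monotone_under_new_maximum(self):
        base = np.arange(1.0, 101.0)
        q = association.empirical_q95(base)
        assert association.empirical_q95(np.append(base, 1000.0)) >= q

    def test_small_pool_rejected(self):
        with pytest.raises(ValueError):
            association.empirical_q95(np.arange(10.0))


def make_null(n=200, seed=0, size=2):
    rng = np.random.default_rng(seed)
    m_g = rng.normal(size=n)
    m_s = rng.normal(size=n)
    m = m_g + m_s - np.abs(m_g - m_s) / math.sqrt(2)
    return NullDistribution(
        sizes=np.full(n, size, dtype=int), m=m, m_g=m_g, m_s=m_s,
        min_random_per_size=1,
    )


def module_of(m_g, m_s, size=2, n_seeds=1, tag="A"):
    genes = tuple(f"{tag}{i}" for i in range(size))
    return mebe.Module(
        genes=genes, seed=genes[0], m_g=m_g, m_s=m_s,
        m=m_g + m_s - abs(m_g - m_s) / math.sqrt(2), n_seeds=n_seeds,
    )


class TestProportionalTest:
    def test_counts_and_concordance(self):
        null = make_null(n=1000, seed=1)
        cut = association.concordance_cutoffs(null)
        high = module_of(10.0, 10.0, n_seeds=3)   # far beyond both cutoffs
        low = module_of(0.0, 0.0, n_seeds=7)
        res = association.proportional_test([high, low], null, cut)
        assert (res.a, res.A) == (3, 10)
        assert res.B == 1000
        assert res.p1 == pytest.approx(0.3)
        assert res.z > 0

    def test_random_pool_concordant_fraction_near_joint_rate(self):
        # with independent normal m_g/m_s in one stratum, the joint
        # exceedance of the two marginal Q95 cutoffs is near 0.25%-ish,
        # certainly below 5%
        null = make_null(n=5000, seed=2)
        cut = association.concordance_cutoffs(null)
        pool = null.normalized_pool()
        joint = np.mean((pool["z_g"] > cut[0]) & (pool["z_s"] > cut[1]))
        assert joint < 0.05


class TestMergeModules:
    def _network(self):
        genes = ["A", "B", "C", "D"]
        edges = [("A", "B"), ("B", "C"), ("C", "D")]
        return WeightedNetwork(genes, edges, np.ones(4), np.ones(4))

    def _scored(self, module, significant):
        return ScoredModule(module=module, z_m=0, z_g=0, z_s=0,
                            p_m=0, p_g=0, p_s=0, stratum_fallback=False,
                            significant=significant)

    def test_union_and_induced_edges(self):
        net = self._network()
        m1 = mebe.Module(genes=("A", "B"), seed="A", m_g=1, m_s=1, m=2)
        m2 = mebe.Module(genes=("B", "C"), seed="B", m_g=1, m_s=1, m=2)
        sub = association.merge_significant_modules(
            [self._scored(m1, True), self._scored(m2, True)], net
        )
        assert sub.genes == ["A", "B", "C"]
        assert sub.edges == [("A", "B"), ("B", "C")]

    def test_no_significant_modules_gives_none(self):
        net = self._network()
        m1 = mebe.Module(genes=("A", "B"), seed="A", m_g=1, m_s=1, m=2)
        assert association.merge_significant_modules(
            [self._scored(m1, False)], net) is None

    def test_concordance_mask_restricts(self):
        net = self._network()
        m1 = mebe.Module(genes=("A", "B"), seed="A", m_g=1, m_s=1, m=2)
        m2 = mebe.Module(genes=("C", "D"), seed="C", m_g=1, m_s=1, m=2)
        sub = association.merge_significant_modules(
            [self._scored(m1, True), self._scored(m2, True)], net,
            concordant=np.array([True, False]),
        )
        assert sub.genes == ["A", "B"]


def oracle_enrichment_score(scores: pd.Series, gene_set):
    """Brute-force running sum, coded independently of the implementation."""
    ranked = sorted(scores.sort_index().items(), key=lambda kv: -kv[1])
    n, nh = len(ranked), len(gene_set)
    denom = sum(abs(v) for g, v in ranked if g in gene_set)
    walk, best = 0.0, 0.0
    for g, v in ranked:
        if g in gene_set:
            walk += abs(v) / denom if denom > 0 else 1.0 / nh
        else:
            walk -= 1.0 / (n - nh)
        if abs(walk) > abs(best):
            best = walk
    return best


class TestGsea:
    def test_top_k_set_positive_and_matches_oracle(self):
        scores = pd.Series(np.arange(10.0, 0.0, -1.0),
                           index=[f"G{i}" for i in range(10)])
        gene_set = {"G0", "G1", "G2"}
        es = association.enrichment_score(scores, gene_set)
        assert es > 0
        assert es == pytest.approx(oracle_enrichment_score(scores, gene_set))

    def test_matches_oracle_on_all_small_instances(self):
        from itertools import combinations

        rng = np.random.default_rng(9)
        for n in range(3, 9):
            genes = [f"G{i}" for i in range(n)]
            scores = pd.Series(rng.normal(size=n), index=genes)
            for k in range(1, min(4, n - 1) + 1):
                for subset in combinations(genes, k):
                    es = association.enrichment_score(scores, set(subset))
                    assert es == pytest.approx(
                        oracle_enrichment_score(scores, set(subset)), abs=1e-12
                    )

    def test_whole_universe_degenerate(self):
        scores = pd.Series([3.0, 2.0, 1.0], index=["A", "B", "C"])
        assert association.enrichment_score(scores, {"A", "B", "C"}) == 0.0

    def test_empty_set_rejected(self):
        scores = pd.Series([1.0], index=["A"])
        with pytest.raises(ValueError):
            association.enrichment_score(scores, set())

    def test_nes_deterministic_and_normalized(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=30), index=[f"G{i}" for i in range(30)])
        top = set(scores.nlargest(5).index)
        es1, nes1 = association.gsea_nes(scores, top, n_perm=200,
                                         rng=np.random.default_rng(1))
        es2, nes2 = association.gsea_nes(scores, top, n_perm=200,
                                         rng=np.random.default_rng(1))
        assert (es1, nes1) == (es2, nes2)
        assert nes1 > 1.0  # a top-scoring set is enriched beyond the null mean

    def test_nes_combined_is_mean(self):
        sub = association.Subnetwork(genes=["A"], edges=[],
                                     nes_gwas=2.0, nes_expr=1.0)
        assert sub.nes_combined == pytest.approx(1.5)


class TestTraitSimilarity:
    def test_identical_sets_give_one(self):
        sets = {("t1", "c1"): {"A", "B"}, ("t2", "c1"): {"A", "B"}}
        mat = association.trait_similarity(sets)
        assert mat.loc["t1", "t2"] == 1.0

    def test_disjoint_sets_give_zero(self):
        sets = {("t1", "c1"): {"A"}, ("t2", "c1"): {"B"}}
        assert association.trait_similarity(sets).loc["t1", "t2"] == 0.0

    def test_direct_jaccard_value(self):
        sets = {("t1", "c1"): {"A", "B", "C"}, ("t2", "c1"): {"B", "C", "D"}}
        assert association.trait_similarity(sets).loc["t1", "t2"] == pytest.approx(0.5)

    def test_mean_across_shared_cell_types_only(self):
        sets = {
            ("t1", "c1"): {"A"}, ("t2", "c1"): {"A"},       # JI = 1
            ("t1", "c2"): {"A"}, ("t2", "c2"): {"B"},       # JI = 0
            ("t1", "c3"): {"A"},                             # t2 absent
        }
        assert association.trait_similarity(sets).loc["t1", "t2"] == pytest.approx(0.5)

    def test_no_shared_cell_type_is_missing(self):
        sets = {("t1", "c1"): {"A"}, ("t2", "c2"): {"B"}}
        mat = association.trait_similarity(sets)
        assert np.isnan(mat.loc["t1", "t2"])
        assert mat.loc["t1", "t1"] == 1.0
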