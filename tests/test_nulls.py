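import numpy as np
import pytest

from netconcord import mebe, nulls
from netconcord.config import RunConfig
from netconcord.network import WeightedNetwork
from netconcord.nulls import NullDistribution


class TestPermuteWeights:
    def test_multisets_and_edges_preserved(self, random_weighted_network):
        net = random_weighted_network(n_nodes=15, seed=1)
        perm = nulls.permute_weights(net, np.random.default_rng(0))
        np.testing.assert_allclose(np.sort(perm.v_g), np.sort(net.v_g))
        np.testing.assert_allclose(np.sort(perm.v_s), np.sort(net.v_s))
        assert perm.edge_index == net.edge_index

    def test_seed_contract(self, random_weighted_network):
        net = random_weighted_network(n_nodes=30, seed=2)
        p1 = nulls.permute_weights(net, np.random.default_rng(5))
        p2 = nulls.permute_weights(net, np.random.default_rng(5))
        p3 = nulls.permute_weights(net, np.random.default_rng(6))
        np.testing.assert_array_equal(p1.v_g, p2.v_g)
        assert not np.array_equal(p1.v_g, p3.v_g)

    def test_independent_permutations(self, random_weighted_network):
        # v_g and v_s are permuted independently: the gene-wise pairing
        # is destroyed (checked on a network where v_s = v_g)
        net = random_weighted_network(n_nodes=200, seed=3)
        net = net.with_weights(net.v_g, net.v_g.copy())
        perm = nulls.permute_weights(net, np.random.default_rng(1))
        assert not np.array_equal(perm.v_g, perm.v_s)


def small_config(**kw):
    defaults = dict(min_random_per_size=30, max_virtual_rounds=50, rng_seed=0)
    defaults.update(kw)
    return RunConfig(**defaults)


class TestVirtualSearch:
    def test_stops_when_strata_filled(self, random_weighted_network):
        net = random_weighted_network(n_nodes=12, p_edge=0.3, seed=4)
        real = mebe.search_all_seeds(net, 0.1, 0.1)
        sizes = {m.size for m in real}
        cfg = small_config()
        null = nulls.run_virtual_search(net, sizes, cfg)
        for s in sizes:
            counts = null.stratum_counts()
            assert counts.get(s, 0) >= cfg.min_random_per_size or s in null.deficient_sizes
        assert null.rounds_executed <= cfg.max_virtual_rounds

    def test_round_cap_flags_unreachable_size(self, random_weighted_network):
        net = random_weighted_network(n_nodes=12, p_edge=0.3, seed=4)
        cfg = small_config(max_virtual_rounds=3)
        null = nulls.run_virtual_search(net, {99}, cfg)
        assert null.rounds_executed == 3
        assert 99 in null.deficient_sizes

    def test_reproducible_given_seed(self, random_weighted_network):
        net = random_weighted_network(n_nodes=12, p_edge=0.3, seed=5)
        cfg = small_config(max_virtual_rounds=4)
        n1 = nulls.run_virtual_search(net, {2}, cfg, seed=11)
        n2 = nulls.run_virtual_search(net, {2}, cfg, seed=11)
        np.testing.assert_array_equal(n1.m, n2.m)
        np.testing.assert_array_equal(n1.sizes, n2.sizes)

    def test_self_normalization_centering(self, random_weighted_network):
        # z-normalizing each random module by its own size stratum gives
        # per-stratum mean 0 and sample sd 1
        # sparse 30-node graph: strata are populated by several distinct
        # local optima, so no usable stratum is degenerate (on a tiny dense
        # graph every round can rediscover the same global-max module,
        # which is a legitimate zero-variance hard error)
        net = random_weighted_network(n_nodes=30, p_edge=0.12, seed=0)
        cfg = small_config(min_random_per_size=5, max_virtual_rounds=10)
        null = nulls.run_virtual_search(net, set(), cfg)
        pool = null.normalized_pool()
        for size in np.unique(null.sizes):
            stratum, fallback = null.stratum_for(int(size))
            if fallback:
                continue
            z = pool["z_m"][null.sizes == size]
            assert abs(z.mean()) < 1e-9
            assert z.std(ddof=1) == pytest.approx(1.0)


def make_null(sizes, m, m_g=None, m_s=None, min_random=1):
    m = np.asarray(m, dtype=float)
    return NullDistribution(
        sizes=np.asarray(sizes, dtype=int),
        m=m,
        m_g=np.asarray(m_g, dtype=float) if m_g is not None else m.copy(),
        m_s=np.asarray(m_s, dtype=float) if m_s is not None else m.copy(),
        min_random_per_size=min_random,
    )


def module_of(size, m_g, m_s):
    genes = tuple(f"X{i}" for i in range(size))
    from math import sqrt
    m = m_g + m_s - abs(m_g - m_s) / sqrt(2)
    return mebe.Module(genes=genes, seed=genes[0], m_g=m_g, m_s=m_s, m=m)


class TestNormalizeAndTest:
    def test_stratum_z_hand_example(self):
        # stratum {1, 2, 3}: u = 2, sample sd = 1, so m = 3 -> z_m = 1
        null = make_null([2, 2, 2], [1.0, 2.0, 3.0])
        mod = module_of(2, 3.0, 3.0)
        mod = mebe.Module(genes=mod.genes, seed=mod.seed, m_g=3.0, m_s=3.0, m=3.0)
        [scored] = nulls.normalize_and_test([mod], null)
        assert scored.z_m == pytest.approx(1.0)

    def test_center_of_null_has_p_half(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=1001)
        null = make_null([2] * 1001, vals)
        mod = mebe.Module(genes=("A", "B"), seed="A",
                          m_g=float(vals.mean()), m_s=float(vals.mean()),
                          m=float(vals.mean()))
        [scored] = nulls.normalize_and_test([mod], null)
        assert scored.p_m == pytest.approx(0.5, abs=0.05)
        assert scored.z_m == pytest.approx(0.0, abs=1e-9)

    def test_beyond_pool_p_zero(self):
        null = make_null([2] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])
        mod = mebe.Module(genes=("A", "B"), seed="A", m_g=99.0, m_s=99.0, m=99.0)
        [scored] = nulls.normalize_and_test([mod], null)
        assert scored.p_m == 0.0
        assert scored.significant

    def test_zero_variance_stratum_raises(self):
        null = make_null([2, 2, 3, 3], [1.0, 1.0, 1.0, 2.0])
        mod = mebe.Module(genes=("A", "B"), seed="A", m_g=1.0, m_s=1.0, m=1.0)
        with pytest.raises(ValueError, match="zero-variance"):
            nulls.normalize_and_test([mod], null)

    def test_deficient_size_borrows_nearest_larger(self):
        null = make_null([2, 2, 2, 4, 4, 4], [1.0, 2, 3, 10, 11, 12],
                         min_random=3)
        assert null.stratum_for(3) == (4, True)   # tie 2 vs 4 -> larger
        assert null.stratum_for(2) == (2, False)
        assert null.stratum_for(9) == (4, True)
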