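import numpy as np
import networkx as nx
import pytest

import oracles as O
from conftest import make_network
from trtnet.construction import WEIGHTED
from trtnet.metrics import (ModulePartition, assortativity, betweenness,
                            characteristic_path_length, clustering, degree,
                            global_efficiency, global_metrics, hierarchy,
                            local_efficiency, modularity, nodal_efficiency,
                            nodal_metrics, participation, random_rewire,
                            shortest_path_lengths, small_world,
                            synchronization)


def star(n):
    a = np.zeros((n, n))
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


def complete(n):
    return np.ones((n, n)) - np.eye(n)


def path_graph(n):
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


def random_weighted(n, p, seed):
    rng = np.random.default_rng(seed)
    a = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(iu[0].size) < p
    w = rng.uniform(0.5, 1.5, iu[0].size) * mask
    a[iu] = w
    return a + a.T


class TestDegreeAndPaths:
    def test_star_and_complete_degrees(self):
        k = degree(make_network(star(6)))
        assert k[0] == 5 and np.all(k[1:] == 1)
        assert np.all(degree(make_network(complete(5))) == 4)

    def test_weighted_degree_is_strength(self):
        a = random_weighted(8, 0.5, 0)
        net = make_network(a, WEIGHTED)
        assert np.allclose(degree(net), a.sum(axis=0))

    def test_path_graph_distance(self):
        d = shortest_path_lengths(make_network(path_graph(3)))
        assert d[0, 2] == 2

    def test_reciprocal_weight_convention(self):
        a = np.zeros((2, 2))
        a[0, 1] = a[1, 0] = 0.5
        d = shortest_path_lengths(make_network(a, WEIGHTED))
        assert d[0, 1] == pytest.approx(2.0)

    def test_unreachable_is_infinite(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1
        d = shortest_path_lengths(make_network(a))
        assert np.isinf(d[0, 2])


class TestEfficiencyAndPathLength:
    def test_complete_graph_unit_values(self):
        net = make_network(complete(6))
        assert characteristic_path_length(net) == pytest.approx(1.0)
        assert global_efficiency(net) == pytest.approx(1.0)
        assert local_efficiency(net) == pytest.approx(1.0)

    def test_edgeless_graph_zero_efficiency(self):
        net = make_network(np.zeros((4, 4)))
        assert global_efficiency(net) == 0.0

    def test_p4_efficiency_by_pair_enumeration(self):
        # pairs at distance 1: 3, distance 2: 2, distance 3: 1 (each ordered
        # twice over 4*3 ordered pairs)
        expected = (3 / 1 + 2 / 2 + 1 / 3) * 2 / (4 * 3)
        net = make_network(path_graph(4))
        assert global_efficiency(net) == pytest.approx(expected, abs=1e-12)

    def test_star_leaf_nodal_efficiency(self):
        e = nodal_efficiency(make_network(star(6)))
        assert e[0] == pytest.approx(1.0)  # center reaches all in 1 hop
        assert e[1] == pytest.approx((1 + 4 * 0.5) / 5)

    def test_isolated_node_efficiency_zero(self):
        a = path_graph(3)
        a = np.pad(a, (0, 1))
        e = nodal_efficiency(make_network(a))
        assert e[3] == 0.0


class TestClustering:
    def test_complete_and_star(self):
        c, cp = clustering(make_network(complete(5)))
        assert np.allclose(c, 1.0) and cp == pytest.approx(1.0)
        c, cp = clustering(make_network(star(6)))
        assert np.allclose(c, 0.0) and cp == 0.0

    def test_triangle_with_pendant(self):
        a = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (1, 2), (0, 3)]:
            a[i, j] = a[j, i] = 1
        c, _ = clustering(make_network(a))
        assert c[0] == pytest.approx(1.0 / 3.0)  # 1 edge among 3 neighbours
        assert c[3] == 0.0

    def test_weighted_onnela_bounded_and_scale_invariant(self):
        a = random_weighted(10, 0.6, 1)
        c1, _ = clustering(make_network(a, WEIGHTED))
        c2, _ = clustering(make_network(3.7 * a, WEIGHTED))
        assert np.all((c1 >= 0) & (c1 <= 1))
        # max-weight normalisation makes Onnela clustering scale-invariant
        assert np.allclose(c1, c2, atol=1e-12)


class TestBetweenness:
    def test_path_middle_and_star_center(self):
        b = betweenness(make_network(path_graph(3)))
        assert b[1] == pytest.approx(1.0)
        n = 8
        b = betweenness(make_network(star(n)))
        assert b[0] == pytest.approx((n - 1) * (n - 2) / 2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_weighted_matches_geodesic_enumeration(self, seed):
        a = random_weighted(8, 0.5, seed)
        b = betweenness(make_network(a, WEIGHTED))
        assert np.allclose(b, O.brute_betweenness(a, True), atol=1e-9)


class TestRewireAndSmallWorld:
    def test_degree_sequence_preserved(self):
        a = random_weighted(15, 0.3, 3) > 0
        net = make_network(a.astype(float))
        surr = random_rewire(net, seed=0)
        assert np.array_equal(np.sort(degree(net)), np.sort(degree(surr)))
        assert not np.array_equal(net.adjacency, surr.adjacency)

    def test_weighted_rewire_preserves_weight_multiset(self):
        a = random_weighted(12, 0.4, 4)
        net = make_network(a, WEIGHTED)
        surr = random_rewire(net, seed=1)
        iu = np.triu_indices(12, 1)
        assert np.allclose(np.sort(a[iu][a[iu] > 0]),
                           np.sort(surr.adjacency[iu][surr.adjacency[iu] > 0]))

    def test_complete_graph_unswappable_warns(self):
        net = make_network(complete(5))
        with pytest.warns(RuntimeWarning, match="no feasible"):
            surr = random_rewire(net, seed=0)
        assert np.array_equal(surr.adjacency, net.adjacency)

    def test_surrogate_clustering_matches_density(self):
        # rewired Erdos-Renyi stays Erdos-Renyi-like: E[Cp] ~ edge density
        g = nx.gnp_random_graph(20, 0.4, seed=5)
        a = nx.to_numpy_array(g)
        net = make_network(a)
        density = a.sum() / (20 * 19)
        cps = []
        rng = np.random.default_rng(0)
        for _ in range(100):
            _, cp = clustering(random_rewire(net, seed=rng))
            cps.append(cp)
        assert np.mean(cps) == pytest.approx(density, abs=0.05)

    def test_er_graph_near_unit_gamma_lambda(self):
        g = nx.gnp_random_graph(24, 0.35, seed=1)
        net = make_network(nx.to_numpy_array(g))
        gamma, lam, sigma = small_world(net, n_random=40, seed=2)
        assert gamma == pytest.approx(1.0, abs=0.25)
        assert lam == pytest.approx(1.0, abs=0.1)
        assert sigma == gamma / lam

    def test_ring_lattice_high_gamma(self):
        g = nx.watts_strogatz_graph(100, 6, 0.0, seed=0)  # regular ring
        net = make_network(nx.to_numpy_array(g))
        gamma, lam, sigma = small_world(net, n_random=20, seed=3)
        assert gamma > 3.0
        assert sigma == pytest.approx(gamma / lam, abs=1e-12)


class TestSecondOrder:
    def test_star_assortativity_minus_one(self):
        assert assortativity(make_network(star(7))) == pytest.approx(-1.0)

    def test_regular_graph_assortativity_undefined(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        assert np.isnan(assortativity(make_network(a)))

    def test_assortativity_matches_edge_list_oracle(self):
        a = (random_weighted(10, 0.45, 6) > 0).astype(float)
        net = make_network(a)
        assert assortativity(net) == pytest.approx(O.brute_assortativity(a),
                                                   abs=1e-10)

    def test_hierarchy_recovers_planted_slope(self, rng):
        # regression oracle on a noisy power law c = k^-1.5 * exp(eps):
        # check our estimator against the closed-form slope on the same graph
        a = (random_weighted(30, 0.3, 7) > 0).astype(float)
        net = make_network(a)
        h = hierarchy(net)
        assert h == pytest.approx(O.brute_hierarchy(a, False), abs=1e-10)

    def test_hierarchy_degenerate_flagged(self):
        assert np.isnan(hierarchy(make_network(star(5))))

    def test_synchronization_complete_and_disconnected(self):
        assert synchronization(make_network(complete(6))) == pytest.approx(1.0)
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        assert synchronization(make_network(a)) == 0.0

    def test_p4_synchronization_eigendecomposition_oracle(self):
        a = path_graph(4)
        s = synchronization(make_network(a))
        assert s == pytest.approx(O.brute_synchronization(a), abs=1e-12)


class TestModularityAndParticipation:
    def test_two_cliques_q_half(self):
        a = np.zeros((10, 10))
        a[:5, :5] = complete(5)
        a[5:, 5:] = complete(5)
        part, q = modularity(make_network(a))
        assert part.n_modules == 2
        assert q == pytest.approx(0.5)
        assert len(set(part.labels[:5])) == 1
        assert len(set(part.labels[5:])) == 1

    def test_complete_graph_single_module(self):
        part, q = modularity(make_network(complete(6)))
        assert part.n_modules == 1
        assert q <= 0 + 1e-12

    def test_planted_three_blocks_recovered(self):
        rng = np.random.default_rng(9)
        n_block = 10
        a = np.zeros((30, 30))
        for i in range(30):
            for j in range(i + 1, 30):
                p = 0.9 if i // n_block == j // n_block else 0.05
                if rng.random() < p:
                    a[i, j] = a[j, i] = 1
        part, _ = modularity(make_network(a))
        assert part.n_modules == 3
        for blk in range(3):
            labs = part.labels[blk * n_block:(blk + 1) * n_block]
            assert len(set(labs)) == 1

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity(make_network(np.zeros((4, 4))))

    def test_participation_within_module_zero(self):
        a = np.zeros((6, 6))
        a[:3, :3] = complete(3)
        a[3:, 3:] = complete(3)
        part = ModulePartition(np.array([0, 0, 0, 1, 1, 1]))
        pc, pcnorm = participation(make_network(a), part)
        assert np.allclose(pc, 0.0)
        assert np.allclose(pcnorm, 0.0)

    def test_even_split_pc_half_pcnorm_one(self):
        # node 0 has one edge into each of two modules
        a = np.zeros((5, 5))
        a[0, 1] = a[1, 0] = 1  # module 0
        a[0, 3] = a[3, 0] = 1  # module 1
        a[1, 2] = a[2, 1] = 1
        a[3, 4] = a[4, 3] = 1
        part = ModulePartition(np.array([0, 0, 0, 1, 1]))
        pc, pcnorm = participation(make_network(a), part)
        assert pc[0] == pytest.approx(0.5)
        assert pcnorm[0] == pytest.approx(1.0)

    def test_single_module_pcnorm_flagged(self):
        part = ModulePartition(np.zeros(5, dtype=int))
        _, pcnorm = participation(make_network(complete(5)), part)
        assert np.all(np.isnan(pcnorm))

    def test_unlabeled_nodes_rejected(self):
        with pytest.raises(ValueError):
            participation(make_network(complete(5)),
                          ModulePartition(np.array([0, 1])))


class TestInvariances:
    def test_isomorphism_invariance(self):
        a = (random_weighted(9, 0.4, 11) > 0).astype(float)
        rng = np.random.default_rng(1)
        perm = rng.permutation(9)
        pa = a[np.ix_(perm, perm)]
        na, nb = make_network(a), make_network(pa)
        assert clustering(na)[1] == pytest.approx(clustering(nb)[1], 1e-12)
        assert characteristic_path_length(na) == pytest.approx(
            characteristic_path_length(nb), 1e-12)
        assert np.allclose(degree(na)[perm], degree(nb))
        assert np.allclose(betweenness(na)[perm], betweenness(nb), atol=1e-9)

    def test_weighted_scale_covariance(self):
        a = random_weighted(10, 0.5, 12)
        c = 2.5
        n1 = make_network(a, WEIGHTED)
        n2 = make_network(c * a, WEIGHTED)
        # distances scale by 1/c, so efficiencies scale by c
        assert global_efficiency(n2) == pytest.approx(
            c * global_efficiency(n1), rel=1e-10)
        assert np.allclose(nodal_efficiency(n2), c * nodal_efficiency(n1))
        # binarized view is unchanged
        b1 = make_network((a > 0).astype(float))
        b2 = make_network((c * a > 0).astype(float))
        assert np.array_equal(b1.adjacency, b2.adjacency)

    def test_sigma_identity(self):
        g = nx.gnp_random_graph(15, 0.4, seed=2)
        net = make_network(nx.to_numpy_array(g))
        gamma, lam, sigma = small_world(net, n_random=10, seed=0)
        assert sigma == pytest.approx(gamma / lam, abs=1e-12)


def test_bundled_metrics_complete_graph():
    gm = global_metrics(make_network(complete(6)), n_random=5, seed=0)
    assert gm.Cp == pytest.approx(1.0)
    assert gm.Lp == pytest.approx(1.0)
    assert gm.Eglob == pytest.approx(1.0)
    assert gm.Eloc == pytest.approx(1.0)
    assert gm.synchronization == pytest.approx(1.0)
    assert gm.n_modules == 1
    nm = nodal_metrics(make_network(complete(6)))
    assert np.all(nm.degree == 5)
    assert np.allclose(nm.clustering, 1.0)
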