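"""topology: the ten node indices against hand values and brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from netdisrupt import topology

import oracles


class TestShortestPathKernel:
    def test_c4_two_shortest_paths_to_opposite(self, c4):
        dist, sigma = topology.single_source_shortest_paths(c4, 1)
        assert dist[3] == 2
        assert sigma[3] == 2

    def test_path_single_route(self, path3):
        dist, sigma = topology.single_source_shortest_paths(path3, "A")
        assert dist["C"] == 2 and sigma["C"] == 1

    def test_unknown_source_raises(self, path3):
        with pytest.raises(KeyError):
            topology.single_source_shortest_paths(path3, "Z")

    def test_sigma_matches_enumeration(self, random_graphs):
        for g in random_graphs[:5]:
            s = next(iter(g))
            dist, sigma = topology.single_source_shortest_paths(g, s)
            for t in dist:
                assert sigma[t] == oracles.brute_sigma(g, s, t), (s, t)


class TestLocalIndices:
    def test_triangle(self, triangle):
        t = topology.degree_and_local_indices(triangle)
        assert (t["degree"] == 2).all()
        assert (t["clusteringCoefficient"] == 1.0).all()

    def test_path_center(self, path3):
        t = topology.degree_and_local_indices(path3)
        assert t.loc["B", "clusteringCoefficient"] == 0.0
        assert t.loc["B", "neighborhoodConnectivity"] == 1.0

    def test_star(self):
        star = nx.star_graph(4)  # center 0, leaves 1..4
        t = topology.degree_and_local_indices(star)
        assert t.loc[0, "clusteringCoefficient"] == 0.0
        assert t.loc[0, "neighborhoodConnectivity"] == 1.0
        assert (t.loc[1:, "neighborhoodConnectivity"] == 4.0).all()


class TestPathIndices:
    def test_path_hand_values(self, path3):
        t = topology.path_indices(path3)
        assert t.loc["B", "eccentricity"] == 1
        assert t.loc["B", "averageShortestPathLength"] == 1.0
        assert t.loc["B", "closenessCentrality"] == 1.0
        assert t.loc["A", "averageShortestPathLength"] == 1.5
        assert t.loc["A", "closenessCentrality"] == pytest.approx(2 / 3)
        # radiality: (diam + 1 - asp)/diam with diam = 2
        assert t.loc["A", "radiality"] == pytest.approx(0.75)
        assert t.loc["B", "radiality"] == 1.0

    def test_max_radiality_at_min_asp(self, random_graphs):
        for g in random_graphs[:5]:
            t = topology.path_indices(g)
            for comp in nx.connected_components(g):
                if len(comp) < 2:
                    continue
                sub = t.loc[sorted(comp)]
                assert sub["radiality"].idxmax() == sub["averageShortestPathLength"].idxmin()

    def test_isolated_nodes_all_zero(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("Z")
        t = topology.path_indices(g)
        assert (t.loc["Z"] == 0).all()


class TestBetweennessStress:
    def test_path_center(self, path3):
        t = topology.betweenness_and_stress(path3, normalized=True)
        assert t.loc["B", "betweennessCentrality"] == 1.0
        assert t.loc["B", "stress"] == 1

    def test_c4_enumeration(self, c4):
        raw = topology.betweenness_and_stress(c4, normalized=False)
        norm = topology.betweenness_and_stress(c4, normalized=True)
        assert (raw["stress"] == 1).all()
        assert np.allclose(raw["betweennessCentrality"], 0.5)
        assert np.allclose(norm["betweennessCentrality"], 0.5 / 3)

    def test_matches_brute_force(self, random_graphs):
        for g in random_graphs[:6]:
            t = topology.betweenness_and_stress(g, normalized=False)
            betw, stress = oracles.brute_betweenness_stress(g)
            for v in g:
                assert t.loc[v, "betweennessCentrality"] == pytest.approx(betw[v])
                assert t.loc[v, "stress"] == pytest.approx(stress[v])

    def test_matches_networkx_on_connected(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            g = nx.connected_watts_strogatz_graph(18, 4, 0.3,
                                                  seed=int(rng.integers(2**31)))
            t = topology.betweenness_and_stress(g, normalized=True)
            ref = nx.betweenness_centrality(g, normalized=True)
            assert np.allclose(t["betweennessCentrality"], [ref[v] for v in g])


class TestIndexTable:
    def test_k3_all_indices(self, triangle):
        t = topology.compute_index_table(triangle)
        expect = {
            "degree": 2, "clusteringCoefficient": 1, "betweennessCentrality": 0,
            "stress": 0, "eccentricity": 1, "averageShortestPathLength": 1,
            "closenessCentrality": 1, "radiality": 1,
        }
        for col, val in expect.items():
            assert (t[col] == val).all(), col

    def test_invariants_on_random_graphs(self, random_graphs):
        for g in random_graphs:
            t = topology.compute_index_table(g)
            vals = t[list(topology.INDEX_COLUMNS)].to_numpy()
            assert np.isfinite(vals).all() and (vals >= 0).all()
            assert t["degree"].mean() == pytest.approx(2 * g.number_of_edges() / len(g))
            active = t["averageShortestPathLength"] > 0
            assert np.allclose(t.loc[active, "closenessCentrality"],
                               1 / t.loc[active, "averageShortestPathLength"])
            nz = t["degree"] > 0
            assert (t.loc[nz, "eccentricity"] >=
                    t.loc[nz, "averageShortestPathLength"]).all()

    def test_full_table_matches_oracles(self, random_graphs):
        for g in random_graphs[:4]:
            t = topology.compute_index_table(g, normalized_betweenness=False)
            ecc, asp, clo, rad = oracles.brute_path_indices(g)
            clus, nc, tc = oracles.brute_local_indices(g)
            betw, stress = oracles.brute_betweenness_stress(g)
            for v in g:
                row = t.loc[v]
                assert row["eccentricity"] == pytest.approx(ecc[v])
                assert row["averageShortestPathLength"] == pytest.approx(asp[v])
                assert row["closenessCentrality"] == pytest.approx(clo[v])
                assert row["radiality"] == pytest.approx(rad[v])
                assert row["clusteringCoefficient"] == pytest.approx(clus[v])
                assert row["neighborhoodConnectivity"] == pytest.approx(nc[v])
                assert row["topologicalCoefficient"] == pytest.approx(tc[v])
                assert row["betweennessCentrality"] == pytest.approx(betw[v])
                assert row["stress"] == pytest.approx(stress[v])

    def test_betweenness_sum_identity(self, random_graphs):
        # sum of raw betweenness = sum over pairs of mean interior path length
        for g in random_graphs[:4]:
            t = topology.betweenness_and_stress(g, normalized=False)
            total = 0.0
            import itertools
            for s, u in itertools.combinations(list(g), 2):
                if not nx.has_path(g, s, u):
                    continue
                paths = list(nx.all_shortest_paths(g, s, u))
                total += np.mean([len(p) - 2 for p in paths])
            assert t["betweennessCentrality"].sum() == pytest.approx(total)

    def test_adding_edge_never_increases_eccentricity(self, random_graphs):
        rng = np.random.default_rng(11)
        for g in random_graphs[:5]:
            g = g.copy()
            before = topology.path_indices(g)["eccentricity"]
            nodes = list(g)
            candidates = [(a, b) for i, a in enumerate(nodes)
                          for b in nodes[i + 1:] if not g.has_edge(a, b)]
            if not candidates:
                continue
            a, b = candidates[int(rng.integers(len(candidates)))]
            g.add_edge(a, b)
            after = topology.path_indices(g)["eccentricity"]
            joined = (before > 0) & (after > 0)  # components may merge
            assert (after[joined] <= before[joined]).all()

    def test_relabeling_invariance(self, random_graphs):
        g = random_graphs[0]
        perm = {v: f"X{v}" for v in g}
        t1 = topology.compute_index_table(g)
        t2 = topology.compute_index_table(nx.relabel_nodes(g, perm))
        for v in g:
            assert np.allclose(t1.loc[v, list(topology.INDEX_COLUMNS)].astype(float),
                               t2.loc[perm[v], list(topology.INDEX_COLUMNS)].astype(float))

    def test_tsv_round_trip_bit_exact(self, tmp_path, random_graphs):
        t = topology.compute_index_table(random_graphs[1])
        p = tmp_path / "idx.tsv"
        topology.write_index_table(t, p)
        back = topology.read_index_table(p)
        assert np.array_equal(back.to_numpy(), t.to_numpy())
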