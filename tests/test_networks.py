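"""SRI arithmetic, network construction, the four centrality measures."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from flocknet.arrivals import DyadCounts
from flocknet.networks import (build_network, compute_centralities,
                               compute_sri, summarize_event)


def individuals_table(sexes: dict) -> pd.DataFrame:
    return pd.DataFrame({"individual_id": list(sexes),
                         "sex": list(sexes.values()),
                         "cohort": 2014})


def power_iteration(a: np.ndarray, iters: int = 20_000) -> np.ndarray:
    # shift by the max row sum so the dominant eigenvalue is unique in
    # magnitude even on bipartite graphs (same leading eigenvector)
    shift = a.sum(axis=1).max()
    m = a + shift * np.eye(a.shape[0])
    v = np.ones(a.shape[0])
    for _ in range(iters):
        w = m @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return v
        v = w / nrm
    return np.abs(v) / np.abs(v).max()


class TestSRI:
    def test_hand_computed_value(self):
        # x=2, n_a=4, n_b=3 -> 2 / (2 + 2 + 1) = 0.4
        counts = DyadCounts(x={("A", "B"): 2}, n={"A": 4, "B": 3})
        sri = compute_sri(counts)
        assert sri.get("A", "B") == pytest.approx(0.4, abs=1e-12)

    def test_endpoints(self):
        never = DyadCounts(x={}, n={"A": 3, "B": 2})
        assert compute_sri(never).get("A", "B") == 0.0
        always = DyadCounts(x={("A", "B"): 5}, n={"A": 5, "B": 5})
        assert compute_sri(always).get("A", "B") == 1.0

    def test_inconsistent_counts_rejected(self):
        counts = DyadCounts(x={("A", "B"): 4}, n={"A": 3, "B": 5})
        with pytest.raises(ValueError, match="exceed"):
            compute_sri(counts)

    @pytest.mark.parametrize("seed", range(20))
    def test_bounds_and_symmetry_on_random_counts(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"B{k}" for k in range(8)]
        n = {i: int(rng.integers(1, 20)) for i in ids}
        x = {}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                x[(a, b)] = int(rng.integers(0, min(n[a], n[b]) + 1))
        sri = compute_sri(DyadCounts(x=x, n=n))
        for (a, b), v in sri.sri.items():
            assert 0.0 <= v <= 1.0
            assert sri.get(b, a) == v


class TestBuildNetwork:
    def test_bipartite_keeps_only_opposite_sex_edges(self):
        from flocknet.networks import SRIMatrix
        sri = SRIMatrix(sri={("A", "B"): 0.5, ("B", "C"): 0.4,
                             ("A", "C"): 0.3})
        ind = individuals_table({"A": 1, "B": 0, "C": 1})
        bip = build_network(sri, ind, bipartite=True)
        assert set(map(frozenset, bip.edges)) == {frozenset({"A", "B"}),
                                                  frozenset({"B", "C"})}

    def test_all_same_sex_component_removed(self):
        from flocknet.networks import SRIMatrix
        sri = SRIMatrix(sri={("A", "B"): 0.5})
        ind = individuals_table({"A": 1, "B": 1})
        bip = build_network(sri, ind, bipartite=True)
        assert bip.number_of_nodes() == 0

    def test_missing_sex_in_bipartite_mode_names_individual(self):
        from flocknet.networks import SRIMatrix
        sri = SRIMatrix(sri={("A", "B"): 0.5})
        ind = individuals_table({"A": 1})
        with pytest.raises(ValueError, match="'B'"):
            build_network(sri, ind, bipartite=True)

    def test_degree_zero_filter(self):
        from flocknet.networks import SRIMatrix
        sri = SRIMatrix(sri={("A", "B"): 0.5, ("C", "D"): 0.0},
                        individuals=["A", "B", "C", "D"])
        ind = individuals_table({"A": 1, "B": 0, "C": 1, "D": 0})
        net = build_network(sri, ind)
        assert set(net.nodes) == {"A", "B"}


class TestCentralities:
    def test_strength_follows_scaled_sum(self):
        # neighbour SRIs {0.4, 0.2} in a 5-vertex network:
        # S = 2 * 0.6 / 5 = 0.24
        g = nx.Graph()
        g.add_edge("X", "A", weight=0.4)
        g.add_edge("X", "B", weight=0.2)
        g.add_edge("C", "D", weight=0.1)
        cent = compute_centralities(g)
        s = cent.set_index("individual_id").loc["X", "strength"]
        assert s == pytest.approx(0.24, abs=1e-9)

    def test_plain_sum_strength_option(self):
        g = nx.Graph()
        g.add_edge("X", "A", weight=0.4)
        g.add_edge("X", "B", weight=0.2)
        cent = compute_centralities(g, strength_definition="sum")
        s = cent.set_index("individual_id").loc["X", "strength"]
        assert s == pytest.approx(0.6, abs=1e-12)

    def test_two_node_network_eigenvector_both_one(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=0.7)
        cent = compute_centralities(g)
        assert np.allclose(cent["eigenvector"], 1.0)

    def test_star_graph_hub_one_leaves_half(self):
        g = nx.star_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        cent = compute_centralities(g).set_index("individual_id")
        assert cent.loc[0, "eigenvector"] == pytest.approx(1.0, abs=1e-9)
        for leaf in range(1, 5):
            assert cent.loc[leaf, "eigenvector"] == \
                pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("seed", range(30))
    def test_eigenvector_matches_power_iteration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        g = nx.gnp_random_graph(n, 0.3, seed=seed)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.05, 1.0))
        if g.number_of_edges() == 0:
            return
        # power iteration from a flat start is only well-defined on a
        # connected graph (unique dominant eigenvector)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        cent = compute_centralities(g)
        nodes = sorted(g.nodes)
        a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        expected = power_iteration(a)
        got = cent.set_index("individual_id").loc[nodes, "eigenvector"]
        assert np.allclose(got.to_numpy(), expected, atol=1e-8)

    def test_opposite_sex_degree_bounded_by_degree(self, small_sim, params):
        from flocknet.arrivals import associate_arrivals, detect_arrivals
        arr = detect_arrivals(small_sim["visits"], params)
        sri = compute_sri(associate_arrivals(arr, params))
        net = build_network(sri, small_sim["individuals"])
        bip = build_network(sri, small_sim["individuals"], bipartite=True)
        cent = compute_centralities(net, bip)
        assert (cent["opposite_sex_degree"] <= cent["degree"]).all()
        assert (cent["degree"] >= 1).all()

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            compute_centralities(nx.Graph())


class TestSummarizeEvent:
    def test_hand_arithmetic(self):
        cent = pd.DataFrame({
            "individual_id": list("abc"), "degree": [1, 2, 3],
            "strength": [0.1, 0.2, 0.3], "eigenvector": [1.0, 0.5, 0.25],
            "opposite_sex_degree": [0, 1, 2]})
        out = summarize_event(cent).set_index("measure")
        assert out.loc["degree", "mean"] == pytest.approx(2.0)
        assert out.loc["degree", "sd"] == pytest.approx(1.0)
        assert out.loc["degree", "n"] == 3

    def test_single_individual_sd_absent(self):
        cent = pd.DataFrame({
            "individual_id": ["a"], "degree": [4], "strength": [0.2],
            "eigenvector": [1.0], "opposite_sex_degree": [2]})
        out = summarize_event(cent).set_index("measure")
        assert np.isnan(out.loc["degree", "sd"])
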