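import numpy as np
import pandas as pd
import pytest
from scipy import stats

import teconet as tc
from oracles import exhaustive_barber_best, random_bipartite_network
from teconet.network import BipartiteNetwork, _fisher_mc_p


def _records(rows):
    return pd.DataFrame(rows, columns=["gene_id", "te_id", "r", "padj"])


def _net(edges, genes=None, tes=None):
    genes = genes or {g for g, _, _ in edges}
    tes = tes or {t for _, t, _ in edges}
    return BipartiteNetwork(
        set(genes), set(tes), [(g, t, {"r": w}) for g, t, w in edges]
    )


class TestBuildNetwork:
    def test_nodes_and_edges_counted(self):
        recs = _records(
            [("g1", "t1", 0.5, 0.001), ("g1", "t2", -0.5, 0.001),
             ("g2", "t1", 0.6, 0.001)]
        )
        net = tc.build_network(recs)
        assert net.n_nodes == 4 and net.n_edges == 3

    def test_empty_records_give_empty_network(self):
        net = tc.build_network(_records([]))
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_id_in_both_classes_rejected(self):
        recs = _records(
            [("g1", "t1", 0.5, 0.01), ("t1", "t2", 0.5, 0.01)]
        )
        with pytest.raises(ValueError, match="biparticity"):
            tc.build_network(recs)

    def test_duplicate_pair_rejected(self):
        recs = _records(
            [("g1", "t1", 0.5, 0.01), ("g1", "t1", 0.6, 0.01)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            tc.build_network(recs)


class TestNormalizedDegree:
    def test_full_and_partial_connectivity(self):
        edges = [("g1", f"t{i}", 0.5) for i in range(4)]
        edges += [("g2", "t0", 0.5), ("g2", "t1", 0.5)]
        net = _net(edges)
        nd = tc.normalized_degree(net)
        assert nd["g1"] == 1.0  # connected to all 4 TEs
        assert nd["g2"] == 0.5
        assert nd["t0"] == 1.0  # both genes

    def test_isolated_node_zero(self):
        net = _net([("g1", "t1", 0.5)], genes={"g1", "g2"}, tes={"t1"})
        assert tc.normalized_degree(net)["g2"] == 0.0


class TestHubs:
    def test_star_center_is_sole_hub(self):
        net = _net([("g1", f"t{i}", 0.5) for i in range(20)])
        assert tc.hubs(net) == {"g1"}

    def test_regular_network_ties_include_everyone(self):
        edges = [("g1", "t1", 0.5), ("g2", "t2", 0.5)]
        net = _net(edges)
        assert tc.hubs(net) == {"g1", "g2", "t1", "t2"}

    def test_planted_top_node_at_one_percent(self):
        rng = np.random.default_rng(0)
        edges = [("hub", f"t{i}", 0.9) for i in range(30)]
        for i in range(49):
            edges.append((f"g{i}", f"t{i % 30}", float(rng.uniform(0.4, 0.6))))
        net = _net(edges)
        assert tc.hubs(net, top_fraction=0.01) == {"hub"}


class TestBarberModularity:
    def test_single_edge_same_module_is_zero(self):
        net = _net([("g1", "t1", 1.0)])
        assert tc.barber_modularity(net, {"g1": 0, "t1": 0}) == pytest.approx(0.0)

    def test_two_disjoint_edges_split_is_half(self):
        net = _net([("g1", "t1", 1.0), ("g2", "t2", 1.0)])
        q = tc.barber_modularity(net, {"g1": 0, "t1": 0, "g2": 1, "t2": 1})
        assert q == pytest.approx(0.5)

    def test_two_disjoint_edges_merged_is_zero(self):
        net = _net([("g1", "t1", 1.0), ("g2", "t2", 1.0)])
        q = tc.barber_modularity(net, {"g1": 0, "t1": 0, "g2": 0, "t2": 0})
        assert q == pytest.approx(0.0)

    def test_invariance_under_relabeling_and_weight_scaling(self):
        rng = np.random.default_rng(1)
        net = random_bipartite_network(rng)
        nodes = sorted(net.gene_nodes | net.te_nodes)
        part = {v: i % 3 for i, v in enumerate(nodes)}
        q1 = tc.barber_modularity(net, part)
        relabeled = {v: (c + 7) * 13 for v, c in part.items()}
        assert tc.barber_modularity(net, relabeled) == pytest.approx(q1)
        scaled = BipartiteNetwork(
            net.gene_nodes, net.te_nodes,
            [(g, t, {"r": a["r"] * 0.25}) for g, t, a in net.edges()],
        )
        assert tc.barber_modularity(scaled, part) == pytest.approx(q1)

    def test_weightless_network_rejected(self):
        net = BipartiteNetwork({"g1"}, {"t1"}, [])
        with pytest.raises(ValueError):
            tc.barber_modularity(net, {"g1": 0, "t1": 0})


class TestDetectModules:
    def test_disconnected_bicliques_recovered(self):
        edges = [(f"ga{i}", f"ta{j}", 0.8) for i in range(2) for j in range(3)]
        edges += [(f"gb{i}", f"tb{j}", 0.8) for i in range(3) for j in range(2)]
        net = _net(edges)
        part, q = tc.detect_modules(net, seed=0)
        modules = {
            frozenset(v for v, c in part.items() if c == m)
            for m in set(part.values())
        }
        expected = {
            frozenset({"ga0", "ga1", "ta0", "ta1", "ta2"}),
            frozenset({"gb0", "gb1", "gb2", "tb0", "tb1"}),
        }
        assert modules == expected
        assert q == pytest.approx(0.5)

    def test_single_biclique_one_module_matches_closed_form(self):
        edges = [(f"g{i}", f"t{j}", 1.0) for i in range(3) for j in range(3)]
        net = _net(edges)
        part, q = tc.detect_modules(net, seed=0)
        assert len({c for c in part.values() if c != -1}) == 1
        assert q == pytest.approx(
            tc.barber_modularity(net, {v: 0 for v in part})
        )
        assert q == pytest.approx(0.0)

    def test_matches_exhaustive_search_on_small_graphs(self):
        rng = np.random.default_rng(6)
        for _ in range(6):
            net = random_bipartite_network(rng)
            part, q = tc.detect_modules(net, seed=2)
            assert q == pytest.approx(exhaustive_barber_best(net), abs=1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        net = random_bipartite_network(rng)
        p1, q1 = tc.detect_modules(net, seed=5)
        p2, q2 = tc.detect_modules(net, seed=5)
        assert p1 == p2 and q1 == q2

    def test_within_module_edges_partition_edge_set(self):
        edges = [(f"ga{i}", f"ta{j}", 0.8) for i in range(2) for j in range(3)]
        edges += [(f"gb{i}", f"tb{j}", 0.8) for i in range(3) for j in range(2)]
        net = _net(edges)
        part, _ = tc.detect_modules(net, seed=0)
        per_module = sum(
            1
            for g, t, _ in net.edges()
            if part[g] == part[t] and part[g] != -1
        )
        assert per_module == net.n_edges


class TestModuleEnrichment:
    def test_concentrated_category_flagged(self):
        partition = {f"t{i}": (0 if i < 10 else 1) for i in range(40)}
        labels = {f"t{i}": ("Alu" if i < 10 else "L1") for i in range(40)}
        out = tc.module_enrichment(partition, labels, n_sim=50_000, seed=0)
        row = out[(out["module"] == 0) & (out["category"] == "Alu")].iloc[0]
        assert row["flagged"] and row["p"] < 1e-3

    def test_uniform_category_not_flagged(self):
        partition = {f"t{i}": i % 2 for i in range(40)}
        labels = {f"t{i}": ("Alu" if i % 4 < 2 else "L1") for i in range(40)}
        out = tc.module_enrichment(partition, labels, n_sim=20_000, seed=0)
        assert (~out["flagged"]).all()

    def test_monte_carlo_matches_exact_fisher(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n_tot = int(rng.integers(12, 30))
            k_cat = int(rng.integers(3, n_tot - 3))
            n_mod = int(rng.integers(3, n_tot - 3))
            a = int(
                rng.integers(max(0, n_mod - (n_tot - k_cat)), min(n_mod, k_cat) + 1)
            )
            table = [
                [a, n_mod - a],
                [k_cat - a, n_tot - n_mod - k_cat + a],
            ]
            exact = stats.fisher_exact(table).pvalue
            mc = _fisher_mc_p(
                a, n_mod, k_cat, n_tot, 100_000, np.random.default_rng(3)
            )
            assert mc == pytest.approx(exact, abs=0.005)

    def test_diagonal_table_extreme(self):
        p = _fisher_mc_p(10, 10, 10, 20, 100_000, np.random.default_rng(0))
        assert p < 1e-4

    def test_requires_two_categories(self):
        partition = {"t1": 0, "t2": 0}
        labels = {"t1": "Alu", "t2": "Alu"}
        with pytest.raises(ValueError, match="2 categories"):
            tc.module_enrichment(partition, labels, n_sim=100)
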