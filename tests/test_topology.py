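"""Topology metrics, centrality, keystoneness and attack tolerance."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ticknet.containers import CountTable, ValidationError
from ticknet.topology import (
    attack,
    connectivity_loss,
    eigenvector_centrality,
    hub_scores,
    keystoneness,
    removal_fraction_at_loss,
    summarize_topology,
    ubiquity,
)


def signed(graph: nx.Graph, weight: float = 1.0) -> nx.Graph:
    for u, v, d in graph.edges(data=True):
        d.setdefault("weight", weight)
        d["absweight"] = abs(d["weight"])
        d["sign"] = "positive" if d["weight"] > 0 else "negative"
    return graph


def exhaustive_cl(graph: nx.Graph, removed: set) -> float:
    """Pair-reachability by BFS from every surviving node (independent oracle)."""
    keep = [n for n in graph.nodes if n not in removed]
    sub = graph.subgraph(keep)
    reachable = 0
    for a, b in itertools.combinations(keep, 2):
        if nx.has_path(sub, a, b):
            reachable += 1
    n = graph.number_of_nodes()
    total = n * (n - 1) // 2
    return 1.0 - reachable / total if total else 0.0


class TestSummarize:
    def test_triangle_closed_forms(self):
        report = summarize_topology(signed(nx.complete_graph(3)))
        assert report.average_degree == pytest.approx(2.0)
        assert report.diameter == 1
        assert report.average_clustering == pytest.approx(1.0)
        assert report.pct_positive == 100.0
        assert report.n_positive + report.n_negative == report.n_edges

    def test_sign_counts_and_percentages(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_edge("b", "c", weight=-0.4)
        g.add_edge("c", "d", weight=0.7)
        report = summarize_topology(signed(g))
        assert (report.n_positive, report.n_negative) == (2, 1)
        assert report.pct_positive == pytest.approx(66.7)
        assert report.pct_negative == pytest.approx(33.3)

    def test_empty_graph_flagged(self):
        report = summarize_topology(nx.Graph())
        assert report.n_nodes == 0 and report.undefined

    def test_disjoint_cliques_modularity_closed_form(self):
        """Union of k equal cliques: Q = 1 - 1/k under the clique partition."""
        k, m = 4, 5
        g = nx.disjoint_union_all([nx.complete_graph(m) for _ in range(k)])
        report = summarize_topology(signed(g))
        assert report.n_modules == k
        assert report.modularity == pytest.approx(1 - 1 / k, abs=1e-10)


class TestCentrality:
    def test_star_analytic_values(self):
        cent = eigenvector_centrality(signed(nx.star_graph(8)))
        assert cent[0] == pytest.approx(1.0)
        for leaf in range(1, 9):
            assert cent[leaf] == pytest.approx(1 / np.sqrt(8), abs=1e-8)

    def test_complete_graph_uniform(self):
        cent = eigenvector_centrality(signed(nx.complete_graph(5)))
        assert cent.to_numpy() == pytest.approx(np.ones(5))

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            g = nx.gnp_random_graph(30, 0.15, seed=seed)
            if g.number_of_edges() == 0:
                continue
            for _, _, d in g.edges(data=True):
                d["weight"] = rng.uniform(0.2, 1.0) * rng.choice([-1, 1])
            cent = eigenvector_centrality(signed(g))
            a = np.abs(nx.to_numpy_array(g, weight="weight"))
            vals, vecs = np.linalg.eigh(a)
            lead = np.abs(vecs[:, np.argmax(vals)])
            lead /= lead.max()
            np.testing.assert_allclose(cent.to_numpy(), lead, atol=1e-8)

    def test_hub_scores_equal_eigenvector_on_undirected(self):
        g = signed(nx.gnp_random_graph(20, 0.2, seed=3))
        np.testing.assert_allclose(
            hub_scores(g).to_numpy(), eigenvector_centrality(g).to_numpy(), atol=1e-8
        )

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValidationError):
            eigenvector_centrality(nx.empty_graph(4))

    def test_relabeling_invariance(self):
        g = signed(nx.gnp_random_graph(12, 0.3, seed=4))
        cent = eigenvector_centrality(g)
        mapping = {n: f"x{n}" for n in g.nodes}
        cent_r = eigenvector_centrality(nx.relabel_nodes(g, mapping))
        for n in g.nodes:
            assert cent_r[f"x{n}"] == pytest.approx(cent[n], abs=1e-10)


class TestUbiquityKeystones:
    def test_ubiquity_fractions(self):
        df = pd.DataFrame(
            {f"s{j}": [1 if j < 3 else 0, 5, 0] for j in range(12)},
            index=["partial", "everywhere", "absent"],
        )
        ub = ubiquity(CountTable(df))
        assert ub["everywhere"] == 1.0
        assert ub["absent"] == 0.0
        assert ub["partial"] == pytest.approx(0.25)

    def test_rare_isolated_taxon_not_keystone(self):
        g = signed(nx.star_graph(4))
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in range(5)})
        g.add_node("t5")  # isolated, rare
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.integers(50, 100, size=(6, 10)),
            index=[f"t{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(10)],
        )
        df.loc["t5"] = 0
        df.loc["t5", "s0"] = 1
        report = keystoneness(g, CountTable(df))
        assert not report.loc["t5", "keystone"]
        assert not report.loc["t5", "criterion_i"]

    def test_mismatched_taxa_rejected(self, small_counts):
        g = signed(nx.complete_graph(3))
        with pytest.raises(ValidationError):
            keystoneness(g, small_counts)


class TestConnectivityLoss:
    def test_path_graph_worked_example(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        assert connectivity_loss(g, ["b"]) == pytest.approx(5 / 6)

    def test_remove_nothing_zero_loss(self):
        assert connectivity_loss(nx.complete_graph(6), []) == 0.0

    def test_star_center_removal_total_loss(self):
        g = nx.star_graph(7)
        assert connectivity_loss(g, [0]) == pytest.approx(1.0)

    def test_matches_exhaustive_bfs_on_small_graphs(self):
        rng = np.random.default_rng(2)
        for seed in range(20):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, rng.uniform(0.15, 0.6), seed=seed)
            removed = set(
                rng.choice(n, size=int(rng.integers(0, n)), replace=False).tolist()
            )
            assert connectivity_loss(g, removed) == pytest.approx(
                exhaustive_cl(g, removed), abs=1e-12
            )

    def test_unknown_node_rejected(self):
        with pytest.raises(ValidationError):
            connectivity_loss(nx.path_graph(3), ["zz"])


class TestAttack:
    def test_directed_star_breaks_after_hub(self):
        curve = attack(signed(nx.star_graph(10)), "directed")
        assert curve.cl[0] == 0.0
        assert curve.cl[1] == pytest.approx(1.0)
        assert removal_fraction_at_loss(curve, 0.90) == pytest.approx(1 / 11)
        assert np.all(np.diff(curve.cl) >= -1e-12)  # non-decreasing

    def test_random_attack_k5_first_step_lossless(self):
        curve = attack(signed(nx.complete_graph(5)), "random", n_iterations=40, seed=0)
        # K4 remains connected: only the pair count shrinks
        assert curve.cl[1] == pytest.approx(1 - 6 / 10)
        assert curve.cl[-1] == pytest.approx(1.0)

    def test_random_attack_seed_determinism(self):
        g = signed(nx.gnp_random_graph(15, 0.3, seed=1))
        a = attack(g, "random", n_iterations=10, seed=7)
        b = attack(g, "random", n_iterations=10, seed=7)
        np.testing.assert_array_equal(a.cl, b.cl)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValidationError):
            attack(signed(nx.path_graph(4)), "clever")

    def test_curve_matches_stepwise_connectivity_loss(self):
        g = signed(nx.gnp_random_graph(12, 0.3, seed=5))
        curve = attack(g, "directed")
        order = curve.removal_order
        for k in range(len(order) + 1):
            assert curve.cl[k] == pytest.approx(
                connectivity_loss(g, order[:k]), abs=1e-12
            )

    def test_loss_target_zero_reached_immediately(self):
        curve = attack(signed(nx.path_graph(5)), "directed")
        assert removal_fraction_at_loss(curve, 0.0) == 0.0

    def test_directed_dominates_random_on_hub_graphs(self):
        wins = 0
        trials = 20
        for seed in range(trials):
            g = signed(nx.barabasi_albert_graph(40, 2, seed=seed))
            directed = removal_fraction_at_loss(attack(g, "directed"), 0.90)
            random = removal_fraction_at_loss(
                attack(g, "random", n_iterations=20, seed=seed), 0.90
            )
            wins += directed <= random
        assert wins >= 0.95 * trials
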