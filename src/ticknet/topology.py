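"""Network topology summaries, keystoneness scoring and attack tolerance.

Keystone taxa are flagged by three criteria on the co-occurrence network:
(i) high eigenvector centrality, (ii) ubiquity (presence across samples), and
(iii) the combination of high relative abundance with criterion (i).

Attack tolerance measures how fast the network loses connectivity as nodes
are removed, either uniformly at random (averaged over iterations) or in
decreasing order of betweenness centrality. Connectivity loss after removing
a node set is

    CL = 1 - (reachable unordered pairs remaining) / (N (N-1) / 2),

with N the intact node count, so CL = 0 for the intact network and 1 once no
two surviving nodes can reach each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .compnet import SignedNetwork
from .containers import CountTable, ValidationError

__all__ = [
    "TopologyReport",
    "AttackCurve",
    "summarize_topology",
    "eigenvector_centrality",
    "hub_scores",
    "ubiquity",
    "keystoneness",
    "connectivity_loss",
    "attack",
    "removal_fraction_at_loss",
]


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    pct_positive: float
    pct_negative: float
    diameter: int | None
    average_degree: float
    weighted_degree: float
    average_path_length: float | None
    modularity: float | None
    n_modules: int
    average_clustering: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class AttackCurve:
    strategy: str
    fractions: np.ndarray  # k/N for k = 0..N
    cl: np.ndarray  # mean connectivity loss after k removals
    n_iterations: int
    removal_order: list | None = None  # directed strategy only


def _graph(net: SignedNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, SignedNetwork) else net


def summarize_topology(net: SignedNetwork | nx.Graph) -> TopologyReport:
    """Table-style topology metrics on the undirected simple graph.

    Percentages are 100*count/edges rounded to one decimal; diameter and
    average path length refer to the largest connected component; modularity
    comes from greedy modularity communities on absolute edge weights.
    """
    g = _graph(net)
    n, e = g.number_of_nodes(), g.number_of_edges()
    undefined: list[str] = []
    signs = [d.get("sign", "positive" if d.get("weight", 1) > 0 else "negative")
             for _, _, d in g.edges(data=True)]
    n_pos = sum(s == "positive" for s in signs)
    n_neg = e - n_pos
    if e:
        pct_pos = round(100.0 * n_pos / e, 1)
        pct_neg = round(100.0 * n_neg / e, 1)
    else:
        pct_pos = pct_neg = 0.0
        undefined.append("pct_positive")

    if n == 0:
        return TopologyReport(0, 0, 0, 0, 0.0, 0.0, None, 0.0, 0.0, None, None, 0, 0.0,
                              undefined=("all",))

    avg_degree = 2.0 * e / n
    wdeg = [sum(abs(d.get("weight", 1.0)) for _, _, d in g.edges(u, data=True))
            for u in g.nodes]
    weighted_degree = float(np.mean(wdeg))

    diameter: int | None = None
    apl: float | None = None
    if e:
        largest = g.subgraph(max(nx.connected_components(g), key=len))
        diameter = nx.diameter(largest)
        apl = nx.average_shortest_path_length(largest)
    else:
        undefined += ["diameter", "average_path_length"]

    modularity: float | None = None
    n_modules = 0
    if e:
        comms = list(nx.community.greedy_modularity_communities(g, weight="absweight"))
        modularity = nx.community.modularity(g, comms, weight="absweight")
        n_modules = len(comms)
    else:
        undefined.append("modularity")

    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        n_positive=n_pos,
        n_negative=n_neg,
        pct_positive=pct_pos,
        pct_negative=pct_neg,
        diameter=diameter,
        average_degree=avg_degree,
        weighted_degree=weighted_degree,
        average_path_length=apl,
        modularity=modularity,
        n_modules=n_modules,
        average_clustering=float(nx.average_clustering(g)) if n else 0.0,
        undefined=tuple(undefined),
    )


def _power_iteration(a: np.ndarray, tol: float = 1e-10, max_iter: int = 100_000) -> np.ndarray:
    # shift by the spectral-radius bound so iteration converges on bipartite
    # graphs too; A + cI has the same Perron vector as A
    shift = max(a.sum(axis=1).max(), 1.0)
    a = a + shift * np.eye(a.shape[0])
    v = np.ones(a.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        w = a @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValidationError("centrality undefined: zero adjacency")
        w /= norm
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    return v


def eigenvector_centrality(net: SignedNetwork | nx.Graph) -> pd.Series:
    """Eigenvector centrality on |weight| adjacency, max-normalized to 1.

    Power iteration from the all-ones vector to tolerance 1e-10; on
    disconnected graphs the component with the largest spectral radius
    dominates, deterministically.
    """
    g = _graph(net)
    if g.number_of_edges() == 0:
        raise ValidationError("eigenvector centrality undefined on an edgeless graph")
    nodes = list(g.nodes)
    a = np.abs(nx.to_numpy_array(g, nodelist=nodes, weight="weight"))
    v = np.abs(_power_iteration(a))
    v /= v.max()
    return pd.Series(v, index=nodes, name="eigenvector_centrality")


def hub_scores(net: SignedNetwork | nx.Graph) -> pd.Series:
    """Kleinberg hub scores, max-normalized.

    For an undirected graph the HITS hub and authority vectors coincide with
    the dominant eigenvector of the (absolute-weight) adjacency, so this
    equals :func:`eigenvector_centrality`; kept as its own entry point for
    report parity.
    """
    s = eigenvector_centrality(net)
    s.name = "hub_score"
    return s


def ubiquity(counts: CountTable) -> pd.Series:
    """Fraction of samples in which each taxon is detected (count > 0)."""
    return (counts.counts > 0).mean(axis=1).rename("ubiquity")


def keystoneness(
    net: SignedNetwork | nx.Graph,
    counts: CountTable,
    centrality_quantile: float = 0.9,
    ubiquity_min: float = 0.8,
    abundance_quantile: float = 0.75,
) -> pd.DataFrame:
    """Per-taxon keystoneness report with the three criteria and a composite.

    criterion_i: centrality >= the given quantile of centralities;
    criterion_ii: ubiquity >= ubiquity_min;
    criterion_iii: abundance >= its quantile AND criterion_i;
    keystone: all three. Sorted by centrality, descending.
    """
    g = _graph(net)
    if set(g.nodes) != set(counts.taxa):
        raise ValidationError("network nodes and count-table taxa differ")
    if g.number_of_edges() == 0:
        warnings.warn("edgeless network: all centralities set to 0", stacklevel=2)
        cent = pd.Series(0.0, index=counts.taxa, name="eigenvector_centrality")
    else:
        cent = eigenvector_centrality(g).reindex(counts.taxa)
    ubiq = ubiquity(counts)
    abund = counts.mean_relative_abundance()
    c_thr = cent.quantile(centrality_quantile)
    a_thr = abund.quantile(abundance_quantile)
    crit_i = cent >= c_thr
    crit_ii = ubiq >= ubiquity_min
    crit_iii = (abund >= a_thr) & crit_i
    report = pd.DataFrame(
        {
            "eigenvector_centrality": cent,
            "ubiquity": ubiq,
            "mean_relative_abundance": abund,
            "criterion_i": crit_i,
            "criterion_ii": crit_ii,
            "criterion_iii": crit_iii,
            "keystone": crit_i & crit_ii & crit_iii,
        }
    )
    return report.sort_values("eigenvector_centrality", ascending=False)


def connectivity_loss(graph: nx.Graph, removed_nodes: Iterable) -> float:
    """CL = 1 - (surviving reachable pairs) / (pairs of the intact graph)."""
    removed = set(removed_nodes)
    unknown = removed - set(graph.nodes)
    if unknown:
        raise ValidationError(f"removed nodes not in graph: {sorted(unknown)[:5]}")
    n = graph.number_of_nodes()
    total = n * (n - 1) // 2
    if total == 0:
        return 0.0
    sub = graph.subgraph(set(graph.nodes) - removed)
    remaining = sum(s * (s - 1) // 2 for s in (len(c) for c in nx.connected_components(sub)))
    return 1.0 - remaining / total


def _cl_curve_for_order(graph: nx.Graph, order: Sequence) -> np.ndarray:
    """CL after each prefix of a removal order, via reverse union-find.

    Nodes are *added* in reverse order with union-find bookkeeping of
    component sizes, giving the whole curve in near-linear time.
    """
    n = graph.number_of_nodes()
    total = n * (n - 1) // 2
    index = {u: i for i, u in enumerate(order)}
    parent = list(range(n))
    size = [1] * n
    present = [False] * n

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = 0
    pairs_after_k = np.zeros(n + 1)
    # k = n: everything removed -> 0 pairs
    for k in range(n - 1, -1, -1):
        u = order[k]
        iu = index[u]
        present[iu] = True
        for v in graph.neighbors(u):
            iv = index[v]
            if not present[iv]:
                continue
            ru, rv = find(iu), find(iv)
            if ru != rv:
                pairs += size[ru] * size[rv]
                if size[ru] < size[rv]:
                    ru, rv = rv, ru
                parent[rv] = ru
                size[ru] += size[rv]
        pairs_after_k[k] = pairs
    if total == 0:
        return np.zeros(n + 1)
    return 1.0 - pairs_after_k / total


def attack(
    net: SignedNetwork | nx.Graph,
    strategy: str = "random",
    n_iterations: int = 100,
    seed: int | np.random.Generator | None = None,
    recompute: bool = False,
) -> AttackCurve:
    """Attack-tolerance curve under random or betweenness-directed removal.

    random: ``n_iterations`` independent uniform removal orders, CL averaged
    at each step. directed: one order by betweenness centrality on the intact
    graph, highest first, ties broken by node ID; with ``recompute=True`` the
    ranking is refreshed after every removal.
    """
    g = _graph(net)
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValidationError("cannot attack an empty graph")
    if strategy == "random":
        if n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        acc = np.zeros(n + 1)
        for _ in range(n_iterations):
            order = [nodes[i] for i in rng.permutation(n)]
            acc += _cl_curve_for_order(g, order)
        return AttackCurve("random", np.arange(n + 1) / n, acc / n_iterations, n_iterations)
    if strategy == "directed":
        if recompute:
            order = []
            h = g.copy()
            while h.number_of_nodes():
                bc = nx.betweenness_centrality(h)
                nxt = min(h.nodes, key=lambda u: (-bc[u], str(u)))
                order.append(nxt)
                h.remove_node(nxt)
        else:
            bc = nx.betweenness_centrality(g)
            order = sorted(nodes, key=lambda u: (-bc[u], str(u)))
        cl = _cl_curve_for_order(g, order)
        return AttackCurve("directed", np.arange(n + 1) / n, cl, 1, removal_order=order)
    raise ValidationError(f"unknown attack strategy {strategy!r}")


def removal_fraction_at_loss(curve: AttackCurve, loss_target: float = 0.90) -> float:
    """Smallest removal fraction whose CL reaches the target (step semantics)."""
    reached = np.flatnonzero(curve.cl >= loss_target)
    if reached.size == 0:
        raise ValidationError(f"connectivity loss never reaches {loss_target}")
    return float(curve.fractions[reached[0]])
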