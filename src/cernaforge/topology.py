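"""Network topology diagnostics: degree/power-law fit, average path length
with a degree-preserving rewiring null, centralities and hub extraction.

The power-law diagnostic is the log-log least-squares fit on raw degree
frequencies (the NetworkAnalyzer convention that yields an R^2), not a
maximum-likelihood tail fit.  The average-path-length (APL) null rewires each
edge-type class separately so ceRNA edges stay lncRNA-TF bipartite and PPI
edges stay TF-TF, and reports the empirical p as (number of random networks
with APL strictly shorter than the real one) / n_random, with no continuity
correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path


@dataclass
class PowerLawFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class NullTestResult:
    real_apl: float
    n_random: int
    count_shorter: int
    random_apls: list[float] = field(repr=False, default_factory=list)

    @property
    def empirical_p(self) -> float:
        return self.count_shorter / self.n_random


@dataclass
class HubSet:
    nodes: list[str]
    fraction: float
    kinds: dict[str, str]

    @property
    def n_lncrna(self) -> int:
        return sum(1 for n in self.nodes if self.kinds.get(n) == "lncRNA")

    @property
    def n_tf(self) -> int:
        return sum(1 for n in self.nodes if self.kinds.get(n) == "TF")

    def __len__(self) -> int:
        return len(self.nodes)


def degree_distribution_fit(net: nx.Graph) -> PowerLawFit:
    """Least-squares line on (log10 k, log10 f(k)) over degrees k >= 1.

    Requires at least 3 distinct degree values with nonzero frequency.
    """
    degrees = [d for _, d in net.degree if d >= 1]
    if not degrees:
        raise ValueError("network has no nodes of degree >= 1")
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise ValueError(f"power-law fit needs >=3 distinct degrees, got {len(ks)}")
    fit = stats.linregress(np.log10(ks), np.log10(counts))
    return PowerLawFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(ks),
    )


def _pairwise_distances(net: nx.Graph) -> np.ndarray:
    adj = nx.to_scipy_sparse_array(net, nodelist=sorted(net.nodes), format="csr")
    return shortest_path(adj, method="auto", directed=False, unweighted=True)


def average_path_length(net: nx.Graph) -> float:
    """Mean BFS distance over unordered pairs in the same component."""
    if net.number_of_edges() == 0:
        raise ValueError("average path length undefined on an edgeless graph")
    dist = _pairwise_distances(net)
    iu = np.triu_indices(dist.shape[0], k=1)
    vals = dist[iu]
    finite = vals[np.isfinite(vals)]
    return float(finite.mean())


def node_metrics(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness and mean shortest-path length."""
    nodes = sorted(net.nodes)
    dist = _pairwise_distances(net)
    mean_spl = []
    for i in range(len(nodes)):
        row = np.delete(dist[i], i)
        finite = row[np.isfinite(row)]
        mean_spl.append(float(finite.mean()) if finite.size else math.nan)
    btw = nx.betweenness_centrality(net, normalized=True)
    clo = nx.closeness_centrality(net)
    return pd.DataFrame(
        {
            "degree": [net.degree[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
            "mean_shortest_path": mean_spl,
        },
        index=nodes,
    )


def rewire_degree_preserving(
    net: nx.Graph, n_swaps_factor: float = 10.0, seed: int | None = None
) -> nx.Graph:
    """Double-edge-swap randomisation within each edge-type class.

    ceRNA swaps exchange TF partners between two lncRNA-TF edges, keeping
    bipartiteness; PPI swaps are ordinary double swaps within TF-TF edges.
    The degree sequence and per-type edge counts are preserved exactly; no
    self-loops or parallel edges are introduced.  ``n_swaps_factor * |E_type|``
    swaps are attempted per class.  If every attempt is rejected the input is
    returned as a copy with a warning.
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(net.nodes(data=True))
    for u, v, d in net.edges(data=True):
        g.add_edge(u, v, etype=d.get("etype", "ceRNA"))
    kinds = nx.get_node_attributes(net, "kind")
    n_success = 0
    n_attempts_total = 0
    for etype in sorted({d["etype"] for _, _, d in g.edges(data=True)}):
        if etype == "ceRNA":
            # orient (lncRNA, TF)
            edges = [
                (u, v) if kinds.get(u) == "lncRNA" else (v, u)
                for u, v, d in g.edges(data=True)
                if d["etype"] == etype
            ]
        else:
            edges = [(u, v) for u, v, d in g.edges(data=True) if d["etype"] == etype]
        m = len(edges)
        if m < 2:
            continue
        n_attempts = int(n_swaps_factor * m)
        n_attempts_total += n_attempts
        for _ in range(n_attempts):
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            if etype == "ceRNA":
                l1, t1 = edges[i]
                l2, t2 = edges[j]
                new1, new2 = (l1, t2), (l2, t1)
            else:
                a, b = edges[i]
                c, d_ = edges[j]
                if rng.integers(0, 2):
                    c, d_ = d_, c
                new1, new2 = (a, c), (b, d_)
            if new1[0] == new1[1] or new2[0] == new2[1]:
                continue
            if g.has_edge(*new1) or g.has_edge(*new2):
                continue
            g.remove_edge(*edges[i])
            g.remove_edge(*edges[j])
            g.add_edge(*new1, etype=etype)
            g.add_edge(*new2, etype=etype)
            edges[i], edges[j] = new1, new2
            n_success += 1
    if n_attempts_total and n_success == 0:
        warnings.warn("graph too constrained to swap; returning an unchanged copy", stacklevel=2)
    return g


def apl_null_test(
    net: nx.Graph, n_random: int = 1000, seed: int | None = None, n_swaps_factor: float = 10.0
) -> NullTestResult:
    """Empirical APL test against degree-preserving random networks.

    p = (#random networks with APL < real APL) / n_random, exactly.
    Per-replicate seeds are spawned from the master seed.
    """
    real = average_path_length(net)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_random)
    randoms: list[float] = []
    count_shorter = 0
    for s in child_seeds:
        g = rewire_degree_preserving(net, n_swaps_factor=n_swaps_factor, seed=int(s) % (2**31))
        apl = average_path_length(g)
        randoms.append(apl)
        if apl < real:
            count_shorter += 1
    return NullTestResult(
        real_apl=real, n_random=n_random, count_shorter=count_shorter, random_apls=randoms
    )


def select_hubs(net: nx.Graph, fraction: float = 0.10) -> HubSet:
    """Top floor(fraction * |V|) nodes by degree.

    Ties at the cutoff are broken by higher betweenness, then lexicographic
    node id, so the selection is permutation-invariant.
    """
    if net.number_of_nodes() < 10:
        raise ValueError("hub selection needs >=10 nodes")
    n_hubs = math.floor(fraction * net.number_of_nodes())
    btw = nx.betweenness_centrality(net, normalized=True)
    ranked = sorted(net.nodes, key=lambda v: (-net.degree[v], -btw[v], str(v)))
    kinds = nx.get_node_attributes(net, "kind")
    return HubSet(nodes=ranked[:n_hubs], fraction=fraction, kinds=kinds)


def hub_subnetwork(net: nx.Graph, hubs: HubSet | list[str]) -> nx.Graph:
    """Vertex-induced subgraph on the hub set, attributes preserved."""
    nodes = hubs.nodes if isinstance(hubs, HubSet) else list(hubs)
    missing = set(nodes) - set(net.nodes)
    if missing:
        raise ValueError(f"hub nodes not in network: {sorted(missing)[:5]}")
    return net.subgraph(nodes).copy()
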