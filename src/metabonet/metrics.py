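"""Node- and graph-level measures for the inferred networks.

Centralities: eigencentrality (undirected influence), HITS hub and
authority scores (directed influence through outgoing/incoming arcs),
and flow betweenness (total all-pairs max-flow lost when a node is
removed — a gatekeeping measure).  Community structure: largest-clique
enumeration, Louvain modularity optimisation and the Reichardt–
Bornholdt spinglass algorithm.  Topology: density, reciprocity,
characteristic path length, global transitivity, weighted clustering
(Barrat for undirected, Clemente–Grassi total for directed) and the
Humphries–Gurney small-world index.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "eigencentrality",
    "hub_authority",
    "flow_betweenness",
    "CliqueReport",
    "largest_cliques",
    "membership_frequency",
    "Partition",
    "modularity",
    "louvain",
    "spinglass",
    "TopologySummary",
    "topology_summary",
    "weighted_clustering",
    "small_world_index",
]


def _adjacency(g: nx.Graph, weight: str = "weight") -> tuple[list, np.ndarray]:
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=weight)
    return nodes, a


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------


def eigencentrality(g: nx.Graph, tol: float = 1e-10, max_iter: int = 100000) -> pd.Series:
    """Principal eigenvector of the weighted adjacency, rescaled to max 1.

    Power iteration from the uniform vector (deterministic); the
    Perron–Frobenius vector is nonnegative, so on a connected graph the
    most influential node scores exactly 1.  An empty graph scores all
    zero.
    """
    nodes, a = _adjacency(g)
    if a.sum() == 0:
        return pd.Series(0.0, index=nodes)
    # diagonal shift: keeps the eigenvectors, makes the dominant
    # eigenvalue unique in magnitude (bipartite graphs oscillate otherwise)
    shift = a.sum(axis=1).max()
    m = a + shift * np.eye(len(nodes))
    x = np.ones(len(nodes))
    for _ in range(max_iter):
        y = m @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return pd.Series(0.0, index=nodes)
        y /= norm
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    return pd.Series(x / x.max(), index=nodes)


def hub_authority(g: nx.DiGraph) -> tuple[pd.Series, pd.Series]:
    """HITS hub and authority scores, each rescaled to max 1.

    Hub scores are the principal eigenvector of ``A @ A.T`` and
    authority scores that of ``A.T @ A`` (weighted adjacency), i.e.
    the fixed point of the HITS iteration.  A node with no outgoing
    arcs has hub score 0.
    """
    nodes, a = _adjacency(g)
    if a.sum() == 0:
        zero = pd.Series(0.0, index=nodes)
        return zero, zero.copy()

    def principal(m: np.ndarray) -> np.ndarray:
        w, v = np.linalg.eigh(m)
        vec = np.abs(v[:, -1])
        return vec / vec.max() if vec.max() > 0 else vec

    return (
        pd.Series(principal(a @ a.T), index=nodes),
        pd.Series(principal(a.T @ a), index=nodes),
    )


def _maxflow_total(g: nx.DiGraph, directed: bool) -> float:
    """Sum of max-flow values over all (ordered or unordered) node pairs."""
    nodes = list(g.nodes)
    total = 0.0
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :] if not directed else nodes:
            if directed and s == t:
                continue
            total += nx.maximum_flow_value(g, s, t, capacity="capacity")
    return total


def flow_betweenness(g: nx.Graph) -> pd.Series:
    """Flow betweenness: all-pairs max-flow lost when a node is removed.

    Edge weights act as capacities.  For node v the score is the sum
    over pairs (i, j), i, j != v, of maxflow(i, j; G) minus
    maxflow(i, j; G - v); pairs are unordered for undirected networks
    and ordered for directed ones.  Isolated and pendant nodes score 0.
    """
    directed = g.is_directed()
    d = nx.DiGraph()
    d.add_nodes_from(g.nodes)
    for u, v, data in g.edges(data=True):
        cap = float(data.get("weight", 1.0))
        d.add_edge(u, v, capacity=cap)
        if not directed:
            d.add_edge(v, u, capacity=cap)

    # per-pair max-flow on the full graph, cached for reuse per node
    nodes = list(g.nodes)
    flow = {}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :] if not directed else nodes:
            if directed and s == t:
                continue
            flow[(s, t)] = nx.maximum_flow_value(d, s, t, capacity="capacity")

    scores = {}
    for v in nodes:
        h = d.copy()
        h.remove_node(v)
        lost = 0.0
        for (s, t), base in flow.items():
            if v in (s, t) or base == 0.0:
                continue
            lost += base - nx.maximum_flow_value(h, s, t, capacity="capacity")
        scores[v] = lost
    return pd.Series(scores)


# ---------------------------------------------------------------------------
# Cliques and communities
# ---------------------------------------------------------------------------


@dataclass
class CliqueReport:
    """All largest cliques of a network (ties included)."""

    largest_cliques: list[frozenset] = field(default_factory=list)

    @property
    def size(self) -> int:
        return max((len(c) for c in self.largest_cliques), default=0)

    @property
    def members(self) -> frozenset:
        out: frozenset = frozenset()
        for c in self.largest_cliques:
            out |= c
        return out


def largest_cliques(g: nx.Graph) -> CliqueReport:
    """Enumerate all maximum cliques (Bron–Kerbosch with pivoting).

    Directed networks are symmetrised first: cliques are defined on
    undirected connectivity.
    """
    und = g.to_undirected() if g.is_directed() else g
    cliques = [frozenset(c) for c in nx.find_cliques(und)]
    if not cliques:
        return CliqueReport([])
    top = max(len(c) for c in cliques)
    return CliqueReport([c for c in cliques if len(c) == top])


def membership_frequency(reports: list[CliqueReport]) -> dict:
    """Per node, in how many reports it belongs to >= 1 largest clique.

    With the study design of 7 networks (pooled + 6 age strata) the
    range is 0..7.
    """
    counts: dict = {}
    for rep in reports:
        for node in rep.members:
            counts[node] = counts.get(node, 0) + 1
    return counts


@dataclass
class Partition:
    """A community assignment and its (recomputed) modularity Q."""

    assignment: dict
    modularity: float
    method: str = ""

    @property
    def communities(self) -> list[set]:
        groups: dict = {}
        for node, cid in self.assignment.items():
            groups.setdefault(cid, set()).add(node)
        return list(groups.values())


def modularity(g: nx.Graph, assignment: dict, weight: str = "weight") -> float:
    """Weighted Newman modularity of a community assignment.

    Q = sum_c [ w_in(c)/m  -  (s(c)/(2m))^2 ]  on the undirected view,
    where m is the total edge weight, w_in(c) the intra-community edge
    weight and s(c) the summed node strength of community c.
    """
    und = g.to_undirected() if g.is_directed() else g
    m = sum(d.get(weight, 1.0) for _, _, d in und.edges(data=True))
    if m == 0:
        return 0.0
    intra: dict = {}
    strength: dict = {}
    for u, v, d in und.edges(data=True):
        w = d.get(weight, 1.0)
        strength[assignment[u]] = strength.get(assignment[u], 0.0) + w
        strength[assignment[v]] = strength.get(assignment[v], 0.0) + w
        if assignment[u] == assignment[v]:
            intra[assignment[u]] = intra.get(assignment[u], 0.0) + w
    return sum(
        intra.get(c, 0.0) / m - (strength.get(c, 0.0) / (2.0 * m)) ** 2
        for c in set(assignment.values())
    )


def louvain(g: nx.Graph, seed: int = 0) -> Partition:
    """Louvain weighted-modularity community detection.

    The reported Q is recomputed from scratch on the final assignment.
    """
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    assignment = {node: cid for cid, comm in enumerate(comms) for node in comm}
    return Partition(assignment, modularity(g, assignment), method="louvain")


def spinglass(
    g: nx.Graph, gamma: float = 1.0, steps: int = 10000, seed: int = 0
) -> Partition:
    """Reichardt–Bornholdt spinglass communities by simulated annealing.

    Runs on the symmetrised weighted graph (arc weights averaged),
    per connected component (singletons form their own community);
    seed-reproducible.  The reported Q is recomputed from scratch.
    """
    und = nx.Graph()
    und.add_nodes_from(g.nodes)
    if g.is_directed():
        for u, v, d in g.edges(data=True):
            w = d.get("weight", 1.0) / 2.0
            if und.has_edge(u, v):
                und[u][v]["weight"] += w
            else:
                und.add_edge(u, v, weight=w)
    else:
        und.add_edges_from(g.edges(data=True))

    ig.set_random_number_generator(_random.Random(seed))
    assignment: dict = {}
    next_id = 0
    components = list(nx.connected_components(und))
    if len(components) > 1:
        logger.info("spinglass: %d components, clustering each separately",
                    len(components))
    for comp in components:
        comp = sorted(comp)
        if len(comp) <= 2:
            # trivial components: a singleton, or a connected pair that
            # is necessarily one community (igraph's annealer does not
            # terminate on 2-node graphs)
            for node in comp:
                assignment[node] = next_id
            next_id += 1
            continue
        sub = und.subgraph(comp)
        h = ig.Graph()
        h.add_vertices(len(comp))
        index = {n: i for i, n in enumerate(comp)}
        edges = [(index[u], index[v]) for u, v in sub.edges]
        weights = [sub[u][v].get("weight", 1.0) for u, v in sub.edges]
        h.add_edges(edges)
        cl = h.community_spinglass(
            weights=weights, gamma=gamma, spins=min(25, len(comp))
        )
        for node, cid in zip(comp, cl.membership):
            assignment[node] = next_id + cid
        next_id += len(set(cl.membership))
    return Partition(assignment, modularity(und, assignment), method="spinglass")


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


@dataclass
class TopologySummary:
    """Graph-level descriptors of one network (one table row)."""

    n_nodes: int
    n_edges: int
    density: float
    reciprocity: float | None
    char_path_length: float
    global_transitivity: float
    clustering_binary: float
    clustering_weighted: float
    small_world_index: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "reciprocity": self.reciprocity if self.reciprocity is not None else np.nan,
            "char_path_length": self.char_path_length,
            "global_transitivity": self.global_transitivity,
            "clustering_binary": self.clustering_binary,
            "clustering_weighted": self.clustering_weighted,
            "small_world_index": self.small_world_index,
        }


def characteristic_path_length(g: nx.Graph) -> float:
    """Mean unweighted shortest-path length over connected ordered pairs.

    Disconnected pairs are excluded (and logged) rather than treated
    as infinite.
    """
    total, count, skipped = 0.0, 0, 0
    n = g.number_of_nodes()
    for source, lengths in nx.shortest_path_length(g):
        reached = len(lengths) - 1  # excludes the source itself
        total += sum(lengths.values())
        count += reached
        skipped += (n - 1) - reached
    if skipped:
        logger.info("char_path_length: %d disconnected ordered pairs excluded", skipped)
    return total / count if count else np.nan


def _binary_local_clustering(g: nx.Graph) -> pd.Series:
    """Unweighted local clustering on the undirected binarized view;
    NaN for nodes with degree < 2."""
    und = g.to_undirected() if g.is_directed() else g
    cc = nx.clustering(und)
    deg = dict(und.degree)
    return pd.Series(
        {n: (cc[n] if deg[n] >= 2 else np.nan) for n in und.nodes}, dtype=float
    )


def _nanmean(values) -> float:
    arr = np.asarray(values, dtype=float)
    ok = np.isfinite(arr)
    return float(arr[ok].mean()) if ok.any() else np.nan


def weighted_clustering(g: nx.Graph, mode: str | None = None) -> pd.Series:
    """Weighted local clustering coefficient per node.

    ``barrat_local`` (undirected): C_i = 1/(s_i (k_i - 1)) *
    sum_{j,h} (w_ij + w_ih)/2 * a_ij a_ih a_jh — Barrat's form, which
    reduces to the unweighted local clustering when all weights are 1.

    ``directed_weighted``: the Clemente–Grassi total clustering using
    the symmetrised weights W~ = (W + W')/2 and total degrees.

    Nodes with fewer than 2 (total-degree) neighbours are NaN.  Mode
    defaults to the one matching the graph's directedness.
    """
    if mode is None:
        mode = "directed_weighted" if g.is_directed() else "barrat_local"
    nodes, w = _adjacency(g)
    a = (w > 0).astype(float)

    if mode == "barrat_local":
        if g.is_directed():
            raise ValueError("barrat_local applies to undirected networks")
        k = a.sum(axis=1)
        s = w.sum(axis=1)
        numer = np.diag(w @ a @ a)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = numer / (s * (k - 1.0))
        c = np.where(k >= 2, c, np.nan)
    elif mode == "directed_weighted":
        wt = (w + w.T) / 2.0
        abar = a + a.T
        d_tot = abar.sum(axis=1)
        s_tot = (w + w.T).sum(axis=1)
        s_bil = (wt * a * a.T).sum(axis=1)
        numer = np.diag(wt @ abar @ abar)
        den = s_tot * (d_tot - 1.0) - 2.0 * s_bil
        with np.errstate(invalid="ignore", divide="ignore"):
            c = numer / den
        c = np.where(den > 0, c, np.nan)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(c, index=nodes)


def clustering_summary(g: nx.Graph, mode: str | None = None) -> tuple[float, float, int]:
    """Mean and SEM of the weighted local clustering over defined nodes."""
    c = weighted_clustering(g, mode=mode).dropna()
    if c.empty:
        return np.nan, np.nan, 0
    sem = float(c.std(ddof=1) / np.sqrt(len(c))) if len(c) > 1 else 0.0
    return float(c.mean()), sem, int(len(c))


def small_world_index(g: nx.Graph) -> float:
    """Humphries–Gurney small-world index on the binarized graph.

    SWI = (CC/CC_rand) / (L/L_rand) with the closed-form random-graph
    references CC_rand = density = 2m/(n(n-1)) and
    L_rand = ln(n)/ln(mean degree).  Directed networks are symmetrised
    and binarized first.  Undefined (NaN) when mean degree <= 1.
    """
    und = nx.Graph(g.to_undirected()) if g.is_directed() else g
    n = und.number_of_nodes()
    m = und.number_of_edges()
    if n < 2 or m == 0:
        return np.nan
    mean_deg = 2.0 * m / n
    if mean_deg <= 1.0:
        return np.nan
    cc = _nanmean(_binary_local_clustering(und))
    cc_rand = 2.0 * m / (n * (n - 1.0))
    el = characteristic_path_length(und)
    el_rand = np.log(n) / np.log(mean_deg)
    if not np.isfinite(el) or el <= 0 or cc_rand <= 0 or el_rand <= 0:
        return np.nan
    return (cc / cc_rand) / (el / el_rand)


def topology_summary(g: nx.Graph) -> TopologySummary:
    """Assemble the per-network topology row.

    Density uses the directed/undirected pair count as appropriate;
    reciprocity (reciprocated arcs / total arcs) only applies to
    directed networks; path length and transitivity are computed on
    the unweighted (binarized, symmetrised for transitivity) graph;
    the clustering coefficient is reported both binarized and weighted
    (mean local value over nodes with degree >= 2).
    """
    n = g.number_of_nodes()
    m = g.number_of_edges()
    directed = g.is_directed()
    possible = n * (n - 1) if directed else n * (n - 1) / 2
    density = m / possible if possible else np.nan
    reciprocity = None
    if directed:
        reciprocity = (
            sum(1 for u, v in g.edges if g.has_edge(v, u)) / m if m else np.nan
        )
    und = nx.Graph(g.to_undirected()) if directed else g
    transitivity = nx.transitivity(und)
    cpl = characteristic_path_length(g)
    cc_bin = _nanmean(_binary_local_clustering(g)) if m else np.nan
    cc_w, _, _ = clustering_summary(g)
    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        density=density,
        reciprocity=reciprocity,
        char_path_length=cpl,
        global_transitivity=transitivity,
        clustering_binary=cc_bin,
        clustering_weighted=cc_w,
        small_world_index=small_world_index(g),
    )
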