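"""Graph-theoretical metrics of brain networks.

Twelve global measures (clustering coefficient Cp, characteristic path
length Lp, their surrogate-normalised forms gamma and lambda, small-
worldness sigma = gamma/lambda, local and global efficiency, assortativity,
hierarchy, synchronizability, modularity Q and the number of modules) and
six nodal measures (degree, efficiency, betweenness, clustering,
participation coefficient and its module-count-normalised form), for both
binarized and weighted undirected networks.

Conventions for weighted networks: path length uses edge length = 1/weight
(strong connections are short); clustering uses the Onnela geometric-mean
triangle intensity with weights scaled by the network maximum, which keeps
it in [0, 1]; degree generalises to strength (sum of weights).

Metrics that are undefined on a given graph (assortativity on a regular
graph, hierarchy with too few eligible nodes, normalised participation in
a single-module partition) are returned as NaN rather than silently zero,
so downstream reliability statistics can exclude them pairwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .construction import BINARIZED, WEIGHTED, BrainNetwork

__all__ = [
    "ModulePartition",
    "GlobalMetrics",
    "NodalMetrics",
    "degree",
    "shortest_path_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "clustering",
    "local_efficiency",
    "betweenness",
    "nodal_efficiency",
    "random_rewire",
    "small_world",
    "assortativity",
    "hierarchy",
    "synchronization",
    "modularity",
    "participation",
    "global_metrics",
    "nodal_metrics",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = ["Cp", "Lp", "gamma", "lambda", "sigma", "Eloc",
                       "Eglob", "assortativity", "hierarchy",
                       "synchronization", "modularity_Q", "n_modules"]
NODAL_METRIC_NAMES = ["degree", "efficiency", "betweenness", "clustering",
                      "participation", "participation_norm"]


@dataclass
class ModulePartition:
    """Assignment of every node to one module."""

    labels: np.ndarray  # node index -> module id (0..n_modules-1)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        # relabel to contiguous 0..M-1 so every module is nonempty
        self.labels = np.searchsorted(uniq, self.labels)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class GlobalMetrics:
    Cp: float
    Lp: float
    gamma: float
    lambda_: float
    sigma: float
    Eloc: float
    Eglob: float
    assortativity: float
    hierarchy: float
    synchronization: float
    modularity_Q: float
    n_modules: float

    def to_dict(self) -> dict[str, float]:
        d = {name: getattr(self, "lambda_" if name == "lambda" else name)
             for name in GLOBAL_METRIC_NAMES}
        return d


@dataclass
class NodalMetrics:
    degree: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray
    clustering: np.ndarray
    participation: np.ndarray
    participation_norm: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in NODAL_METRIC_NAMES}


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------

def _binary_adjacency(net: BrainNetwork) -> np.ndarray:
    return (net.adjacency > 0).astype(float)


def to_networkx(net: BrainNetwork) -> nx.Graph:
    g = nx.from_numpy_array(net.adjacency)
    if net.kind == WEIGHTED:
        for _, _, d in g.edges(data=True):
            d["length"] = 1.0 / d["weight"]
    return g


def degree(net: BrainNetwork) -> np.ndarray:
    """Nodal degree (binarized) or strength = sum of weights (weighted)."""
    return net.adjacency.sum(axis=0)


def _length_matrix(net: BrainNetwork) -> np.ndarray:
    a = net.adjacency
    if net.kind == BINARIZED:
        return a
    with np.errstate(divide="ignore"):
        lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
    return lengths


def shortest_path_lengths(net: BrainNetwork) -> np.ndarray:
    """All-pairs distance matrix; unreachable pairs are +inf.

    Binarized graphs use hop counts; weighted graphs use edge length
    1/weight (Dijkstra).
    """
    lengths = _length_matrix(net)
    d = _csgraph_shortest_path(csr_matrix(lengths), method="D", directed=False,
                               unweighted=(net.kind == BINARIZED))
    return d


def _eglob_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        raise ValueError("efficiency undefined for a single-node graph")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf),
                       0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def global_efficiency(net: BrainNetwork,
                      distances: np.ndarray | None = None) -> float:
    """Mean inverse shortest path length over ordered node pairs.

    Unreachable pairs contribute 0, so the measure is defined on
    disconnected graphs and lies in [0, 1].
    """
    d = shortest_path_lengths(net) if distances is None else distances
    return _eglob_from_distances(d)


def characteristic_path_length(net: BrainNetwork,
                               distances: np.ndarray | None = None) -> float:
    """Characteristic path length Lp.

    Mean shortest path length over pairs when the graph is connected; on
    a disconnected graph the harmonic mean N(N-1)/sum(1/d) (infinite
    distances dropping out) so the value stays finite whenever any pair
    is connected.
    """
    d = shortest_path_lengths(net) if distances is None else distances
    n = d.shape[0]
    if n < 2:
        raise ValueError("path length undefined for a single-node graph")
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    if np.all(np.isfinite(vals)):
        return float(vals.mean())
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(vals), 1.0 / vals, 0.0)
    s = inv.sum()
    return float(n * (n - 1) / s) if s > 0 else float("inf")


def clustering(net: BrainNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering c_i and its network mean Cp.

    Binarized: fraction of realised edges among a node's neighbours.
    Weighted: Onnela geometric-mean triangle intensity with weights
    normalised by the maximum weight; nodes with fewer than two
    neighbours get c_i = 0.
    """
    b = _binary_adjacency(net)
    k = b.sum(axis=0)
    denom = k * (k - 1)
    if net.kind == BINARIZED:
        tri = np.diag(b @ b @ b) / 2.0
    else:
        wmax = net.adjacency.max()
        w = (net.adjacency / wmax) ** (1.0 / 3.0) if wmax > 0 else net.adjacency
        tri = np.diag(w @ w @ w) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, 2.0 * tri / np.where(denom > 0, denom, 1.0),
                     0.0)
    return c, float(c.mean())


def local_efficiency(net: BrainNetwork) -> float:
    """Mean, over nodes, of the global efficiency of the neighbour-induced
    subgraph; nodes with fewer than two neighbours contribute 0."""
    b = _binary_adjacency(net)
    n = net.n_nodes
    vals = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(b[i])[0]
        if nbrs.size < 2:
            continue
        sub = net.adjacency[np.ix_(nbrs, nbrs)]
        subnet = BrainNetwork(sub, net.kind, net.membership, net.sparsity,
                              net.threshold_used,
                              [net.roi_labels[j] for j in nbrs])
        vals[i] = global_efficiency(subnet)
    return float(vals.mean())


def betweenness(net: BrainNetwork) -> np.ndarray:
    """Fractional shortest-path betweenness, endpoints excluded.

    b_i = sum over pairs (s, t) of the fraction of s-t geodesics passing
    through i; weighted geodesics use edge length 1/weight.
    """
    g = to_networkx(net)
    weight = "length" if net.kind == WEIGHTED else None
    bc = nx.betweenness_centrality(g, normalized=False, weight=weight)
    return np.array([bc[i] for i in range(net.n_nodes)])


def nodal_efficiency(net: BrainNetwork,
                     distances: np.ndarray | None = None) -> np.ndarray:
    """e_i = mean over j != i of 1/d(i, j); unreachable pairs count 0."""
    d = shortest_path_lengths(net) if distances is None else distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf),
                       0.0)
    return inv.sum(axis=1) / (n - 1)


# ---------------------------------------------------------------------------
# degree-preserving null model and small-world indices
# ---------------------------------------------------------------------------

def random_rewire(net: BrainNetwork, n_iterations: int | None = None,
                  seed: int | np.random.Generator = 0) -> BrainNetwork:
    """Degree-preserving surrogate via double-edge swaps.

    Performs ``n_iterations`` successful swaps (default 10 per edge);
    each swap replaces edges (a, b), (c, d) with (a, d), (c, b), rejected
    if it would create a self-loop or multi-edge, so the degree sequence
    is preserved exactly.  Weighted networks are rewired topologically
    and the original weight multiset is randomly permuted onto the new
    edges.  If no feasible swap exists (e.g. a complete graph) the
    best-effort surrogate is returned with a warning.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    iu, ju = np.nonzero(np.triu(net.adjacency, k=1))
    m = iu.size
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    if n_iterations is None:
        n_iterations = 10 * m
    edges = np.stack([iu, ju], axis=1)
    present = set(map(tuple, edges.tolist()))
    swaps = 0
    attempts = 0
    max_attempts = max(100 * n_iterations, 1000)
    while swaps < n_iterations and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in present or new2 in present or new1 == new2:
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard((min(c, d), max(c, d)))
        present.add(new1)
        present.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        swaps += 1
    if swaps == 0 and n_iterations > 0:
        warnings.warn("no feasible degree-preserving swap found; returning "
                      "the input topology as best-effort surrogate",
                      RuntimeWarning, stacklevel=2)
    adj = np.zeros_like(net.adjacency)
    if net.kind == WEIGHTED:
        weights = net.adjacency[iu, ju]
        weights = rng.permutation(weights)
    else:
        weights = np.ones(m)
    adj[edges[:, 0], edges[:, 1]] = weights
    adj = adj + adj.T
    return BrainNetwork(adj, net.kind, net.membership, net.sparsity,
                        net.threshold_used, list(net.roi_labels),
                        net.subject_id, net.scan_id)


def small_world(net: BrainNetwork, n_random: int = 100,
                n_iterations: int | None = None,
                seed: int = 0) -> tuple[float, float, float]:
    """Normalised clustering gamma, normalised path length lambda, and
    small-worldness sigma = gamma/lambda, against a degree-matched
    surrogate ensemble."""
    _, cp = clustering(net)
    lp = characteristic_path_length(net)
    rng = np.random.default_rng(seed)
    cps, lps = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_random):
            surr = random_rewire(net, n_iterations, rng)
            _, cp_r = clustering(surr)
            cps.append(cp_r)
            lps.append(characteristic_path_length(surr))
    cp_rand = float(np.mean(cps))
    lp_rand = float(np.mean(lps))
    if cp_rand == 0:
        raise ValueError("degenerate surrogate ensemble: mean random "
                         "clustering is zero")
    gamma = cp / cp_rand
    lam = lp / lp_rand if lp_rand > 0 else float("nan")
    sigma = gamma / lam
    return gamma, lam, sigma


# ---------------------------------------------------------------------------
# second-order global structure
# ---------------------------------------------------------------------------

def assortativity(net: BrainNetwork) -> float:
    """Degree-degree (strength-strength for weighted) Pearson correlation
    over edge endpoints, both orientations counted; NaN when the endpoint
    degrees have zero variance (e.g. regular graphs)."""
    iu, ju = np.nonzero(np.triu(net.adjacency, k=1))
    if iu.size < 2:
        return float("nan")
    k = degree(net)
    x = np.concatenate([k[iu], k[ju]])
    y = np.concatenate([k[ju], k[iu]])
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def hierarchy(net: BrainNetwork) -> float:
    """Hierarchy coefficient b from the power-law scaling c_i ~ k_i^(-b).

    Least-squares slope of log c_i on log k_i over nodes with degree >= 2
    and positive clustering; NaN with fewer than 3 eligible nodes or no
    degree heterogeneity among them.
    """
    c, _ = clustering(net)
    k = degree(net)
    kb = _binary_adjacency(net).sum(axis=0)
    elig = (kb >= 2) & (c > 0) & (k > 0)
    if elig.sum() < 3:
        return float("nan")
    lk = np.log(k[elig])
    lc = np.log(c[elig])
    if np.std(lk) == 0:
        return float("nan")
    with warnings.catch_warnings():
        # few eligible nodes with close degrees are poorly conditioned but
        # still well-defined; the zero-variance case is excluded above
        warnings.simplefilter("ignore")
        slope = np.polyfit(lk, lc, 1)[0]
    return float(-slope)


def synchronization(net: BrainNetwork) -> float:
    """Synchronizability s = lambda_2 / lambda_max of the graph Laplacian
    L = D - A (weighted Laplacian for weighted networks); 0 for a
    disconnected network (lambda_2 = 0)."""
    a = net.adjacency
    lap = np.diag(a.sum(axis=0)) - a
    ev = np.linalg.eigvalsh(lap)
    lam_max = ev[-1]
    if lam_max <= 0:
        return 0.0
    lam2 = ev[1]
    if lam2 < 1e-10 * max(lam_max, 1.0):
        return 0.0
    return float(lam2 / lam_max)


def modularity(net: BrainNetwork,
               seed: int = 0) -> tuple[ModulePartition, float]:
    """Newman modularity maximisation by deterministic greedy
    agglomeration (Clauset-Newman-Moore); returns the partition and Q.

    The algorithm is deterministic, so repeated runs on the same network
    give identical partitions — test-retest comparisons are not polluted
    by algorithmic randomness (``seed`` is accepted for interface
    stability but unused by the greedy algorithm).
    """
    if net.n_edges == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    g = to_networkx(net)
    weight = "weight" if net.kind == WEIGHTED else None
    comms = nx.community.greedy_modularity_communities(g, weight=weight)
    labels = np.zeros(net.n_nodes, dtype=int)
    for mod_id, members in enumerate(comms):
        for node in members:
            labels[node] = mod_id
    part = ModulePartition(labels)
    q = nx.community.modularity(g, comms, weight=weight)
    return part, float(q)


def participation(net: BrainNetwork,
                  part: ModulePartition) -> tuple[np.ndarray, np.ndarray]:
    """Participation coefficient PC_i = 1 - sum_m (k_im / k_i)^2 and its
    module-count-normalised form PCnorm_i = PC_i / (1 - 1/M).

    PC is 0 when all of a node's edges stay inside its own module and
    approaches 1 - 1/M when they spread evenly over the M modules;
    dividing by that maximum makes values comparable across partitions
    with different module counts.  Isolated nodes get PC = 0; PCnorm is
    NaN when the partition has a single module.
    """
    if part.labels.size != net.n_nodes:
        raise ValueError("partition must label every node")
    k = degree(net)
    m = part.n_modules
    k_im = np.zeros((net.n_nodes, m))
    for mod in range(m):
        k_im[:, mod] = net.adjacency[:, part.labels == mod].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(k[:, None] > 0, k_im / np.where(k[:, None] > 0,
                                                        k[:, None], 1.0), 0.0)
    pc = np.where(k > 0, 1.0 - (frac ** 2).sum(axis=1), 0.0)
    if m <= 1:
        pcnorm = np.full(net.n_nodes, np.nan)
    else:
        pcnorm = pc / (1.0 - 1.0 / m)
    return pc, pcnorm


# ---------------------------------------------------------------------------
# bundled computation
# ---------------------------------------------------------------------------

def global_metrics(net: BrainNetwork, n_random: int = 100,
                   n_iterations: int | None = None, seed: int = 0,
                   include_normalized: bool = True) -> GlobalMetrics:
    """All twelve global metrics of one network.

    ``include_normalized=False`` skips the surrogate-ensemble quantities
    gamma/lambda/sigma (returned as NaN), which dominate runtime.
    """
    d = shortest_path_lengths(net)
    _, cp = clustering(net)
    lp = characteristic_path_length(net, d)
    eglob = _eglob_from_distances(d)
    eloc = local_efficiency(net)
    if include_normalized and net.n_edges >= 2 and n_random > 0:
        try:
            gamma, lam, sigma = small_world(net, n_random, n_iterations, seed)
        except ValueError:
            # degenerate surrogate ensemble (e.g. triangle-free nulls):
            # flagged rather than fatal so sparse grid levels stay usable
            gamma = lam = sigma = float("nan")
    else:
        gamma = lam = sigma = float("nan")
    part, q = (modularity(net) if net.n_edges > 0
               else (ModulePartition(np.zeros(net.n_nodes)), float("nan")))
    return GlobalMetrics(
        Cp=cp, Lp=lp, gamma=gamma, lambda_=lam, sigma=sigma, Eloc=eloc,
        Eglob=eglob, assortativity=assortativity(net),
        hierarchy=hierarchy(net), synchronization=synchronization(net),
        modularity_Q=q, n_modules=float(part.n_modules))


def nodal_metrics(net: BrainNetwork,
                  part: ModulePartition | None = None) -> NodalMetrics:
    """All six nodal metrics of one network.

    The module partition for the participation coefficients is computed
    by :func:`modularity` when not supplied.
    """
    if part is None:
        part, _ = modularity(net)
    d = shortest_path_lengths(net)
    c, _ = clustering(net)
    pc, pcnorm = participation(net, part)
    return NodalMetrics(
        degree=degree(net), efficiency=nodal_efficiency(net, d),
        betweenness=betweenness(net), clustering=c,
        participation=pc, participation_norm=pcnorm,
        roi_labels=list(net.roi_labels))
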