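"""Region adjacency, the intrinsic MRF (ICAR) prior and Moran's I.

The structured spatial effect f_str carries an intrinsic Gaussian Markov
random field prior: conditional on its neighbours, a region's effect is
normal with mean the neighbour average and variance τ²/N_s,

    f_str(s) | f_str(r), r ~ s  ∼  N( Σ_{r∼s} f_str(r) / N_s , τ² / N_s ).

The implied (improper) joint density is ∝ exp(-f'Qf / 2τ²) with the graph
Laplacian precision Q = D - A.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

# Adjacency of Kenya's eight pre-2010 administrative provinces, encoded from
# standard provincial contiguity (the survey frames never print it).
KENYA_PROVINCES = [
    "Central", "Coast", "Eastern", "Nairobi", "North Eastern", "Nyanza",
    "Rift Valley", "Western",
]
KENYA_EDGES = [
    ("Central", "Eastern"), ("Central", "Nairobi"), ("Central", "Rift Valley"),
    ("Coast", "Eastern"), ("Coast", "North Eastern"), ("Coast", "Rift Valley"),
    ("Eastern", "Nairobi"), ("Eastern", "North Eastern"),
    ("Eastern", "Rift Valley"), ("Nairobi", "Rift Valley"),
    ("Nyanza", "Rift Valley"), ("Nyanza", "Western"),
    ("Rift Valley", "Western"),
]


@dataclass
class RegionGraph:
    """Ordered region labels with symmetric adjacency."""

    region_ids: list
    graph: nx.Graph

    def __post_init__(self):
        labels = list(self.region_ids)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate region labels")
        for u, v in self.graph.edges:
            if u == v:
                raise ValueError(f"self-loop at {u}")
            if u not in labels or v not in labels:
                raise ValueError(f"edge ({u},{v}) uses unknown region label")
        self.region_ids = labels

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def neighbors(self, s) -> list:
        return sorted(self.graph.neighbors(s))

    @property
    def n_neighbors(self) -> np.ndarray:
        return np.array([self.graph.degree(s) for s in self.region_ids])

    def index(self, s) -> int:
        return self.region_ids.index(s)

    @property
    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    @classmethod
    def from_edges(cls, region_ids, edges) -> "RegionGraph":
        g = nx.Graph()
        g.add_nodes_from(region_ids)
        g.add_edges_from(edges)
        return cls(list(region_ids), g)


def kenya_province_graph() -> RegionGraph:
    return RegionGraph.from_edges(KENYA_PROVINCES, KENYA_EDGES)


def read_adjacency(path) -> RegionGraph:
    """Read a region graph from the plain edge-list dialect or a BayesX .gra.

    Edge-list dialect: first line is the region count S, next S lines list
    the region labels in order, remaining lines are "regionA<TAB/space>regionB"
    pairs.  BayesX .gra dialect: S, then per region its label, its neighbour
    count, and the (1-based or 0-based) neighbour indices.
    """
    with open(path) as fh:
        tokens = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if str(path).endswith(".gra"):
        return _read_gra(tokens)
    s = int(tokens[0])
    labels = tokens[1 : 1 + s]
    edges = []
    for line in tokens[1 + s :]:
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed edge line: {line!r}")
        edges.append(tuple(parts))
    return RegionGraph.from_edges(labels, edges)


def _read_gra(tokens):
    s = int(tokens[0])
    labels, nbr_lists = [], []
    i = 1
    for _ in range(s):
        labels.append(tokens[i])
        k = int(tokens[i + 1])
        nbr_lists.append([int(t) for t in tokens[i + 2].split()] if k else [])
        if k and len(nbr_lists[-1]) != k:
            raise ValueError(f"region {labels[-1]}: expected {k} neighbours")
        i += 3 if k else 2
        if not k:
            nbr_lists[-1] = []
    base = 0 if any(0 in nb for nb in nbr_lists) else 1
    edges = set()
    for a, nbrs in enumerate(nbr_lists):
        for b in nbrs:
            edges.add(tuple(sorted((labels[a], labels[b - base]))))
    g = RegionGraph.from_edges(labels, edges)
    # .gra files list both directions; verify symmetry of the listing
    for a, nbrs in enumerate(nbr_lists):
        for b in nbrs:
            if a + base not in nbr_lists[b - base]:
                raise ValueError(
                    f"asymmetric adjacency: {labels[a]} lists {labels[b-base]} "
                    "but not conversely")
    return g


def mrf_precision(graph: RegionGraph) -> np.ndarray:
    """Intrinsic MRF precision Q = D - A (graph Laplacian).

    Rows sum to zero; rank is S minus the number of connected components.
    Isolated regions get a zero row/column — their structured effect is
    pinned to 0 by the island policy and their variation is left to the
    unstructured iid term.
    """
    if graph.n_regions < 2:
        raise ValueError("need at least 2 regions")
    if (graph.n_neighbors == 0).any():
        import warnings

        warnings.warn("graph has isolated regions; their structured effect is "
                      "fixed at 0")
    a = nx.to_numpy_array(graph.graph, nodelist=graph.region_ids)
    return np.diag(a.sum(axis=1)) - a


def conditional_prior_params(graph: RegionGraph, s, f: np.ndarray,
                             tau_s: float) -> tuple[float, float]:
    """Mean and variance of f_str(s) given neighbour values: the ICAR
    full conditional N(neighbour mean, τ²/N_s)."""
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    nbrs = [graph.index(r) for r in graph.neighbors(s)]
    if not nbrs:
        raise ValueError(f"region {s} is isolated; conditional prior undefined")
    f = np.asarray(f, dtype=float)
    return float(np.mean(f[nbrs])), float(tau_s**2 / len(nbrs))


def morans_i(values, graph: RegionGraph, n_perm: int = 999,
             seed: int = 0) -> tuple[float, float]:
    """Moran's I with binary (row-unstandardized) weights and a two-sided
    permutation test — the robust choice at a handful of areal units.

    I = (S/W) Σ_ij w_ij (x_i - x̄)(x_j - x̄) / Σ_i (x_i - x̄)².
    """
    x = np.asarray(values, dtype=float)
    if x.shape[0] != graph.n_regions:
        raise ValueError("values length must equal number of regions")
    if np.var(x) == 0:
        raise ValueError("constant values: Moran's I undefined")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    w = nx.to_numpy_array(graph.graph, nodelist=graph.region_ids)
    s_tot = w.sum()

    def stat(v):
        d = v - v.mean()
        return len(v) / s_tot * (d @ w @ d) / (d @ d)

    i_obs = stat(x)
    rng = np.random.default_rng(seed)
    perm = np.array([stat(rng.permutation(x)) for _ in range(n_perm)])
    # two-sided permutation p-value with the observed statistic included
    p = (1 + np.sum(np.abs(perm - perm.mean()) >= abs(i_obs - perm.mean()))) / (n_perm + 1)
    return float(i_obs), float(min(p, 1.0))
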