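"""Prior interaction graphs and their Laplacians.

The GraphNet penalty draws on an undirected prior graph over the features
of one block (gene-gene interactions, typically).  This module loads such
graphs (edge list or SIF), aligns them to a block's feature list, builds
raw / normalized Laplacians with their largest eigenvalue, and implements
the structured perturbations used to interrogate what the graph
contributes: label permutation and edge removal (random / inner / outer /
isolating).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

logger = logging.getLogger(__name__)

__all__ = [
    "PriorGraph",
    "GraphLaplacian",
    "load_graph",
    "align_graph",
    "build_laplacian",
    "largest_eigenvalue",
    "permute_labels",
    "remove_edges",
    "graph_summary",
    "pairwise_distances",
]

# Dense eigendecomposition below this size; iterative sparse solver above.
_DENSE_EIG_CUTOFF = 500


@dataclass
class PriorGraph:
    """Undirected simple labelled graph (no self-loops, no duplicate edges).

    Wraps a :class:`networkx.Graph`; node order is the insertion order and is
    preserved by every transformation so Laplacian rows match feature order
    after alignment.
    """

    g: nx.Graph

    @classmethod
    def from_edges(
        cls,
        nodes: list[str],
        edges: list[tuple],
        weights: dict | None = None,
    ) -> "PriorGraph":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            u, v = e[0], e[1]
            if u == v:
                continue
            w = 1.0
            if len(e) > 2:
                w = float(e[2])
            elif weights is not None:
                w = float(weights.get((u, v), weights.get((v, u), 1.0)))
            g.add_edge(u, v, weight=w)
        return cls(g)

    @property
    def nodes(self) -> list:
        return list(self.g.nodes)

    @property
    def edges(self) -> set:
        return {frozenset((u, v)) for u, v in self.g.edges}

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def degree(self, node) -> int:
        return self.g.degree[node]

    def is_weighted(self) -> bool:
        return any(d.get("weight", 1.0) != 1.0 for _, _, d in self.g.edges(data=True))

    def copy(self) -> "PriorGraph":
        return PriorGraph(self.g.copy())


@dataclass
class GraphLaplacian:
    """Graph Laplacian (raw ``L = D - A`` or normalized
    ``I - D^{-1/2} A D^{-1/2}``) with its largest eigenvalue cached.

    Isolated nodes get an all-zero row and column in both variants, so the
    penalty is inert on features absent from the prior graph.
    """

    matrix: sp.csr_matrix
    variant: str
    node_order: list
    _lambda_max: float | None = field(default=None, repr=False)

    @property
    def shape(self):
        return self.matrix.shape

    @property
    def lambda_max(self) -> float:
        if self._lambda_max is None:
            self._lambda_max = largest_eigenvalue(self)
        return self._lambda_max


def load_graph(path, format: str = "edgelist",
               relation_whitelist: set | None = None) -> PriorGraph:
    """Load an undirected simple graph from an edge list or SIF file.

    Edge list: two whitespace-separated label columns, optional third
    numeric weight column; ``#`` lines ignored.  SIF:
    ``source<TAB>relation<TAB>target1 [target2 ...]`` — relation tokens are
    ignored unless a whitelist is given.  Duplicate / reversed edges
    collapse; self-loops are dropped (count logged).
    """
    path = str(path)
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if format == "edgelist":
                parts = line.split()
                if len(parts) not in (2, 3):
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                    )
                u, v = parts[0], parts[1]
                try:
                    w = float(parts[2]) if len(parts) == 3 else 1.0
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric edge weight {parts[2]!r}"
                    ) from None
                if u == v:
                    n_self += 1
                    g.add_node(u)
                    continue
                g.add_edge(u, v, weight=w)
            elif format == "sif":
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) == 1:
                    g.add_node(parts[0])
                    continue
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: SIF line needs source, relation, target(s)"
                    )
                src, rel, targets = parts[0], parts[1], parts[2:]
                if relation_whitelist is not None and rel not in relation_whitelist:
                    continue
                for t in targets:
                    if t == src:
                        n_self += 1
                        g.add_node(src)
                        continue
                    g.add_edge(src, t, weight=1.0)
            else:
                raise ValueError(f"unknown graph format {format!r}")
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    return PriorGraph(g)


def align_graph(
    graph: PriorGraph,
    feature_names: list[str],
    feature_to_node: dict | None = None,
) -> PriorGraph:
    """Restrict/extend the graph to exactly one node per feature, in order.

    Features absent from the graph become isolated nodes; when several
    features map to the same graph node (``feature_to_node``), each receives
    a copy of that node's edges; graph nodes matching no feature are dropped.
    """
    if not feature_names:
        raise ValueError("feature_names must be non-empty")
    if feature_to_node is None:
        feature_to_node = {}
    out = nx.Graph()
    out.add_nodes_from(feature_names)
    node_features: dict = {}
    for f in feature_names:
        node_features.setdefault(feature_to_node.get(f, f), []).append(f)
    for u, v, data in graph.g.edges(data=True):
        w = data.get("weight", 1.0)
        for fu in node_features.get(u, ()):
            for fv in node_features.get(v, ()):
                if fu != fv:
                    out.add_edge(fu, fv, weight=w)
    return PriorGraph(out)


def build_laplacian(graph: PriorGraph, variant: str = "raw") -> GraphLaplacian:
    """Laplacian of an (aligned) graph.

    raw: ``L = D - A``.  normalized: ``I - D^{-1/2} A D^{-1/2}`` on
    non-isolated nodes, all-zero row/column on isolated nodes.  Weighted
    graphs use weighted degrees.
    """
    if variant not in ("raw", "normalized"):
        raise ValueError(f"unknown Laplacian variant {variant!r}")
    nodes = graph.nodes
    p = len(nodes)
    A = nx.to_scipy_sparse_array(graph.g, nodelist=nodes, weight="weight",
                                 format="csr", dtype=float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    if variant == "raw":
        L = sp.diags(deg) - A
    else:
        with np.errstate(divide="ignore"):
            dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
        Dinv = sp.diags(dinv)
        I_nz = sp.diags((deg > 0).astype(float))
        L = I_nz - Dinv @ A @ Dinv
    L = sp.csr_matrix((L + L.T) / 2.0)  # exact symmetry
    return GraphLaplacian(matrix=L, variant=variant, node_order=list(nodes))


def largest_eigenvalue(L: GraphLaplacian, tol: float = 1e-6,
                       maxiter: int | None = None) -> float:
    """Largest eigenvalue of the Laplacian, cached on the object.

    Dense eigendecomposition below 500 nodes, otherwise a Lanczos sparse
    eigensolver with relative tolerance 1e-6.
    """
    if L._lambda_max is not None:
        return L._lambda_max
    p = L.matrix.shape[0]
    if L.matrix.nnz == 0:
        lam = 0.0
    elif p < _DENSE_EIG_CUTOFF:
        lam = float(np.linalg.eigvalsh(L.matrix.toarray())[-1])
    else:
        try:
            vals = spla.eigsh(L.matrix, k=1, which="LA", tol=tol,
                              maxiter=maxiter, return_eigenvectors=False)
            lam = float(vals[0])
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError(
                "largest-eigenvalue iteration did not converge; consider a "
                "dense eigendecomposition for this graph size"
            ) from exc
    lam = max(lam, 0.0)
    L._lambda_max = lam
    return lam


def permute_labels(graph: PriorGraph, seed: int) -> PriorGraph:
    """Permute node labels uniformly at random; the unlabelled edge
    structure (hence the degree multiset) is unchanged."""
    rng = np.random.default_rng(seed)
    nodes = graph.nodes
    perm = rng.permutation(len(nodes))
    mapping = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
    out = nx.Graph()
    out.add_nodes_from(nodes)  # preserve node order
    for u, v, data in graph.g.edges(data=True):
        out.add_edge(mapping[u], mapping[v], **data)
    return PriorGraph(out)


def remove_edges(
    graph: PriorGraph,
    mode: str,
    node_subset: set | None = None,
    fraction: float = 0.0,
    seed: int = 0,
) -> PriorGraph:
    """Structured edge removal; the node set is never changed.

    random: remove ``floor(fraction * |E|)`` uniformly chosen edges.
    inner: remove edges with both endpoints in ``node_subset``.
    outer: remove edges with exactly one endpoint in ``node_subset``.
    isolate: remove every edge incident to ``node_subset``.
    """
    out = graph.g.copy()
    if mode == "random":
        if not (0.0 <= fraction <= 1.0):
            raise ValueError(f"fraction must be in [0, 1], got {fraction}")
        edges = list(out.edges)
        k = math.floor(fraction * len(edges))
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(edges), size=k, replace=False) if k else []
        out.remove_edges_from(edges[i] for i in chosen)
    elif mode in ("inner", "outer", "isolate"):
        if not node_subset:
            raise ValueError(f"mode {mode!r} requires a non-empty node_subset")
        S = set(node_subset)
        to_drop = []
        for u, v in out.edges:
            inside = (u in S) + (v in S)
            if mode == "inner" and inside == 2:
                to_drop.append((u, v))
            elif mode == "outer" and inside == 1:
                to_drop.append((u, v))
            elif mode == "isolate" and inside >= 1:
                to_drop.append((u, v))
        out.remove_edges_from(to_drop)
    else:
        raise ValueError(f"unknown removal mode {mode!r}")
    return PriorGraph(out)


def graph_summary(graph: PriorGraph) -> dict:
    """Node/edge counts, density, isolated fraction, and diameter/radius of
    the largest connected component."""
    p = graph.n_nodes
    m = graph.n_edges
    density = m / (p * (p - 1) / 2) if p > 1 else 0.0
    isolated = sum(1 for v in graph.g.nodes if graph.g.degree[v] == 0)
    diameter = radius = None
    if m > 0:
        comp = max(nx.connected_components(graph.g), key=len)
        sub = graph.g.subgraph(comp)
        ecc = nx.eccentricity(sub)
        diameter = max(ecc.values())
        radius = min(ecc.values())
    elif p > 0:
        diameter = radius = 0
    return {
        "n_nodes": p,
        "n_edges": m,
        "density": density,
        "isolated_fraction": isolated / p if p else 0.0,
        "diameter": diameter,
        "radius": radius,
    }


def pairwise_distances(graph: PriorGraph, nodes) -> dict:
    """Shortest-path length between every pair of the given nodes.

    Unweighted graphs use BFS hop counts; weighted graphs use weighted
    shortest paths.  Unreachable pairs map to ``inf``.
    """
    nodes = list(nodes)
    for v in nodes:
        if v not in graph.g:
            raise KeyError(f"unknown node {v!r}")
    weighted = graph.is_weighted()
    out: dict = {}
    for i, u in enumerate(nodes):
        if weighted:
            lengths = nx.single_source_dijkstra_path_length(graph.g, u)
        else:
            lengths = nx.single_source_shortest_path_length(graph.g, u)
        for v in nodes[i:]:
            d = float(lengths[v]) if v in lengths else float("inf")
            out[(u, v)] = d
            out[(v, u)] = d
    return out
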