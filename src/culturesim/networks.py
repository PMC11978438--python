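"""Social-network topologies for the agent population.

Agents occupy fixed positions (nodes) of a static undirected network; a
newborn inherits the position of the agent it replaces.  Supported families:

``erdos_renyi``
    G(N, p) with p = k / (N - 1), so the expected mean degree is k.
``complete``
    Every pair connected (the k argument is ignored).
``small_world``
    Watts-Strogatz ring with even base degree k, rewiring probability 0.1.
``scale_free``
    Barabasi-Albert with attachment parameter m = round(k / 2), giving an
    asymptotic mean degree of about k.
``user_supplied``
    Read from a two-column whitespace-delimited edge list (0-based ids).

Isolated nodes in sparse random graphs are kept as-is: an isolated agent can
never learn socially and always proceeds to innovation, which is precisely
the behaviour the sparse limit k -> 0 probes.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

__all__ = ["SocialNetwork", "build_network", "neighbours",
           "read_edgelist", "write_edgelist"]

FAMILIES = ("erdos_renyi", "complete", "small_world", "scale_free",
            "user_supplied")


class SocialNetwork:
    """An undirected, irreflexive network with stable 0-based node ids.

    Wraps a :class:`networkx.Graph` and caches per-node neighbour index
    arrays for the simulation hot loop.
    """

    def __init__(self, graph: nx.Graph, family: str = "user_supplied",
                 mean_degree_target: float | None = None) -> None:
        if any(u == v for u, v in graph.edges):
            raise ValueError("self-loops are not allowed")
        n = graph.number_of_nodes()
        if set(graph.nodes) != set(range(n)):
            raise ValueError("nodes must be labelled 0..N-1")
        self.graph = graph
        self.family = family
        self.mean_degree_target = mean_degree_target
        self._neighbour_arrays: list[np.ndarray] = [
            np.fromiter(graph.neighbors(i), dtype=np.int64)
            for i in range(n)
        ]

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    def neighbours(self, node: int) -> np.ndarray:
        """Neighbour ids of ``node`` (possibly empty)."""
        if not 0 <= node < self.node_count:
            raise KeyError(f"unknown node {node}")
        return self._neighbour_arrays[node]

    def mean_degree(self) -> float:
        n = self.node_count
        return 2.0 * self.graph.number_of_edges() / n if n else 0.0

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Adjacency in compressed sparse row form ``(indptr, indices)``."""
        degrees = np.array([len(a) for a in self._neighbour_arrays],
                           dtype=np.int64)
        indptr = np.zeros(self.node_count + 1, dtype=np.int64)
        np.cumsum(degrees, out=indptr[1:])
        if self._neighbour_arrays:
            indices = np.concatenate(self._neighbour_arrays)
        else:
            indices = np.empty(0, dtype=np.int64)
        return indptr, indices.astype(np.int64)


def build_network(family: str, node_count: int, mean_degree: float = 0.0,
                  seed: int | None = None, *,
                  rewiring_prob: float = 0.1,
                  edge_list_path: str | Path | None = None) -> SocialNetwork:
    """Generate a social network of the given family.

    Parameters
    ----------
    family
        One of ``erdos_renyi``, ``complete``, ``small_world``,
        ``scale_free``, ``user_supplied``.
    node_count
        Population size N (>= 1).
    mean_degree
        Target mean degree k; interpretation depends on the family
        (ignored for ``complete`` and ``user_supplied``).
    seed
        Seed for the topology randomness.
    rewiring_prob
        Watts-Strogatz rewiring probability (small_world only).
    edge_list_path
        Path of the edge list (user_supplied only).
    """
    n = node_count
    if n < 1:
        raise ValueError(f"node_count must be >= 1, got {n}")
    if family not in FAMILIES:
        raise ValueError(f"unknown network family {family!r}; "
                         f"choose from {FAMILIES}")

    if family == "complete":
        g = nx.complete_graph(n)
        return SocialNetwork(g, family, float(n - 1))

    if family == "user_supplied":
        if edge_list_path is None:
            raise ValueError("user_supplied networks need edge_list_path")
        return read_edgelist(edge_list_path, node_count=n)

    k = float(mean_degree)
    if not 0.0 <= k <= n - 1:
        raise ValueError(f"mean_degree must be in [0, N-1], got {k}")

    if family == "erdos_renyi":
        p = k / (n - 1) if n > 1 else 0.0
        g = nx.fast_gnp_random_graph(n, p, seed=seed)
    elif family == "small_world":
        base = int(round(k))
        if base % 2 or base < 2:
            raise ValueError(
                "small_world needs an even base degree k >= 2, got "
                f"{mean_degree}")
        g = nx.watts_strogatz_graph(n, base, rewiring_prob, seed=seed)
    else:  # scale_free
        m = max(1, int(round(k / 2.0)))
        if m >= n:
            raise ValueError(f"scale_free needs round(k/2) < N, got k={k}")
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    g.add_nodes_from(range(n))  # keep isolated nodes
    return SocialNetwork(g, family, k)


def neighbours(net: SocialNetwork, node: int) -> set[int]:
    """Neighbour set of ``node`` in ``net`` (empty for isolated nodes)."""
    return set(int(j) for j in net.neighbours(node))


def read_edgelist(path: str | Path, node_count: int | None = None
                  ) -> SocialNetwork:
    """Read an undirected network from a two-column edge list.

    One edge per line, whitespace-delimited 0-based integer node ids;
    duplicate edges and self-loops are rejected.  ``node_count`` may extend
    the network with isolated high-id nodes.
    """
    g = nx.Graph()
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            u, v = int(parts[0]), int(parts[1])
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate edge {key}")
            seen.add(key)
            g.add_edge(u, v)
    max_id = max(g.nodes, default=-1)
    n = max(max_id + 1, node_count or 0)
    g.add_nodes_from(range(n))
    return SocialNetwork(g, "user_supplied")


def write_edgelist(net: SocialNetwork, path: str | Path) -> None:
    """Dump the network as a two-column edge list (each edge once)."""
    with open(path, "w") as fh:
        for u, v in sorted((min(u, v), max(u, v)) for u, v in net.graph.edges):
            fh.write(f"{u} {v}\n")
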