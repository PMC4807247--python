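"""Null-model graph generators used for comparison tables.

Three classic families, each seed-deterministic:

- ``er_graph``: G(n, m) Erdős–Rényi with exactly ``m`` distinct edges
  (directed or undirected), uniform over all such graphs;
- ``ba_graph``: a Barabási–Albert variant that starts from a complete
  directed clique of ``seed_size`` nodes and attaches each new node to
  ``edges_per_step`` existing nodes (linear preferential attachment on
  total degree), every edge pointing new -> existing -- the replier ->
  earlier-poster orientation. In the default exact-count mode the first
  arrivals, which face fewer existing nodes than ``edges_per_step``, draw
  targets with multiplicity so the final edge count is exactly
  ``seed_size*(seed_size-1) + edges_per_step*(n - seed_size)``;
- ``ws_graph``: a Watts–Strogatz ring lattice with ``k`` nearest
  neighbors and independent rewiring probability ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["ModelSpec", "er_graph", "ba_graph", "ws_graph", "make_model"]


@dataclass
class ModelSpec:
    model: str  # er_directed | er_undirected | ba_directed | ws
    n: int
    m: int | None = None  # ER edge count
    seed_size: int = 5  # BA
    edges_per_step: int = 7  # BA
    k: int = 6  # WS neighbors (even)
    p: float = 0.45  # WS rewiring probability
    seed: int = 0

    def validate(self) -> None:
        if self.model not in {"er_directed", "er_undirected", "ba_directed", "ws"}:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.model.startswith("er"):
            if self.m is None:
                raise ValueError("ER models need an edge count m")
            cap = self.n * (self.n - 1)
            if self.model == "er_undirected":
                cap //= 2
            if not 0 <= self.m <= cap:
                raise ValueError(f"m={self.m} outside [0, {cap}]")
        if self.model == "ba_directed" and self.n < self.seed_size:
            raise ValueError("n must be >= seed_size")
        if self.model == "ws":
            if self.k >= self.n:
                raise ValueError("WS requires k < n")
            if not 0.0 <= self.p <= 1.0:
                raise ValueError("rewire probability must lie in [0, 1]")


def _sample_distinct(rng: np.random.Generator, space: int, m: int) -> np.ndarray:
    """m distinct integers uniform on [0, space) by rejection (m << space)."""
    if m > space:
        raise ValueError("cannot draw more distinct items than the space holds")
    if m * 2 >= space:  # dense regime: permutation is cheap enough
        return rng.permutation(space)[:m]
    chosen: set[int] = set()
    while len(chosen) < m:
        batch = rng.integers(0, space, size=max(1024, int(1.2 * (m - len(chosen)))))
        for c in batch:
            chosen.add(int(c))
            if len(chosen) == m:
                break
    return np.fromiter(chosen, dtype=np.int64, count=m)


def er_graph(n: int, m: int, directed: bool = True,
             rng: np.random.Generator | int | None = None):
    """G(n, m): exactly ``m`` distinct edges, no self-loops."""
    spec = ModelSpec(model="er_directed" if directed else "er_undirected", n=n, m=m)
    spec.validate()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if directed:
        idx = _sample_distinct(rng, n * (n - 1), m)
        i = idx // (n - 1)
        r = idx % (n - 1)
        j = np.where(r < i, r, r + 1)
        g = nx.DiGraph()
    else:
        idx = _sample_distinct(rng, n * (n - 1) // 2, m)
        # decode the linear index of an unordered pair {i < j}
        i = (np.floor((np.sqrt(8 * idx.astype(float) + 1) + 1) / 2)).astype(np.int64)
        # fix rare off-by-one from float sqrt at large indices
        i = np.where(i * (i - 1) // 2 > idx, i - 1, i)
        i = np.where((i + 1) * i // 2 <= idx, i + 1, i)
        j = (idx - i * (i - 1) // 2).astype(np.int64)
        g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(i.tolist(), j.tolist()))
    assert g.number_of_edges() == m
    return g


def ba_graph(n: int, seed_size: int = 5, edges_per_step: int = 7,
             rng: np.random.Generator | int | None = None) -> nx.MultiDiGraph:
    """Directed preferential-attachment graph, edges new -> existing.

    Because no edge ever points from an older node to a newer one, the
    only cycles live inside the seed clique: the largest strongly
    connected component is exactly the ``seed_size`` seed nodes for every
    ``n`` and every RNG state.
    """
    ModelSpec(model="ba_directed", n=n, seed_size=seed_size,
              edges_per_step=edges_per_step).validate()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g = nx.MultiDiGraph()
    g.add_nodes_from(range(n))
    deg = np.zeros(n, dtype=np.int64)
    for u in range(seed_size):
        for v in range(seed_size):
            if u != v:
                g.add_edge(u, v)
    deg[:seed_size] = 2 * (seed_size - 1)
    for new in range(seed_size, n):
        weights = deg[:new].astype(float)
        p = weights / weights.sum()
        if new >= edges_per_step:
            targets = rng.choice(new, size=edges_per_step, replace=False, p=p)
        else:  # exact-count mode: repeat targets so every step adds the same
            targets = rng.choice(new, size=edges_per_step, replace=True, p=p)
        for t in targets:
            g.add_edge(new, int(t))
            deg[int(t)] += 1
        deg[new] += edges_per_step
    expected = seed_size * (seed_size - 1) + edges_per_step * (n - seed_size)
    assert g.number_of_edges() == expected
    return g


def ws_graph(n: int, k: int = 6, p: float = 0.45,
             rng: np.random.Generator | int | None = None) -> nx.Graph:
    """Watts–Strogatz small-world graph (ring lattice + rewiring)."""
    ModelSpec(model="ws", n=n, k=k, p=p).validate()
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(2**31))
    else:
        seed = int(rng or 0)
    return nx.watts_strogatz_graph(n, k, p, seed=seed)


def make_model(spec: ModelSpec):
    """Dispatch a :class:`ModelSpec` to its generator."""
    spec.validate()
    if spec.model == "er_directed":
        return er_graph(spec.n, spec.m, directed=True, rng=spec.seed)
    if spec.model == "er_undirected":
        return er_graph(spec.n, spec.m, directed=False, rng=spec.seed)
    if spec.model == "ba_directed":
        return ba_graph(spec.n, spec.seed_size, spec.edges_per_step, rng=spec.seed)
    return ws_graph(spec.n, spec.k, spec.p, rng=spec.seed)
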