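"""Bow-Tie decomposition of a directed graph.

Every node is assigned to exactly one of six reachability classes around
the largest strongly connected component (Broder-style semantics):

- ``SCC``: the largest strongly connected component;
- ``IN``: nodes outside SCC that can reach it;
- ``OUT``: nodes outside SCC reachable from it;
- ``TUBES``: remaining nodes on a directed IN -> OUT path avoiding SCC;
- ``TENDRILS``: remaining nodes reachable from IN or reaching OUT (but
  not both);
- ``DISC``: everything else, including smaller strongly connected
  components that satisfy none of the above.

Self-loops are ignored. Ties for the largest SCC break toward the
component containing the lexicographically smallest node id, making the
decomposition deterministic.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx

__all__ = ["BowTieDecomposition", "bowtie_decompose", "bowtie_table", "CLASSES"]

CLASSES = ("SCC", "IN", "OUT", "TENDRILS", "TUBES", "DISC")


@dataclass
class BowTieDecomposition:
    classes: dict  # node -> class label
    counts: dict[str, int]
    fractions: dict[str, float]  # percentages summing to 100

    def nodes_in(self, label: str) -> set:
        return {n for n, c in self.classes.items() if c == label}


def _adjacency(g) -> tuple[dict, dict]:
    fwd: dict = {n: set() for n in g.nodes}
    rev: dict = {n: set() for n in g.nodes}
    for u, v in g.edges():
        if u == v:
            continue
        fwd[u].add(v)
        rev[v].add(u)
    return fwd, rev


def _multi_source_reachable(adj: dict, sources) -> set:
    seen = set(sources)
    queue = deque(seen)
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return seen


def bowtie_decompose(g) -> BowTieDecomposition:
    """Partition the nodes of a directed graph into the six Bow-Tie
    classes; fractions are percentages of the node count."""
    if g.number_of_nodes() == 0:
        raise ValueError("bowtie_decompose needs at least one node")
    if not g.is_directed():
        raise ValueError("bowtie_decompose needs a directed graph")
    fwd, rev = _adjacency(g)
    sccs = list(nx.strongly_connected_components(g))
    max_size = max(len(c) for c in sccs)
    ties = [c for c in sccs if len(c) == max_size]
    scc = min(ties, key=lambda c: min(str(n) for n in c))

    from_scc = _multi_source_reachable(fwd, scc)
    to_scc = _multi_source_reachable(rev, scc)
    out_set = from_scc - scc
    in_set = to_scc - scc

    classes = {n: "DISC" for n in g.nodes}
    for n in scc:
        classes[n] = "SCC"
    for n in in_set:
        classes[n] = "IN"
    for n in out_set:
        classes[n] = "OUT"

    rest = set(g.nodes) - scc - in_set - out_set
    # A path from IN to a rest node cannot traverse SCC (the node would be
    # in OUT), so unrestricted traversals suffice.
    from_in = _multi_source_reachable(fwd, in_set) - in_set if in_set else set()
    to_out = _multi_source_reachable(rev, out_set) - out_set if out_set else set()
    for n in rest:
        f = n in from_in
        t = n in to_out
        if f and t:
            classes[n] = "TUBES"
        elif f or t:
            classes[n] = "TENDRILS"

    n_total = g.number_of_nodes()
    counts = {c: 0 for c in CLASSES}
    for c in classes.values():
        counts[c] += 1
    fractions = {c: 100.0 * counts[c] / n_total for c in CLASSES}
    return BowTieDecomposition(classes=classes, counts=counts, fractions=fractions)


def bowtie_table(decompositions: dict, include_reference: bool = True):
    """Class-percentage comparison table (one column per network).

    ``decompositions`` maps a network name to a
    :class:`BowTieDecomposition`. With ``include_reference``, published
    reference columns for networks this package cannot recompute
    (Myspace, a Java forum, the Web graph) are appended for side-by-side
    reading.
    """
    import pandas as pd

    from .reference import BOWTIE_REFERENCE_COLUMNS

    data = {name: [d.fractions[c] for c in CLASSES] for name, d in decompositions.items()}
    if include_reference:
        for name, col in BOWTIE_REFERENCE_COLUMNS.items():
            data[name] = [col[c] for c in CLASSES]
    return pd.DataFrame(data, index=list(CLASSES))
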