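"""Reply-network construction.

Three rules turn a threaded corpus into a directed conversation multigraph
with self-loops (one edge per message, replier -> addressee):

1. opening a thread adds a self-loop at the initiator;
2. a message with no explicit target adds an edge to the thread initiator
   (a self-loop when the initiator posts it);
3. a message replying to a specific message adds an edge to that message's
   author (a self-loop when replying to oneself).

The undirected "friend" projection keeps one edge per member pair that
ever exchanged messages, dropping direction, multiplicity and self-loops.
"""

from __future__ import annotations

import networkx as nx

from .corpus import CorpusFormatError, ForumCorpus

__all__ = [
    "build_conversation_graph",
    "strip_self_loops",
    "to_friend_graph",
    "self_loop_census",
    "write_edgelist",
    "read_edgelist",
]

#: edge-kind attribute values
OPENING = "opening"
TO_INITIATOR = "to_initiator"
TO_MESSAGE = "to_message"


def build_conversation_graph(corpus: ForumCorpus) -> nx.MultiDiGraph:
    """One directed edge per message; nodes are members who posted.

    Edges carry ``message_id``, ``thread_id`` and ``kind`` in
    {``opening``, ``to_initiator``, ``to_message``}; the total edge count
    equals the corpus message count.
    """
    g = nx.MultiDiGraph()
    for thread in corpus.threads:
        authors = {m.message_id: m.author for m in thread.messages}
        for pos, msg in enumerate(thread.messages):
            if msg.reply_to is None:
                target = msg.author if pos == 0 else thread.initiator
                kind = OPENING if pos == 0 else TO_INITIATOR
            else:
                if msg.reply_to not in authors:
                    raise CorpusFormatError(
                        f"message {msg.message_id}: reply_to outside thread"
                        f" {thread.thread_id}"
                    )
                target = authors[msg.reply_to]
                kind = TO_MESSAGE
            g.add_edge(
                msg.author,
                target,
                message_id=msg.message_id,
                thread_id=thread.thread_id,
                kind=kind,
            )
    return g


def self_loop_census(g: nx.MultiDiGraph) -> dict[str, int]:
    """Self-loop counts by provenance.

    ``opening`` loops mark thread initiations; ``untargeted`` loops are
    initiators posting into their own thread without naming a target;
    ``self_reply`` loops are explicit replies to one's own message. The
    three provenances are reported separately rather than folded into one
    number.
    """
    census = {"opening": 0, "untargeted": 0, "self_reply": 0}
    for u, v, data in g.edges(data=True):
        if u != v:
            continue
        if data.get("kind") == OPENING:
            census["opening"] += 1
        elif data.get("kind") == TO_INITIATOR:
            census["untargeted"] += 1
        else:
            census["self_reply"] += 1
    return census


def strip_self_loops(g: nx.MultiDiGraph) -> nx.MultiDiGraph:
    """Copy of ``g`` without self-loops.

    The removed count is recorded in ``graph['removed_self_loops']``;
    structure-level metrics are computed on this stripped graph.
    """
    out = g.copy()
    loops = list(nx.selfloop_edges(out, keys=True))
    out.remove_edges_from(loops)
    out.graph["removed_self_loops"] = len(loops)
    return out


def to_friend_graph(g: nx.MultiDiGraph | nx.DiGraph) -> nx.Graph:
    """Undirected simple projection: direction, multiplicity and
    self-loops discarded. Idempotent."""
    friend = nx.Graph()
    friend.add_nodes_from(g.nodes)
    friend.add_edges_from((u, v) for u, v in g.edges() if u != v)
    return friend


def write_edgelist(g, path) -> None:
    """Weighted edge list ``source<TAB>target<TAB>multiplicity``."""
    mult: dict[tuple, int] = {}
    for u, v in g.edges():
        mult[(u, v)] = mult.get((u, v), 0) + 1
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# directed={int(g.is_directed())}\n")
        for (u, v), w in sorted(mult.items()):
            fh.write(f"{u}\t{v}\t{w}\n")


def read_edgelist(path):
    """Read a weighted edge list written by :func:`write_edgelist`."""
    directed = True
    edges = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "directed=" in line:
                    directed = line.split("directed=")[1].strip() == "1"
                continue
            if not line:
                continue
            u, v, w = line.split("\t")
            edges.append((u, v, int(w)))
    g = nx.MultiDiGraph() if directed else nx.MultiGraph()
    for u, v, w in edges:
        for _ in range(w):
            g.add_edge(u, v)
    return g
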