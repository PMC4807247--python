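"""Joining topology and language at the member level.

Builds the 19-column member feature table (6 topological + 13 linguistic
properties), runs the Spearman rank-correlation matrix over it
(pairwise-complete, average ranks on ties), compares positive vs negative
affect rates among members who use both, and computes binned mean
("convergence") curves of a linguistic property over a topological one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import ForumCorpus
from .lexicon import Lexicon, member_profiles
from .netmetrics import betweenness, degree_records, per_node_shortest_path
from .netbuild import to_friend_graph

__all__ = [
    "TOPOLOGICAL_COLUMNS",
    "LINGUISTIC_COLUMNS",
    "member_feature_table",
    "spearman_matrix",
    "affect_comparison",
    "binned_mean_curve",
]

TOPOLOGICAL_COLUMNS = (
    "in_degree",
    "out_degree",
    "n_threads_created",
    "avg_shortest_path",
    "betweenness",
    "clustering",
)
LINGUISTIC_COLUMNS = (
    "word_count",
    "function",
    "social",
    "affective",
    "cognitive",
    "perceptual",
    "biological",
    "relativity",
    "positive",
    "negative",
    "first_person",
    "second_person",
    "third_person",
)


def member_feature_table(
    corpus: ForumCorpus, graph, lexicon: Lexicon
) -> pd.DataFrame:
    """One row per member with available text; 19 feature columns.

    ``graph`` is the conversation multigraph built from the same corpus
    (self-loops intact -- they carry the threads-created count; they are
    stripped internally for path metrics). Members whose node reaches no
    other node get ``NaN`` average shortest path, never zero.
    """
    import networkx as nx

    profiles = member_profiles(corpus, lexicon)
    missing = set(profiles) - set(graph.nodes)
    if missing:
        raise ValueError(
            f"member universe mismatch: {len(missing)} profiled members "
            f"missing from the graph (e.g. {sorted(missing)[:3]})"
        )
    recs = {r.node: r for r in degree_records(graph)}
    stripped = nx.MultiDiGraph(
        (u, v, d) for u, v, d in graph.edges(data=True) if u != v
    )
    stripped.add_nodes_from(graph.nodes)
    asp = per_node_shortest_path(stripped)
    btw = betweenness(stripped)
    clu = {
        n: v
        for n, v in nx.clustering(to_friend_graph(stripped)).items()
    }

    rows = {}
    for member, prof in profiles.items():
        rec = recs[member]
        rates = prof.rates
        rows[member] = {
            "in_degree": rec.in_degree,
            "out_degree": rec.out_degree,
            "n_threads_created": rec.n_threads_created,
            "avg_shortest_path": asp[member],
            "betweenness": btw[member],
            "clustering": clu[member],
            "word_count": prof.word_count,
            **{c: rates[c] for c in LINGUISTIC_COLUMNS if c != "word_count"},
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return table[list(TOPOLOGICAL_COLUMNS) + list(LINGUISTIC_COLUMNS)]


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(rank-correlation matrix, pairwise sample sizes).

    Pairwise-complete observations; average ranks on ties. A pair with
    fewer than 3 complete rows, or a constant column, yields ``NaN``
    (flagged undefined, never forced to a number).
    """
    cols = table.columns
    notna = table.notna()
    n = pd.DataFrame(
        notna.T.astype(int) @ notna.astype(int), index=cols, columns=cols
    )
    corr = table.corr(method="spearman", min_periods=3)
    # pandas leaves constant columns as NaN already; enforce unit diagonal
    # only where the column is non-constant and observed
    for c in cols:
        vals = table[c].dropna()
        if len(vals) >= 1 and vals.nunique() > 1:
            corr.loc[c, c] = 1.0
    return corr, n


@dataclass
class AffectComparison:
    """Negative-vs-positive occurrence-rate comparison among members who
    use both polarities. ``t`` statistics are for negative minus positive;
    both the unequal-variance (Welch, the headline) and pooled-variance
    conventions are reported."""

    n: int
    mean_positive: float
    sd_positive: float
    mean_negative: float
    sd_negative: float
    t_welch: float
    df_welch: float
    p_welch: float
    t_pooled: float
    df_pooled: float
    p_pooled: float


def affect_comparison(table_or_profiles) -> AffectComparison:
    """Two-sample comparison of negative vs positive affect rates.

    Accepts the member feature table (uses its ``positive``/``negative``
    columns) or an iterable of linguistic profiles. Only members with
    strictly positive rates in both polarities enter.
    """
    if isinstance(table_or_profiles, pd.DataFrame):
        pos = table_or_profiles["positive"].to_numpy(float)
        neg = table_or_profiles["negative"].to_numpy(float)
    else:
        profs = list(table_or_profiles)
        pos = np.array([p.rate("positive") for p in profs])
        neg = np.array([p.rate("negative") for p in profs])
    both = (pos > 0) & (neg > 0)
    pos, neg = pos[both], neg[both]
    if pos.size < 2:
        raise ValueError("affect comparison needs >= 2 members using both")
    welch = stats.ttest_ind(neg, pos, equal_var=False)
    pooled = stats.ttest_ind(neg, pos, equal_var=True)
    return AffectComparison(
        n=int(pos.size),
        mean_positive=float(pos.mean()),
        sd_positive=float(pos.std(ddof=1)),
        mean_negative=float(neg.mean()),
        sd_negative=float(neg.std(ddof=1)),
        t_welch=float(welch.statistic),
        df_welch=float(welch.df),
        p_welch=float(welch.pvalue),
        t_pooled=float(pooled.statistic),
        df_pooled=float(2 * pos.size - 2),
        p_pooled=float(pooled.pvalue),
    )


def binned_mean_curve(
    x, y, n_bins: int = 20, log_x: bool = False
) -> pd.DataFrame:
    """Equal-occupancy binned mean of ``y`` over ``x``.

    Heavy-tailed topological properties make equal-width bins degenerate,
    so bins hold (near-)equal numbers of points; ``log_x`` log-transforms
    ``x`` first (requires positive values; a rank-based quantity like the
    bin assignment is unchanged, but reported bin centers then live on the
    log scale's antilog). Returns a frame with per-bin ``x_mean``,
    ``y_mean``, ``count``, plus curve-level attrs: ``turn_bin`` (argmax of
    the bin means), ``increasing_prefix`` and ``decreasing_suffix``
    (lengths of the monotone non-decreasing prefix / non-increasing suffix
    of the bin means) -- an operational two-phase segmentation of
    convergence curves.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} paired finite points")
    if log_x and not np.all(x > 0):
        raise ValueError("log_x requires strictly positive x")
    xs = np.log(x) if log_x else x
    order = np.argsort(xs, kind="mergesort")
    chunks = np.array_split(order, n_bins)
    rows = []
    for chunk in chunks:
        rows.append(
            {
                "x_mean": float(np.exp(xs[chunk].mean())) if log_x else float(x[chunk].mean()),
                "y_mean": float(y[chunk].mean()),
                "count": int(chunk.size),
            }
        )
    curve = pd.DataFrame(rows)
    means = curve["y_mean"].to_numpy()
    inc = 1
    while inc < len(means) and means[inc] >= means[inc - 1]:
        inc += 1
    dec = 1
    while dec < len(means) and means[-dec - 1] >= means[-dec]:
        dec += 1
    curve.attrs["turn_bin"] = int(np.argmax(means))
    curve.attrs["increasing_prefix"] = int(inc)
    curve.attrs["decreasing_suffix"] = int(dec)
    return curve
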