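"""Published reference values carried as documented constants.

The original Douban MDD-group dataset behind these numbers is not
redistributable, and the comparison columns (Myspace, MedHelp, a Java
developer forum, the Web graph) come from third-party studies. None of
these values is recomputed by this package; they exist so that tables
produced from synthetic or user-supplied corpora can be read side by side
with the published ones.
"""

from __future__ import annotations

# --- observed MDD-group corpus scale ---------------------------------------
MDD_MEMBERS = 5050
MDD_THREADS = 3700
MDD_MESSAGES = 40357
MDD_MAX_THREAD_PARTICIPANTS = 276
MDD_MEMBERS_WITH_TEXT = 5013  # 37 deleted accounts lack message text
MDD_THREADS_WITH_TEXT = 3565

# --- linguistic worked-example constants ------------------------------------
MDD_TOTAL_WORDS = 2_281_678
MDD_TAGGED_WORDS = 1_707_151
MDD_TAG_RATE_PCT = 74.82  # = 100 * 1,707,151 / 2,281,678

#: members using negative-only / positive-only / both / neither affect
#: words, out of the 5013 members with text.
MDD_AFFECT_COUNTS = {
    "negative_only": 595,
    "positive_only": 553,
    "both": 2933,
    "neither": 932,
}
MDD_AFFECT_PCT = {
    "negative_only": 11.87,
    "positive_only": 11.03,
    "both": 58.51,
    "neither": 18.59,
}

#: affect occurrence rates among members using both polarities
MDD_POSITIVE_MEAN, MDD_POSITIVE_SD = 4.06, 2.67
MDD_NEGATIVE_MEAN, MDD_NEGATIVE_SD = 4.48, 2.99

# --- network structure constants --------------------------------------------
MDD_NONLOOP_EDGES = 36_657
MDD_FRIEND_EDGES = 17_401
MDD_WEAK_COMPONENTS = 162
MDD_LARGEST_COMPONENT_NODES = 4883  # table variant reports 4881
MDD_ZERO_IN_DEGREE = 1820
MDD_RECIPROCITY_1E2 = 34.0
MDD_CLUSTERING_1E2 = 4.47
MDD_ASP = 4.11
MDD_DIAMETER = 10
MDD_POWERLAW_IN = 2.13
MDD_POWERLAW_OUT = 2.20
MDD_SCC_PCT = 54.53

#: Published Bow-Tie columns (percent per class) that this package never
#: recomputes. The Java-forum study defines edge direction opposite to the
#: reply -> addressee convention used here, so its IN and OUT read swapped.
BOWTIE_REFERENCE_COLUMNS = {
    "MDD (published)": {
        "SCC": 54.53, "IN": 29.27, "OUT": 7.80,
        "TENDRILS": 4.22, "TUBES": 0.04, "DISC": 4.22,
    },
    "Myspace": {
        "SCC": 1.17, "IN": 0.0, "OUT": 81.50,
        "TENDRILS": 0.027, "TUBES": 0.0, "DISC": 17.30,
    },
    "Java forum": {
        "SCC": 12.30, "IN": 54.90, "OUT": 13.00,
        "TENDRILS": 17.50, "TUBES": 0.40, "DISC": 1.90,
    },
    "Web": {
        "SCC": 27.70, "IN": 21.20, "OUT": 21.20,
        "TENDRILS": 21.50, "TUBES": 0.40, "DISC": 8.00,
    },
}

#: Published metric-table columns for the networks not recomputed here.
METRIC_REFERENCE_COLUMNS = {
    "Myspace": {
        "type": "directed", "nodes": 36_459, "edges": 80_675,
        "density_1e5": 6.07, "diameter": 11, "reciprocity_1e2": 1.45,
        "clustering_1e2": 0.031, "avg_shortest_path": 5.14,
        "powerlaw_in": 2.65, "powerlaw_out": 1.99,
    },
    "MedHelp": {
        "type": "undirected", "nodes": 30_915, "edges": 113_273,
        "density_1e5": 23.7, "clustering_1e2": 3.1,
        "avg_shortest_path": 3.81, "powerlaw": 2.12,
    },
}
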