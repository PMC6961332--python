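"""Brute-force Steiner-tree oracle shared by the network tests."""

import itertools
import math

import networkx as nx


def steiner_optimum(graph, seeds):
    """Minimum total edge length of a connected subgraph spanning seeds.

    Enumerates every node superset of the seeds and takes the minimum
    spanning tree of the induced subgraph; feasible for <= 10 nodes.
    """
    G = graph.graph
    others = [n for n in G.nodes if n not in seeds]
    best = math.inf
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            nodes = set(seeds) | set(extra)
            H = G.subgraph(nodes)
            if len(H) and nx.is_connected(H):
                T = nx.minimum_spanning_tree(H, weight="length")
                best = min(best, sum(d["length"]
                                     for _, _, d in T.edges(data=True)))
    return best
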