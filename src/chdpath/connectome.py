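"""Biological distances and subnetworks on a confidence-weighted interactome.

The biological distance between two genes is the weighted sum of direct
distances along the shortest path connecting them in the protein-protein
interaction graph, where the direct distance of an edge is the reciprocal
of its interaction confidence (a 0.8-confidence edge has length 1.25). A
gene's "connectome" is every gene reachable from it, ranked by distance;
membership in the closest 1% is treated as significant proximity
(empirical p <= 0.01).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _edge_length(confidence: float, mode: str) -> float:
    if mode == "reciprocal":
        return 1.0 / confidence
    if mode == "neglog":
        return -math.log(confidence)
    raise ValueError(f"unknown edge length mode {mode!r}")


class PpiGraph:
    """Undirected confidence-weighted interactome.

    Edge confidences lie in (0, 1]; STRING-style integer scores (0-1000)
    are rescaled on ingest. Shortest-path edge lengths are 1/confidence by
    default (``length_mode='neglog'`` gives multiplicative confidences).
    """

    def __init__(self, length_mode: str = "reciprocal"):
        self.graph = nx.Graph()
        self.length_mode = length_mode

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]],
                   length_mode: str = "reciprocal") -> "PpiGraph":
        self = cls(length_mode=length_mode)
        for a, b, conf in edges:
            if a == b:
                logger.warning("dropping self-loop on %s", a)
                continue
            if not 0 < conf <= 1:
                raise ValueError(
                    f"confidence for ({a},{b}) outside (0,1]: {conf}")
            self.graph.add_edge(a, b, confidence=float(conf),
                                length=_edge_length(conf, length_mode))
        return self

    @classmethod
    def from_tsv(cls, path: str | Path,
                 length_mode: str = "reciprocal") -> "PpiGraph":
        """Read a gene_a / gene_b / confidence TSV.

        The confidence scale (0-1 vs STRING 0-1000) is auto-detected from
        the maximum value.
        """
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns[:3])
        conf = df[cols[2]].astype(float)
        if conf.max() > 1:
            conf = conf / 1000.0
        return cls.from_edges(
            zip(df[cols[0]].astype(str), df[cols[1]].astype(str), conf),
            length_mode=length_mode)

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(
            (min(a, b), max(a, b), d["confidence"])
            for a, b, d in self.graph.edges(data=True))
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]).to_csv(
            path, sep="\t", index=False)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def threshold(self, confidence_floor: float) -> "PpiGraph":
        """Subgraph of edges with confidence strictly above the floor."""
        out = PpiGraph(length_mode=self.length_mode)
        out.graph.add_nodes_from(self.graph.nodes)
        out.graph.add_edges_from(
            (a, b, d) for a, b, d in self.graph.edges(data=True)
            if d["confidence"] > confidence_floor)
        return out

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass
class ConnectomeResult:
    """A candidate-known gene pair with its shortest biological route."""

    gene_a: str
    gene_b: str
    distance: float
    route: list[str] = field(default_factory=list)
    degrees_of_separation: int = 0
    percentile_p: float | None = None
    route_str: str = ""


def format_route(graph: PpiGraph, path: Sequence[str]) -> str:
    """Render a route as ``A[1.77]B[1.25]C`` with per-edge direct distances."""
    if not path:
        return ""
    parts = [path[0]]
    for a, b in zip(path, path[1:]):
        parts.append(f"[{graph.graph[a][b]['length']:.2f}]{b}")
    return "".join(parts)


def biological_distance(a: str, b: str, graph: PpiGraph) -> ConnectomeResult:
    """Weighted shortest-path distance and route between two genes.

    A disconnected pair gets an infinite distance and an empty route.
    """
    G = graph.graph
    if a not in G or b not in G:
        raise KeyError(f"gene not in graph: {a if a not in G else b}")
    if a == b:
        return ConnectomeResult(a, b, 0.0, [a], 0, route_str=a)
    try:
        dist, path = nx.single_source_dijkstra(G, a, target=b, weight="length")
    except nx.NetworkXNoPath:
        return ConnectomeResult(a, b, math.inf, [], 0)
    return ConnectomeResult(a, b, float(dist), path, len(path) - 1,
                            route_str=format_route(graph, path))


def connectome_rank(
    a: str, targets: Iterable[str], graph: PpiGraph, top_fraction: float = 0.01
) -> pd.DataFrame:
    """Every gene reachable from ``a`` ranked by biological distance.

    Percentile p is rank / reachable-count, with tied distances sharing
    the maximal rank of the tied block; rows with percentile <= the top
    fraction are flagged as significantly proximal.
    """
    lengths = nx.single_source_dijkstra_path_length(
        graph.graph, a, weight="length")
    lengths.pop(a, None)
    if not lengths:
        return pd.DataFrame(columns=[
            "gene", "distance", "rank", "percentile_p", "top", "is_target"])
    df = (
        pd.DataFrame({"gene": list(lengths), "distance": list(lengths.values())})
        .sort_values(["distance", "gene"], kind="mergesort")
        .reset_index(drop=True)
    )
    df["rank"] = df["distance"].rank(method="max").astype(int)
    df["percentile_p"] = df["rank"] / len(df)
    df["top"] = df["percentile_p"] <= top_fraction
    targets = set(targets)
    df["is_target"] = df["gene"].isin(targets)
    return df


def top1_connectome(a: str, graph: PpiGraph,
                    top_fraction: float = 0.01) -> set[str]:
    """Genes in the closest ``top_fraction`` of ``a``'s connectome."""
    df = connectome_rank(a, (), graph, top_fraction)
    return set(df.loc[df["top"], "gene"])


def closest_known(candidate: str, known: Iterable[str],
                  graph: PpiGraph) -> ConnectomeResult:
    """The known disease gene nearest to a candidate, with its route.

    Ties are broken lexicographically; if no known gene is reachable a
    sentinel row with infinite distance is returned. A candidate that is
    itself known resolves to itself at distance 0.
    """
    known = sorted(set(known))
    if not known:
        raise ValueError("known gene set is empty")
    if candidate in known:
        return biological_distance(candidate, candidate, graph)
    lengths = nx.single_source_dijkstra_path_length(
        graph.graph, candidate, weight="length")
    reachable = [(lengths[g], g) for g in known if g in lengths]
    if not reachable:
        return ConnectomeResult(candidate, "", math.inf, [], 0)
    dist, best = min(reachable)
    res = biological_distance(candidate, best, graph)
    # report known -> candidate orientation as in the published table
    route = list(reversed(res.route))
    res = ConnectomeResult(candidate, best, res.distance, route,
                           res.degrees_of_separation,
                           route_str=format_route(graph, route))
    rank_df = connectome_rank(candidate, [best], graph)
    row = rank_df[rank_df["gene"] == best]
    if not row.empty:
        res.percentile_p = float(row["percentile_p"].iloc[0])
    return res


@dataclass
class Subnetwork:
    """A connected subgraph spanning the retained seed genes."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    focus_genes: list[str]
    known_count: int
    dropped_seeds: list[str]

    @property
    def node_set(self) -> set[str]:
        return set(self.nodes)

    def to_sif(self, path: str | Path) -> None:
        pd.DataFrame(self.edges, columns=["gene_a", "gene_b", "confidence"]
                     ).to_csv(path, sep="\t", index=False)


def minimum_subnetwork(
    seeds: Iterable[str],
    graph: PpiGraph,
    confidence_floor: float = 0.9,
    known: Iterable[str] = (),
) -> Subnetwork:
    """Steiner-style minimum connected subnetwork over the seed genes.

    Edges at or below the confidence floor are removed first. The
    subnetwork grows greedily: starting from the lexicographically first
    seed of the component holding the most seeds, the nearest unconnected
    seed is joined to the growing tree via its shortest path (the
    classical 2-approximation of the Steiner tree). Seeds unreachable from
    that component are excluded and reported.
    """
    G = graph.threshold(confidence_floor).graph
    seeds = sorted(set(seeds))
    present = [s for s in seeds if s in G]
    if not present:
        raise ValueError("no seed gene present after confidence filtering")

    comp_of = {}
    for comp in nx.connected_components(G):
        for node in comp:
            comp_of[node] = comp
    # component holding the most seeds; ties -> smallest member seed
    candidates = {}
    for s in present:
        comp = comp_of[s]
        key = min(comp)
        entry = candidates.setdefault(key, [0, s, comp])
        entry[0] += 1
        entry[1] = min(entry[1], s)
    best_comp = sorted(candidates.values(), key=lambda e: (-e[0], e[1]))[0][2]
    in_comp = [s for s in present if s in best_comp]
    dropped = [s for s in seeds if s not in in_comp]
    if dropped:
        logger.warning("dropping %d seeds outside the chosen component",
                       len(dropped))

    tree_nodes: set[str] = {in_comp[0]}
    tree_edges: set[tuple[str, str]] = set()
    remaining = set(in_comp[1:])
    while remaining:
        dist, paths = nx.multi_source_dijkstra(G, tree_nodes, weight="length")
        target = min(remaining, key=lambda s: (dist[s], s))
        path = paths[target]
        tree_nodes.update(path)
        tree_edges.update(
            (min(u, v), max(u, v)) for u, v in zip(path, path[1:]))
        remaining -= tree_nodes

    nodes = sorted(tree_nodes)
    edges = sorted((a, b, G[a][b]["confidence"]) for a, b in tree_edges)
    known = set(known)
    return Subnetwork(
        nodes=nodes,
        edges=edges,
        focus_genes=[s for s in in_comp],
        known_count=len(known & tree_nodes),
        dropped_seeds=dropped,
    )


def mean_distance_to_set(
    candidates: Iterable[str],
    known: Iterable[str],
    graph: PpiGraph,
    include_self: bool = False,
) -> pd.DataFrame:
    """Mean biological distance from each candidate to the known gene set.

    Unreachable pairs are excluded (counted in ``n_unreachable``); a
    candidate in the known set excludes its own zero self-distance unless
    ``include_self``. Candidates unreachable from every known gene are
    omitted from the table.
    """
    known = sorted(set(known))
    candidates = sorted(set(candidates))
    if not known or not candidates:
        raise ValueError("candidate and known sets must be non-empty")
    rows = []
    for cand in candidates:
        if cand not in graph:
            continue
        lengths = nx.single_source_dijkstra_path_length(
            graph.graph, cand, weight="length")
        targets = [g for g in known if include_self or g != cand]
        dists = [lengths[g] for g in targets if g in lengths]
        n_unreachable = len(targets) - len(dists)
        if not dists:
            logger.warning("%s unreachable from every known gene", cand)
            continue
        rows.append({
            "gene": cand,
            "mean_distance": float(np.mean(dists)),
            "n_known_used": len(dists),
            "n_unreachable": n_unreachable,
        })
    return pd.DataFrame(rows, columns=[
        "gene", "mean_distance", "n_known_used", "n_unreachable"])


# ---------------------------------------------------------------------------
# UPGMA


def _fmt(x: float) -> str:
    return format(round(x, 12), ".12g")


def upgma_tree(labels: Sequence[str], matrix) -> str:
    """UPGMA agglomeration of a distance matrix into a Newick tree.

    The matrix must be symmetric with a zero diagonal. At every step the
    pair of clusters with the smallest average distance merges; ties are
    broken by lexicographic cluster label (the smallest leaf in the
    cluster), making the output deterministic. The result is ultrametric:
    leaf-to-root heights are equal and node heights are half the merge
    distance.
    """
    D = np.asarray(matrix, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("matrix shape does not match labels")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(set(labels)) != n:
        raise ValueError("duplicate labels")
    if n == 1:
        return f"{labels[0]};"

    # cluster state: label -> (size, newick, height)
    clusters = {lab: (1, str(lab), 0.0) for lab in labels}
    dist = {
        frozenset((labels[i], labels[j])): D[i, j]
        for i in range(n) for j in range(i + 1, n)
    }
    while len(clusters) > 1:
        pair = min(
            dist, key=lambda fs: (dist[fs], tuple(sorted(fs))))
        a, b = sorted(pair)
        d = dist.pop(pair)
        size_a, nw_a, h_a = clusters.pop(a)
        size_b, nw_b, h_b = clusters.pop(b)
        h = d / 2.0
        newick = f"({nw_a}:{_fmt(h - h_a)},{nw_b}:{_fmt(h - h_b)})"
        for other in list(clusters):
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((a, other))] = (
                (size_a * da + size_b * db) / (size_a + size_b))
        clusters[a] = (size_a + size_b, newick, h)
    (_, newick, _), = clusters.values()
    return newick + ";"


def distance_matrix(genes: Sequence[str], graph: PpiGraph,
                    unreachable: float | None = None) -> pd.DataFrame:
    """All-pairs biological distance matrix over ``genes``.

    Unreachable pairs get ``unreachable`` (default: twice the largest
    finite distance, so UPGMA places them in an outgroup).
    """
    genes = list(genes)
    mat = np.zeros((len(genes), len(genes)))
    for i, g in enumerate(genes):
        if g not in graph:
            mat[i, :] = math.inf
            mat[:, i] = math.inf
            mat[i, i] = 0.0
            continue
        lengths = nx.single_source_dijkstra_path_length(
            graph.graph, g, weight="length")
        for j, h in enumerate(genes):
            if j == i:
                continue
            mat[i, j] = lengths.get(h, math.inf)
    finite = mat[np.isfinite(mat)]
    cap = unreachable if unreachable is not None else (
        2.0 * finite.max() if finite.size else 1.0)
    mat[~np.isfinite(mat)] = cap
    mat = (mat + mat.T) / 2.0  # symmetrize (caps may differ per side)
    return pd.DataFrame(mat, index=genes, columns=genes)
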