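"""Two-stage clustering of a thresholded co-complex network.

The scored network is first thresholded on the classifier confidence.
Dense overlapping regions are then found by greedy cohesiveness growth in
the style of ClusterOne: a candidate cluster C on a weighted graph has
cohesiveness

    f(C) = w_in / (w_in + w_bound + penalty * |C|)

where ``w_in`` is the total weight of edges inside C and ``w_bound`` the
total weight of edges crossing its boundary. Each dense region is then
re-clustered by Markov clustering (MCL) on its induced subgraph, followed
by the post-filters: members without a sufficiently strong within-cluster
edge are removed, undersized and oversized clusters are dropped, and
duplicates collapsed. A parameter sweep evaluates every combination of
(threshold, density, overlap, inflation) against training complexes with
the weighted k-clique metric, and six cluster sets ranked by precision
are merged into a tiered union.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .goldstd import Complex, ComplexSet
from .kclique import clique_pr
from .pairs import Pair

TIER_LABELS = {
    1: "Extremely High",
    2: "Very High",
    3: "High",
    4: "Moderately High",
    5: "Medium High",
    6: "Medium",
}


@dataclass(frozen=True)
class ClusteringParams:
    score_threshold: float = 0.5
    clusterone_density: float = 0.3
    clusterone_overlap: float = 0.7
    mcl_inflation: float = 2.0
    clusterone_penalty: float = 2.0
    max_cluster_size: int = 100

    def __post_init__(self):
        if not 0 <= self.score_threshold <= 1:
            raise ValueError("score_threshold must be in [0, 1]")
        if not 0 <= self.clusterone_density <= 1:
            raise ValueError("density must be in [0, 1]")
        if not 0 < self.clusterone_overlap <= 1:
            raise ValueError("overlap must be in (0, 1]")
        if self.mcl_inflation < 1:
            raise ValueError("inflation must be >= 1")


def threshold_network(scored: Dict[Pair, float], cutoff: float) -> nx.Graph:
    """Build a weighted graph from pairs scoring at or above ``cutoff``.

    Isolated nodes cannot arise since nodes only enter via retained edges.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    g = nx.Graph()
    for (a, b), s in scored.items():
        if a != b and s >= cutoff:
            g.add_edge(a, b, weight=float(s))
    return g


# ---------------------------------------------------------------------------
# ClusterOne-style greedy cohesiveness growth


def cohesiveness(graph: nx.Graph, cluster: Set, penalty: float) -> float:
    """f(C) = w_in / (w_in + w_bound + penalty * |C|)."""
    w_in = 0.0
    w_bound = 0.0
    for u in cluster:
        for v, data in graph[u].items():
            w = data.get("weight", 1.0)
            if v in cluster:
                if u < v:
                    w_in += w
            else:
                w_bound += w
    denom = w_in + w_bound + penalty * len(cluster)
    return w_in / denom if denom > 0 else 0.0


def _grow_from_seed(graph: nx.Graph, seed_node, penalty: float) -> Set:
    cluster = {seed_node}
    current = cohesiveness(graph, cluster, penalty)
    while True:
        best_gain = 0.0
        best_move = None
        boundary = sorted(
            {v for u in cluster for v in graph[u] if v not in cluster}
        )
        for v in boundary:
            f = cohesiveness(graph, cluster | {v}, penalty)
            if f - current > best_gain + 1e-12:
                best_gain = f - current
                best_move = ("add", v)
        if len(cluster) > 1:
            for v in sorted(cluster):
                f = cohesiveness(graph, cluster - {v}, penalty)
                if f - current > best_gain + 1e-12:
                    best_gain = f - current
                    best_move = ("remove", v)
        if best_move is None:
            return cluster
        op, v = best_move
        cluster = cluster | {v} if op == "add" else cluster - {v}
        current += best_gain


def grow_clusters(graph: nx.Graph, penalty: float = 2.0) -> List[Set]:
    """Greedy cohesiveness growth from every not-yet-covered seed.

    Seeds are taken in order of decreasing weighted degree (ties by node
    id); each grown cluster is a local optimum of the cohesiveness under
    single-node add/remove moves.
    """
    degree = dict(graph.degree(weight="weight"))
    seeds = sorted(graph.nodes, key=lambda v: (-degree[v], str(v)))
    covered: Set = set()
    clusters: List[Set] = []
    for s in seeds:
        if s in covered:
            continue
        c = _grow_from_seed(graph, s, penalty)
        covered |= c
        if c not in clusters:
            clusters.append(c)
    return clusters


def match_coefficient(a: Set, b: Set) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter * inter / (len(a) * len(b))


def _merge_overlapping(clusters: List[Set], max_overlap: float) -> List[Set]:
    clusters = [set(c) for c in clusters]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if match_coefficient(clusters[i], clusters[j]) >= max_overlap:
                    clusters[i] = clusters[i] | clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return clusters


def graph_density(graph: nx.Graph, cluster: Set) -> float:
    """Internal edge weight over the number of possible internal pairs."""
    n = len(cluster)
    if n < 2:
        return 0.0
    w_in = sum(
        d.get("weight", 1.0)
        for u, v, d in graph.subgraph(cluster).edges(data=True)
    )
    return w_in / (n * (n - 1) / 2)


def cluster_one(
    graph: nx.Graph,
    density: float = 0.3,
    max_overlap: float = 0.7,
    penalty: float = 2.0,
    min_size: int = 3,
) -> List[Set]:
    """Dense overlapping regions by greedy cohesiveness growth.

    Grown clusters are merged while their match coefficient
    |A∩B|^2 / (|A||B|) is at or above ``max_overlap``; clusters smaller
    than ``min_size`` or below the ``density`` floor are discarded.
    """
    if graph.number_of_nodes() == 0:
        return []
    grown = grow_clusters(graph, penalty)
    merged = _merge_overlapping(grown, max_overlap)
    kept = [
        c
        for c in merged
        if len(c) >= min_size and graph_density(graph, c) >= density
    ]
    return sorted(kept, key=lambda c: (-len(c), sorted(c)))


# ---------------------------------------------------------------------------
# Markov clustering


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-8,
    self_loops: str = "max",
) -> List[Set]:
    """Markov clustering on a weighted graph.

    Self-loops are added (weight = the node's maximum incident edge weight,
    or 1 for ``self_loops='unit'``), columns normalized, and expansion
    (matrix squaring) alternated with inflation (elementwise power then
    column renormalization) until the column-wise change drops below
    ``tol`` or ``max_iter`` is hit. Clusters are the connected components
    of the non-zero structure of the attractor matrix, so flow can never
    join disconnected components of the input.
    """
    if inflation < 1:
        raise ValueError("inflation must be >= 1")
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    if n == 0:
        return []
    if n == 1:
        return [set(nodes)]
    M = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    if self_loops == "max":
        loops = np.maximum(M.max(axis=1), 1e-12)
    else:
        loops = np.ones(n)
    np.fill_diagonal(M, loops)
    M = M / M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    structure = nx.Graph()
    structure.add_nodes_from(range(n))
    rows, cols = np.nonzero(M > prune)
    structure.add_edges_from(
        (int(i), int(j)) for i, j in zip(rows, cols) if i != j
    )
    clusters = [
        {nodes[i] for i in comp} for comp in nx.connected_components(structure)
    ]
    clusters.sort(key=lambda c: (-len(c), sorted(map(str, c))))
    if not converged:
        import warnings

        warnings.warn("MCL did not converge within max_iter; returning current state")
    return clusters


# ---------------------------------------------------------------------------
# Pipeline


def two_stage_cluster(
    scored: Dict[Pair, float], params: ClusteringParams
) -> ComplexSet:
    """Threshold, grow dense regions, re-cluster each with MCL, post-filter.

    Post-filters follow the published pipeline: cluster members lacking
    any within-cluster edge with weight strictly greater than the score
    threshold are removed; clusters reduced below 2 members, or larger
    than ``max_cluster_size``, are dropped; duplicate member-sets
    collapse to one.
    """
    graph = threshold_network(scored, params.score_threshold)
    regions = cluster_one(
        graph,
        density=params.clusterone_density,
        max_overlap=params.clusterone_overlap,
        penalty=params.clusterone_penalty,
    )
    raw: List[Set] = []
    for region in regions:
        sub = graph.subgraph(region)
        raw.extend(mcl(sub, inflation=params.mcl_inflation))

    kept: List[frozenset] = []
    for cluster in raw:
        sub = graph.subgraph(cluster)
        members = {
            u
            for u in cluster
            if any(
                d.get("weight", 0.0) > params.score_threshold
                for _, _, d in sub.edges(u, data=True)
            )
        }
        if 2 <= len(members) <= params.max_cluster_size:
            kept.append(frozenset(members))
    unique = sorted(set(kept), key=lambda c: (-len(c), sorted(c)))
    return ComplexSet(
        [Complex(f"clust{i:05d}", c) for i, c in enumerate(unique)]
    )


def parameter_grid(
    score_thresholds: Sequence[float],
    overlaps: Sequence[float],
    densities: Sequence[float],
    inflations: Sequence[float],
    **common,
) -> List[ClusteringParams]:
    """Cartesian product of the four swept parameter lists."""
    return [
        ClusteringParams(
            score_threshold=t,
            clusterone_overlap=o,
            clusterone_density=d,
            mcl_inflation=i,
            **common,
        )
        for t, o, d, i in itertools.product(
            score_thresholds, overlaps, densities, inflations
        )
    ]


def parameter_sweep(
    scored: Dict[Pair, float],
    grid: Sequence[ClusteringParams],
    train_gold: ComplexSet,
    sample_limit: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster under every parameter combination and evaluate against gold.

    One row per combination with weighted k-clique precision/recall, F1,
    and the cluster/protein counts; deterministic given the seed.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    for params in grid:
        clusters = two_stage_cluster(scored, params)
        if len(clusters) == 0:
            p_w = r_w = f1 = 0.0
        else:
            ev = clique_pr(clusters, train_gold, sample_limit=sample_limit, seed=seed)
            p_w, r_w, f1 = ev.precision_weighted, ev.recall_weighted, ev.f1
        rows.append(
            {
                "score_threshold": params.score_threshold,
                "clusterone_density": params.clusterone_density,
                "clusterone_overlap": params.clusterone_overlap,
                "mcl_inflation": params.mcl_inflation,
                "precision_weighted": p_w,
                "recall_weighted": r_w,
                "f1": f1,
                "n_clusters": len(clusters),
                "n_proteins": len(clusters.proteins()),
            }
        )
    return pd.DataFrame(rows)


def pareto_frontier(sweep: pd.DataFrame, n_sets: int = 6) -> pd.DataFrame:
    """Up to ``n_sets`` non-dominated sweep rows along the P/R frontier.

    A row is kept when no other row has both higher weighted precision and
    higher weighted recall. The frontier is then thinned to ``n_sets``
    rows spread evenly along it, sorted by precision descending — ready to
    feed ``assemble_tiers`` after re-clustering.
    """
    pts = sweep[["precision_weighted", "recall_weighted"]].to_numpy()
    keep = []
    for i, (p, r) in enumerate(pts):
        dominated = np.any(
            (pts[:, 0] > p) & (pts[:, 1] > r)
        )
        if not dominated and (p > 0 or r > 0):
            keep.append(i)
    frontier = sweep.iloc[keep].drop_duplicates(
        subset=["precision_weighted", "recall_weighted"]
    )
    frontier = frontier.sort_values(
        ["precision_weighted", "recall_weighted"], ascending=[False, True]
    )
    if len(frontier) > n_sets:
        picks = np.unique(
            np.linspace(0, len(frontier) - 1, n_sets).round().astype(int)
        )
        frontier = frontier.iloc[picks]
    return frontier.reset_index(drop=True)


def assemble_tiers(ranked_sets: Sequence[ComplexSet]) -> ComplexSet:
    """Union of up to six cluster sets ranked by precision into one tiered map.

    ``ranked_sets[0]`` is the highest-precision ("Extremely High") set.
    Each unique member-set in the union carries the best (lowest-numbered)
    tier in which it appears.
    """
    if not ranked_sets or len(ranked_sets) > 6:
        raise ValueError("expected between 1 and 6 ranked cluster sets")
    best_tier: Dict[frozenset, int] = {}
    for tier, cset in enumerate(ranked_sets, start=1):
        for c in cset:
            if c.members not in best_tier:
                best_tier[c.members] = tier
    ordered = sorted(best_tier.items(), key=lambda kv: (kv[1], -len(kv[0]), sorted(kv[0])))
    return ComplexSet(
        [
            Complex(f"union{i:05d}", members, tier)
            for i, (members, tier) in enumerate(ordered)
        ]
    )
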