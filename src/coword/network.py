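"""Keyword co-occurrence networks, their statistics, and the knowledge map.

Nodes are keywords; an edge joins two keywords with weight equal to the
number of papers containing both. Five descriptive statistics summarise a
network: edge count, average weighted degree, density, modularity of a
detected community partition, and average clustering coefficient.

The "average weighted degree" here follows the co-word-analysis usage —
the mean co-occurrence weight over edges present in the network (pairs
A-B=10, B-C=20, A-C absent average to 15) — not the graph-theoretic mean
node strength. Both readings are available via ``mode``.

The knowledge map is a 2-D embedding in which distance between keywords
reflects their association strength and a 0-2 density score colours each
keyword from blue (sparse neighbourhood) through green to red (dense,
well-connected neighbourhood). The layout is a deliberately simple stress
majorization (SMACOF); VOSviewer-compatible files are exported so the map
can also be rebuilt in that tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
from networkx.algorithms import community as nx_community

from coword.ingest import keyword_occurrences
from coword.records import PaperRecord


def build_graph(
    records: list[PaperRecord],
    bin_: tuple[int, int] | None = None,
    min_keyword_frequency: int = 1,
) -> nx.Graph:
    """Weighted co-occurrence graph of a (time-binned) corpus.

    Each paper adds +1 to the weight of every unordered pair of its
    distinct keywords. Keywords occurring in fewer than
    ``min_keyword_frequency`` papers (within the bin) are excluded before
    pairing. No self-loops can arise since within-paper keywords are
    distinct after cleaning.
    """
    if bin_ is not None:
        records = [r for r in records if bin_[0] <= r.year <= bin_[1]]
    counts = keyword_occurrences(records)
    keep = {kw for kw, c in counts.items() if c >= min_keyword_frequency}
    g = nx.Graph()
    if bin_ is not None:
        g.graph["bin"] = f"{bin_[0]}-{bin_[1]}"  # scalar: survives GraphML export
    g.add_nodes_from(sorted(keep))
    for rec in records:
        kws = sorted(set(rec.keywords) & keep)
        for a, b in combinations(kws, 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def avg_weighted_degree(graph: nx.Graph, mode: str = "edge_mean") -> float:
    """Average weighted degree of the network.

    ``mode="edge_mean"`` (default): mean edge weight over edges present.
    ``mode="node_mean"``: mean node strength (sum of incident weights),
    the graph-theoretic reading. NaN when the graph has no edges.
    """
    m = graph.number_of_edges()
    if m == 0:
        return math.nan
    total_weight = sum(d["weight"] for _, _, d in graph.edges(data=True))
    if mode == "edge_mean":
        return total_weight / m
    if mode == "node_mean":
        return 2.0 * total_weight / graph.number_of_nodes()
    raise ValueError("mode must be 'edge_mean' or 'node_mean'")


def density(graph: nx.Graph) -> float:
    """Unweighted density: edges present over all possible pairs (NaN for n<2)."""
    n = graph.number_of_nodes()
    if n < 2:
        return math.nan
    return graph.number_of_edges() / (n * (n - 1) / 2)


def avg_clustering(graph: nx.Graph, count_low_degree_as_zero: bool = True) -> float:
    """Mean local clustering coefficient (unweighted triangles).

    Nodes of degree < 2 contribute 0 by default (the convention of common
    network tools); with ``count_low_degree_as_zero=False`` they are
    excluded from the mean instead.
    """
    if graph.number_of_nodes() == 0:
        return math.nan
    local = nx.clustering(graph)  # networkx already assigns 0 to deg<2 nodes
    if count_low_degree_as_zero:
        return float(np.mean(list(local.values())))
    vals = [c for node, c in local.items() if graph.degree(node) >= 2]
    return float(np.mean(vals)) if vals else math.nan


def _exact_max_modularity(graph: nx.Graph) -> list[set]:
    """Globally optimal modularity partition by subset dynamic programming.

    Modularity is additive over communities, so the best partition of a
    node set S is the best split into a community T (containing S's first
    node, to avoid double counting) and the best partition of S\\T. The DP
    visits all 3^n (subset, submask) pairs — exact and fast for small n.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        i, j = nodes.index(u), nodes.index(v)
        w[i, j] = w[j, i] = d["weight"]
    total = w.sum() / 2.0
    strength = w.sum(axis=1)

    def q_of(mask: int) -> float:
        members = [i for i in range(n) if mask >> i & 1]
        w_c = sum(w[i, j] for ai, i in enumerate(members) for j in members[ai + 1:])
        s_c = sum(strength[i] for i in members)
        return w_c / total - (s_c / (2 * total)) ** 2

    q_cache = {}
    best: dict[int, tuple[float, int]] = {0: (0.0, 0)}
    for mask in range(1, 1 << n):
        low = mask & -mask
        rest = mask ^ low
        best_q, best_t = -math.inf, mask
        sub = rest
        while True:  # all submasks T = low | sub, sub ⊆ rest
            t = low | sub
            if t not in q_cache:
                q_cache[t] = q_of(t)
            q = q_cache[t] + best[mask ^ t][0]
            if q > best_q:
                best_q, best_t = q, t
            if sub == 0:
                break
            sub = (sub - 1) & rest
        best[mask] = (best_q, best_t)

    parts = []
    mask = (1 << n) - 1
    while mask:
        t = best[mask][1]
        parts.append({nodes[i] for i in range(n) if t >> i & 1})
        mask ^= t
    return parts


def detect_communities(
    graph: nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
    restarts: int = 10,
    exact_max_nodes: int = 8,
):
    """Community partition maximising weighted modularity.

    Graphs with at most ``exact_max_nodes`` nodes are solved exactly
    (modularity's greedy landscapes mislead heuristics precisely at tiny
    sizes, where exact search is cheap). Larger graphs use Louvain-style
    greedy moves; the visit order depends on the seed, so the run is
    restarted ``restarts`` times from seeds derived from ``seed`` and the
    highest-modularity partition is kept. Deterministic given ``seed``.
    Returns a list of node sets; the empty graph yields an empty partition.
    """
    if graph.number_of_nodes() == 0:
        return []
    if graph.number_of_edges() == 0:
        return [{node} for node in graph.nodes]
    if graph.number_of_nodes() <= exact_max_nodes and resolution == 1.0:
        return _exact_max_modularity(graph)
    best, best_q = None, -math.inf
    for r in range(max(restarts, 1)):
        part = list(
            nx_community.louvain_communities(
                graph, weight="weight", resolution=resolution, seed=seed + r
            )
        )
        q = modularity(graph, part)
        if q > best_q:
            best, best_q = part, q
    return best


def modularity(graph: nx.Graph, partition) -> float:
    """Newman weighted modularity Q of a partition.

    ``Q = sum_c [ W_c/W - (S_c / 2W)^2 ]`` with W the total edge weight,
    W_c the intra-community weight and S_c the community's weighted-degree
    sum. The single whole-graph community gives Q = 0.
    """
    return float(nx_community.modularity(graph, partition, weight="weight"))


@dataclass
class NetworkStats:
    """The five per-bin co-occurrence network statistics."""

    n_nodes: int
    n_edges: int
    avg_weighted_degree: float
    density: float
    modularity: float
    avg_clustering: float


def network_stats(graph: nx.Graph, seed: int = 0) -> NetworkStats:
    if graph.number_of_edges() > 0:
        q = modularity(graph, detect_communities(graph, seed=seed))
    else:
        q = math.nan
    return NetworkStats(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        avg_weighted_degree=avg_weighted_degree(graph),
        density=density(graph),
        modularity=q,
        avg_clustering=avg_clustering(graph),
    )


# ---------------------------------------------------------------------------
# Knowledge map


@dataclass
class MapLayout:
    """2-D positions plus the 0-2 density colour score per keyword."""

    positions: dict[str, tuple[float, float]] = field(default_factory=dict)
    density_score: dict[str, float] = field(default_factory=dict)
    color: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def association_strength(graph: nx.Graph) -> dict[tuple[str, str], float]:
    """Association strength a_ij = 2W * w_ij / (s_i * s_j) per edge."""
    total = sum(d["weight"] for _, _, d in graph.edges(data=True))
    strength = dict(graph.degree(weight="weight"))
    out = {}
    for u, v, d in graph.edges(data=True):
        out[(u, v)] = 2.0 * total * d["weight"] / (strength[u] * strength[v])
    return out


def _target_distances(graph: nx.Graph, nodes: list[str]) -> np.ndarray:
    """All-pairs target distances: shortest paths over 1/a_ij edge lengths;
    disconnected pairs sit at 1.5x the largest finite distance."""
    assoc = association_strength(graph)
    h = nx.Graph()
    h.add_nodes_from(nodes)
    for (u, v), a in assoc.items():
        h.add_edge(u, v, length=1.0 / a)
    idx = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    delta = np.full((n, n), np.inf)
    np.fill_diagonal(delta, 0.0)
    for src, dists in nx.all_pairs_dijkstra_path_length(h, weight="length"):
        for dst, d in dists.items():
            delta[idx[src], idx[dst]] = d
    finite = delta[np.isfinite(delta) & (delta > 0)]
    fill = 1.5 * finite.max() if finite.size else 1.0
    delta[~np.isfinite(delta)] = fill
    return delta


def _smacof(delta: np.ndarray, seed: int, max_iter: int = 500, tol: float = 1e-12) -> np.ndarray:
    """Uniform-weight stress majorization (Guttman transform) in 2-D."""
    n = delta.shape[0]
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 2)) * delta[delta > 0].mean()
    prev_stress = np.inf
    for _ in range(max_iter):
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, 1.0)
        ratio = delta / dist
        np.fill_diagonal(ratio, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
        np.fill_diagonal(dist, 0.0)
        stress = ((dist - delta) ** 2).sum() / 2.0
        if prev_stress - stress < tol * max(prev_stress, 1.0):
            break
        prev_stress = stress
    return x - x.mean(axis=0)


def layout_map(graph: nx.Graph, seed: int = 0) -> MapLayout:
    """Lay out the knowledge map and score keyword density on [0, 2].

    Positions minimise a stress between embedded distances and inverse
    association strengths (shortest-path completed), via iterative
    majorization from a seeded random start. The density score is a
    Gaussian-kernel density at each keyword, with neighbours weighted by
    their total co-occurrence strength, min-max scaled to [0, 2]; colours
    interpolate blue (0) -> green (1) -> red (2).
    """
    nodes = sorted(graph.nodes)
    layout = MapLayout()
    if not nodes:
        return layout
    if len(nodes) == 1:
        layout.positions[nodes[0]] = (0.0, 0.0)
        layout.density_score[nodes[0]] = 0.0
        layout.color[nodes[0]] = _score_to_rgb(0.0)
        return layout

    delta = _target_distances(graph, nodes)
    x = _smacof(delta, seed=seed)

    strength = dict(graph.degree(weight="weight"))
    s = np.array([strength[node] for node in nodes], dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    # bandwidth: mean nearest-neighbour distance of the embedding
    masked = dist + np.eye(len(nodes)) * dist.max()
    h = max(float(masked.min(axis=1).mean()), 1e-9)
    kernel = np.exp(-(dist**2) / (2 * h * h))
    np.fill_diagonal(kernel, 0.0)
    raw = kernel @ s
    lo, hi = raw.min(), raw.max()
    scores = np.zeros_like(raw) if hi == lo else 2.0 * (raw - lo) / (hi - lo)

    for i, node in enumerate(nodes):
        layout.positions[node] = (float(x[i, 0]), float(x[i, 1]))
        layout.density_score[node] = float(scores[i])
        layout.color[node] = _score_to_rgb(float(scores[i]))
    return layout


def _score_to_rgb(score: float) -> tuple[float, float, float]:
    """Blue (0) -> green (1) -> red (2) linear interpolation."""
    score = min(max(score, 0.0), 2.0)
    if score <= 1.0:
        return (0.0, score, 1.0 - score)
    return (score - 1.0, 2.0 - score, 0.0)


# ---------------------------------------------------------------------------
# Exchange-format export


def export_graph(
    graph: nx.Graph,
    layout: MapLayout | None,
    formats: list[str],
    out_prefix: str | Path,
) -> list[Path]:
    """Write the graph (and layout) in exchange formats.

    ``formats`` may contain ``graphml`` (round-trips exactly via networkx),
    ``pajek`` (a ``.net`` file) and ``vos`` (VOSviewer-compatible
    tab-separated map + network files). Returns the written paths.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for fmt in formats:
        if fmt == "graphml":
            path = out_prefix.with_suffix(".graphml")
            nx.write_graphml(graph, path)
            written.append(path)
        elif fmt == "pajek":
            path = out_prefix.with_suffix(".net")
            _write_pajek(graph, layout, path)
            written.append(path)
        elif fmt == "vos":
            written.extend(_write_vosviewer(graph, layout, out_prefix))
        else:
            raise ValueError(f"unknown export format {fmt!r}")
    return written


def _write_pajek(graph: nx.Graph, layout: MapLayout | None, path: Path) -> None:
    nodes = sorted(graph.nodes)
    idx = {node: i + 1 for i, node in enumerate(nodes)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for node in nodes:
            if layout and node in layout.positions:
                px, py = layout.positions[node]
                fh.write(f'{idx[node]} "{node}" {px:.6f} {py:.6f}\n')
            else:
                fh.write(f'{idx[node]} "{node}"\n')
        fh.write("*Edges\n")
        for u, v, d in graph.edges(data=True):
            a, b = sorted((idx[u], idx[v]))
            fh.write(f"{a} {b} {d['weight']}\n")


def _write_vosviewer(graph: nx.Graph, layout: MapLayout | None, out_prefix: Path) -> list[Path]:
    nodes = sorted(graph.nodes)
    idx = {node: i + 1 for i, node in enumerate(nodes)}
    map_path = out_prefix.parent / (out_prefix.name + "_map.txt")
    net_path = out_prefix.parent / (out_prefix.name + "_network.txt")
    with open(map_path, "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\tx\ty\tscore\n")
        for node in nodes:
            px, py = (layout.positions.get(node, (0.0, 0.0)) if layout else (0.0, 0.0))
            score = layout.density_score.get(node, 0.0) if layout else 0.0
            fh.write(f"{idx[node]}\t{node}\t{px:.6f}\t{py:.6f}\t{score:.4f}\n")
    with open(net_path, "w", encoding="utf-8") as fh:
        for u, v, d in graph.edges(data=True):
            a, b = sorted((idx[u], idx[v]))
            fh.write(f"{a}\t{b}\t{d['weight']}\n")
    return [map_path, net_path]


def render_map(graph: nx.Graph, layout: MapLayout, path: str | Path) -> Path:
    """Render the knowledge map to PNG/SVG via matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    strength = dict(graph.degree(weight="weight"))
    max_s = max(strength.values()) if strength else 1
    for u, v, d in graph.edges(data=True):
        xs = [layout.positions[u][0], layout.positions[v][0]]
        ys = [layout.positions[u][1], layout.positions[v][1]]
        ax.plot(xs, ys, color="0.8", lw=0.5, zorder=1)
    for node, (px, py) in layout.positions.items():
        size = 30 + 170 * strength.get(node, 0) / max_s
        ax.scatter([px], [py], s=size, color=layout.color[node], zorder=2)
        ax.annotate(node, (px, py), fontsize=6, ha="center", va="bottom")
    ax.set_axis_off()
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
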