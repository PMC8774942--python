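"""Integrated interactome construction and seed-gene subnetwork extraction.

Interaction edges from curated-database-style edge lists (BioGRID-tab-like,
STRING-link-like) are merged into one directed graph in which every
undirected interaction is stored as an arc pair — the representation used
by classic shortest-path tooling on symmetric interaction data.

The central operation is the *skeleton subnetwork*: for every unordered
pair of seed genes, Dijkstra shortest paths are computed on the full graph,
and the skeleton is the union of those paths (all tied minimum paths by
default, or one deterministic path per pair).  A direct-interaction view
(seed-induced subgraph) and node annotation (constraint, border class,
expression fill) support figure-style rendering and export to GraphML, SIF
and Cytoscape JSON.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .genesets import GeneSet
from .expression import map_color, to_hex, NEUTRAL_GREY

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionEdge",
    "NodeAnnotation",
    "SkeletonSubnetwork",
    "read_biogrid_like",
    "read_string_like",
    "read_annotations",
    "build_graph",
    "shortest_path_skeleton",
    "direct_subnet",
    "annotate_nodes",
    "connectivity_report",
    "export_graph",
    "import_graph",
]

_ORIGINS = ("biogrid_like", "string_like", "custom")


@dataclass(frozen=True)
class InteractionEdge:
    source: str
    target: str
    origin: str = "custom"
    confidence: Optional[float] = None  # STRING-style combined score, 0-1000

    def __post_init__(self) -> None:
        if self.origin not in _ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.confidence is not None and not (0 <= self.confidence <= 1000):
            raise ValueError(f"confidence out of [0,1000]: {self.confidence}")


@dataclass
class NodeAnnotation:
    """Per-gene display/constraint annotation.

    ``oe_lof`` is the gnomAD-style observed/expected loss-of-function ratio
    (low = intolerant to gene loss, drawn smallest); ``border_class`` marks
    why a gene is in the network (mutated in >= 2 cases, bone-related, or
    both); ``fill_logfc`` drives the red-yellow-blue expression fill.
    """

    gene: str
    oe_lof: Optional[float] = None
    constraint_outlier: bool = False
    border_class: str = "other"  # aff_mutated | bone_related | both | other
    fill_logfc: Optional[float] = None
    carriers: int = 0

    def __post_init__(self) -> None:
        if self.oe_lof is not None and self.oe_lof < 0:
            raise ValueError("oe_lof must be >= 0")
        if self.border_class not in ("aff_mutated", "bone_related", "both", "other"):
            raise ValueError(f"unknown border_class {self.border_class!r}")


@dataclass
class SkeletonSubnetwork:
    seed_genes: GeneSet
    graph: nx.DiGraph  # arcs of the subnetwork, weights copied from the full graph
    pair_distances: dict[frozenset, float]
    unreachable_pairs: list[frozenset]
    missing_seeds: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        return list(self.graph.edges)


# ---------------------------------------------------------------------------
# Edge-list readers
# ---------------------------------------------------------------------------

def read_biogrid_like(path: str | Path, col_a: int = 0, col_b: int = 1,
                      sep: str = "\t", skip_header: bool = True) -> list[InteractionEdge]:
    """BioGRID-tab-like TSV: symbol columns at configurable indices."""
    edges = []
    lines = Path(path).read_text().splitlines()
    if skip_header and lines:
        lines = lines[1:]
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split(sep)
        edges.append(InteractionEdge(source=parts[col_a].strip(),
                                     target=parts[col_b].strip(),
                                     origin="biogrid_like"))
    return edges


def read_string_like(path: str | Path) -> list[InteractionEdge]:
    """STRING-link-like whitespace table: protein1 protein2 combined_score."""
    edges = []
    lines = Path(path).read_text().splitlines()
    for ln, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "protein1":  # header
            continue
        if len(parts) < 3:
            raise ValueError(f"{path}: line {ln} needs protein1 protein2 combined_score")
        edges.append(InteractionEdge(source=parts[0], target=parts[1],
                                     origin="string_like", confidence=float(parts[2])))
    return edges


def read_annotations(path: str | Path) -> list[NodeAnnotation]:
    """Node annotation TSV: gene, oe_lof, constraint_outlier, border_class, carriers[, fill_logfc]."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}, keep_default_na=False)
    anns = []
    for row in df.to_dict("records"):
        anns.append(NodeAnnotation(
            gene=row["gene"],
            oe_lof=float(row["oe_lof"]) if str(row.get("oe_lof", "")) != "" else None,
            constraint_outlier=str(row.get("constraint_outlier", "")).lower() in ("1", "true", "yes"),
            border_class=row.get("border_class") or "other",
            fill_logfc=float(row["fill_logfc"]) if str(row.get("fill_logfc", "")) != "" else None,
            carriers=int(row["carriers"]) if str(row.get("carriers", "")) != "" else 0,
        ))
    return anns


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_graph(edges: Iterable[InteractionEdge], weight_mode: str = "unit") -> nx.DiGraph:
    """Merge undirected edges into a bidirected graph.

    Duplicate edges across origins collapse to one arc pair whose
    ``provenance`` is the union of origins.  ``weight_mode='unit'`` gives
    every arc weight 1; ``'string_confidence'`` maps a 0-1000 combined
    score to ``1 - confidence/1000`` clamped to [0.001, 1], so that
    high-confidence interactions are cheaper to traverse (edges without a
    score get weight 1).  Self-loops are dropped (counted in the log).
    """
    if weight_mode not in ("unit", "string_confidence"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    g = nx.DiGraph()
    n_self = 0
    for e in edges:
        if e.source == e.target:
            n_self += 1
            continue
        if weight_mode == "unit" or e.confidence is None:
            w = 1.0
        else:
            w = min(1.0, max(0.001, 1.0 - e.confidence / 1000.0))
        for u, v in ((e.source, e.target), (e.target, e.source)):
            if g.has_edge(u, v):
                g[u][v]["provenance"].add(e.origin)
                g[u][v]["weight"] = min(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w, provenance={e.origin})
    if n_self:
        logger.info("dropped %d self-loop edge(s)", n_self)
    return g


# ---------------------------------------------------------------------------
# Skeleton extraction
# ---------------------------------------------------------------------------

def _shortest_dag_members(g: nx.DiGraph, u: str, v: str):
    """Distance d(u,v) plus nodes/arcs lying on some minimum-weight u->v path.

    A node x is on a tied shortest path iff d(u,x) + d(x,v) == d(u,v); an
    arc (x,y) iff d(u,x) + w(x,y) + d(y,v) == d(u,v).  Distances-to-v come
    from Dijkstra on the reversed graph, so the construction is exact for
    any positive weights (up to floating tolerance).
    """
    du = nx.single_source_dijkstra_path_length(g, u, weight="weight")
    if v not in du:
        return None, set(), set()
    dv = nx.single_source_dijkstra_path_length(g.reverse(copy=False), v, weight="weight")
    d = du[v]
    tol = 1e-9 * max(1.0, d)
    nodes = {x for x in du if x in dv and abs(du[x] + dv[x] - d) <= tol}
    arcs = set()
    for x in nodes:
        for y in g.successors(x):
            if y in nodes and abs(du[x] + g[x][y]["weight"] + dv[y] - d) <= tol:
                arcs.add((x, y))
    return d, nodes, arcs


def _lexicographic_path(g: nx.DiGraph, u: str, v: str, nodes: set, dist_from_u: dict, d: float):
    """Walk the shortest-path DAG from u picking the smallest symbol at ties."""
    tol = 1e-9 * max(1.0, d)
    path = [u]
    x = u
    while x != v:
        nxt = sorted(
            y for y in g.successors(x)
            if y in nodes and abs(dist_from_u[x] + g[x][y]["weight"] - dist_from_u[y]) <= tol
            and dist_from_u[y] <= d + tol
        )
        x = nxt[0]
        path.append(x)
    return path


def shortest_path_skeleton(
    graph: nx.DiGraph,
    seeds: GeneSet,
    max_len: Optional[float] = None,
    ties: str = "all",
) -> SkeletonSubnetwork:
    """Union of pairwise seed shortest paths (Dijkstra) over the full graph.

    ``ties='all'`` includes every tied minimum path per seed pair (via the
    shortest-path predecessor DAG); ``ties='one'`` keeps a single
    deterministic path per pair with lexicographic tie-breaking.  Pairs
    farther apart than ``max_len`` — or disconnected — are listed in
    ``unreachable_pairs``.  Seeds absent from the graph are reported in
    ``missing_seeds`` and skipped.
    """
    if ties not in ("all", "one"):
        raise ValueError(f"unknown ties mode {ties!r}")
    if len(seeds) == 0:
        raise ValueError("seed set must be non-empty")
    present = [s for s in seeds.sorted() if graph.has_node(s)]
    missing = [s for s in seeds.sorted() if not graph.has_node(s)]
    if missing:
        logger.warning("seeds not in graph, skipped: %s", missing)

    sub = nx.DiGraph()
    sub.add_nodes_from(present)
    pair_distances: dict[frozenset, float] = {}
    unreachable: list[frozenset] = []

    for i, u in enumerate(present):
        for v in present[i + 1:]:
            pair = frozenset((u, v))
            d, nodes, arcs = _shortest_dag_members(graph, u, v)
            if d is None or (max_len is not None and d > max_len):
                unreachable.append(pair)
                continue
            pair_distances[pair] = d
            if ties == "all":
                keep_nodes, keep_arcs = nodes, arcs
            else:
                du = nx.single_source_dijkstra_path_length(graph, u, weight="weight")
                path = _lexicographic_path(graph, u, v, nodes, du, d)
                keep_nodes = set(path)
                keep_arcs = set(zip(path, path[1:]))
            sub.add_nodes_from(keep_nodes)
            for (x, y) in keep_arcs:
                sub.add_edge(x, y, **graph[x][y])
                # keep the skeleton symmetric where the full graph is
                if graph.has_edge(y, x):
                    sub.add_edge(y, x, **graph[y][x])
    return SkeletonSubnetwork(seed_genes=seeds, graph=sub,
                              pair_distances=pair_distances,
                              unreachable_pairs=unreachable,
                              missing_seeds=missing)


def direct_subnet(graph: nx.DiGraph, seeds: GeneSet) -> SkeletonSubnetwork:
    """Seed-induced subgraph: only direct seed-seed interactions are kept."""
    if len(seeds) == 0:
        raise ValueError("seed set must be non-empty")
    present = [s for s in seeds.sorted() if graph.has_node(s)]
    missing = [s for s in seeds.sorted() if not graph.has_node(s)]
    sub = nx.DiGraph()
    sub.add_nodes_from(present)
    pair_distances = {}
    for i, u in enumerate(present):
        for v in present[i + 1:]:
            if graph.has_edge(u, v):
                sub.add_edge(u, v, **graph[u][v])
                pair_distances[frozenset((u, v))] = graph[u][v]["weight"]
            if graph.has_edge(v, u):
                sub.add_edge(v, u, **graph[v][u])
    return SkeletonSubnetwork(seed_genes=seeds, graph=sub,
                              pair_distances=pair_distances,
                              unreachable_pairs=[], missing_seeds=missing)


# ---------------------------------------------------------------------------
# Annotation & reporting
# ---------------------------------------------------------------------------

def annotate_nodes(
    subnet: SkeletonSubnetwork,
    annotations: Sequence[NodeAnnotation],
    size_range: tuple[float, float] = (10.0, 50.0),
    color_cap: float = 1.0,
) -> SkeletonSubnetwork:
    """Attach display attributes to every subnetwork node (in place).

    Node size maps oe_lof clamped to [0, 2] linearly onto ``size_range``
    (absent -> midpoint); fill color comes from ``fill_logfc`` through the
    red-yellow-blue expression scale (absent -> neutral grey).  Unannotated
    nodes get defaults; duplicate annotations for one gene raise.
    """
    by_gene: dict[str, NodeAnnotation] = {}
    for a in annotations:
        key = a.gene.casefold()
        if key in by_gene:
            raise ValueError(f"duplicate annotation for gene {a.gene!r}")
        by_gene[key] = a
    lo, hi = size_range
    for node in subnet.graph.nodes:
        a = by_gene.get(str(node).casefold(), NodeAnnotation(gene=str(node)))
        if a.oe_lof is None:
            size = (lo + hi) / 2.0
        else:
            size = lo + (hi - lo) * min(2.0, max(0.0, a.oe_lof)) / 2.0
        fill = map_color(a.fill_logfc, cap=color_cap) if a.fill_logfc is not None else NEUTRAL_GREY
        subnet.graph.nodes[node].update(
            border_class=a.border_class,
            size=size,
            constraint_outlier=a.constraint_outlier,
            fill=to_hex(fill),
            carriers=a.carriers,
            is_seed=node in subnet.seed_genes,
        )
    return subnet


def _count_tied_paths(g: nx.DiGraph, u: str, v: str, nodes: set, du: dict, d: float) -> int:
    """Number of distinct minimum-weight u->v paths (DP over the tie DAG)."""
    tol = 1e-9 * max(1.0, d)
    order = sorted(nodes, key=lambda x: du[x])
    count = {x: 0 for x in order}
    count[u] = 1
    for x in order:
        for y in g.successors(x):
            if y in count and abs(du[x] + g[x][y]["weight"] - du[y]) <= tol:
                count[y] += count[x]
    return count[v]


def connectivity_report(subnet: SkeletonSubnetwork, graph: Optional[nx.DiGraph] = None) -> pd.DataFrame:
    """Per seed pair: distance, tied-path count, intermediate genes.

    Uses the full ``graph`` when given (exact tie counts); otherwise the
    skeleton's own arcs, which carry the same shortest-path structure.
    """
    g = graph if graph is not None else subnet.graph
    rows = []
    seeds = [s for s in subnet.seed_genes.sorted() if subnet.graph.has_node(s)]
    for i, u in enumerate(seeds):
        for v in seeds[i + 1:]:
            pair = frozenset((u, v))
            if pair not in subnet.pair_distances:
                rows.append({"seed_a": u, "seed_b": v, "distance": float("inf"),
                             "n_shortest_paths": 0, "intermediates": ""})
                continue
            d, nodes, _ = _shortest_dag_members(g, u, v)
            du = nx.single_source_dijkstra_path_length(g, u, weight="weight")
            n_paths = _count_tied_paths(g, u, v, nodes, du, d)
            inter = sorted(nodes - {u, v})
            rows.append({"seed_a": u, "seed_b": v, "distance": d,
                         "n_shortest_paths": n_paths,
                         "intermediates": ",".join(inter)})
    df = pd.DataFrame(rows, columns=["seed_a", "seed_b", "distance",
                                     "n_shortest_paths", "intermediates"])
    df.attrs["isolated_seeds"] = [
        s for s in seeds if subnet.graph.degree(s) == 0
    ]
    return df


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_graph(subnet: SkeletonSubnetwork, fmt: str, path: str | Path) -> None:
    """Serialize the (possibly annotated) subnetwork.

    GraphML and Cytoscape JSON are lossless for node/edge attributes and
    round-trip through :func:`import_graph`; SIF is the usual one line per
    undirected interaction.
    """
    path = Path(path)
    g = subnet.graph.copy()
    for _, _, data in g.edges(data=True):
        if isinstance(data.get("provenance"), set):
            data["provenance"] = ",".join(sorted(data["provenance"]))
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        seen = set()
        lines = []
        for u, v in sorted(g.edges):
            if (v, u) in seen:
                continue
            seen.add((u, v))
            lines.append(f"{u}\tinteracts\t{v}")
        for n in sorted(g.nodes):
            if g.degree(n) == 0:
                lines.append(str(n))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "cytoscape_json":
        data = nx.cytoscape_data(g)
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_graph(fmt: str, path: str | Path) -> nx.DiGraph:
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        g = nx.DiGraph(g)
        relabel = {n: str(n) for n in g.nodes}
        g = nx.relabel_nodes(g, relabel)
    elif fmt == "cytoscape_json":
        g = nx.cytoscape_graph(json.loads(path.read_text()))
        g = nx.DiGraph(g)
    else:
        raise ValueError(f"unknown import format {fmt!r}")
    for _, _, data in g.edges(data=True):
        if isinstance(data.get("provenance"), str):
            data["provenance"] = set(data["provenance"].split(","))
    return g
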