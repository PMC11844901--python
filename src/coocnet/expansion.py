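"""Clique selection, community detection, graphlet ranking, query planning.

The expansion step finds "information-dense" maximal cliques (Knet-significant
clusters of tightly co-occurring entities), partitions them into communities,
enumerates k-node community-connecting graphlets (trees with exactly one
crossing edge), ranks them by R = -log(prod W * prod w), and plans tours over
the community multigraph with Christofides' TSP approximation. Visited
graphlets become PubMed queries.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from statsmodels.stats.multitest import multipletests

from .exits import ExitCode, ExitSignal
from .genenorm import AliasLookup
from .knet import knet_permutation_pvalue, pairwise_distances


# ---------------------------------------------------------------------------
# Maximal cliques and the Knet clique test
# ---------------------------------------------------------------------------

def find_maximal_cliques(graph: nx.Graph) -> list[tuple[str, ...]]:
    """All maximal cliques of order >= 3, deterministically ordered."""
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph) if len(c) >= 3]
    return sorted(cliques)


@dataclass
class CliqueRecord:
    nodes: tuple[str, ...]
    auk: float
    p: float
    padj: float = float("nan")
    significant: bool = False


def knet_clique_test(
    graph: nx.Graph,
    cliques: list[tuple[str, ...]] | None = None,
    n_perm: int = 1000,
    fdr: float = 0.01,
    seed: int = 0,
    n_bins: int = 25,
) -> list[CliqueRecord]:
    """Score each maximal clique by the Knet AUK of its membership indicator.

    Distances are wt-weighted shortest paths; the permutation null shuffles
    the indicator over all network nodes. BH correction across cliques.
    """
    if cliques is None:
        cliques = find_maximal_cliques(graph)
    if not cliques:
        return []
    nodes, dist = pairwise_distances(graph, weight="wt")
    index = {n: i for i, n in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    records: list[CliqueRecord] = []
    for clique in cliques:
        weights = np.zeros(len(nodes))
        weights[[index[n] for n in clique]] = 1.0
        auk, p = knet_permutation_pvalue(dist, weights, n_perm=n_perm, rng=rng, n_bins=n_bins)
        records.append(CliqueRecord(nodes=clique, auk=auk, p=p))
    reject, padj, _, _ = multipletests([r.p for r in records], alpha=fdr, method="fdr_bh")
    for rec, rej, adj in zip(records, reject, padj):
        rec.padj = float(max(adj, rec.p))
        rec.significant = bool(rej)
    return records


def prune_to_significant_cliques(
    graph: nx.Graph, records: list[CliqueRecord]
) -> nx.Graph:
    """Induced subgraph on the union of significant-clique nodes.

    Raises ``ExitSignal(no_cliques_or_single_community)`` with fewer than two
    significant cliques.
    """
    significant = [r for r in records if r.significant]
    if len(significant) < 2:
        raise ExitSignal(
            ExitCode.NO_CLIQUES_OR_SINGLE_COMMUNITY,
            f"{len(significant)} significant clique(s)",
        )
    keep = sorted({n for r in significant for n in r.nodes})
    return graph.subgraph(keep).copy()


def detect_communities_C(pruned: nx.Graph, seed: int = 0) -> dict[str, int]:
    """Seeded w-weighted Leiden partition of the clique-pruned network C."""
    from .reconstruction import leiden_partition

    if pruned.number_of_nodes() == 0:
        raise ValueError("pruned network is empty")
    membership = leiden_partition(pruned, weight="w", seed=seed)
    if len(set(membership.values())) < 2:
        raise ExitSignal(
            ExitCode.NO_CLIQUES_OR_SINGLE_COMMUNITY,
            "a single community encompasses all nodes of C",
        )
    return membership


# ---------------------------------------------------------------------------
# Community-connecting graphlets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Graphlet:
    """k nodes, k-1 edges, spanning two communities via one crossing edge."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    communities: tuple[int, int]
    rank: float

    @property
    def crossing_pair(self) -> tuple[int, int]:
        return self.communities


def rank_graphlet(
    node_weights: dict[str, float], edge_weights: dict[tuple[str, str], float]
) -> float:
    """R = -log(prod of member W times prod of member edge w); smaller = closer."""
    product = 1.0
    for name, w in node_weights.items():
        if w <= 0:
            raise ValueError(f"non-positive node weight for {name!r}")
        product *= w
    for pair, w in edge_weights.items():
        if w <= 0:
            raise ValueError(f"non-positive edge weight for {pair!r}")
        product *= w
    return -float(np.log(product))


def _spanning_trees(subgraph: nx.Graph) -> list[tuple[tuple[str, str], ...]]:
    """All spanning trees of a tiny graph, as sorted edge tuples."""
    nodes = sorted(subgraph.nodes())
    if len(nodes) == 1:
        return [()]
    edges = sorted(tuple(sorted(e)) for e in subgraph.edges())
    trees = []
    for combo in itertools.combinations(edges, len(nodes) - 1):
        t = nx.Graph(combo)
        if t.number_of_nodes() == len(nodes) and nx.is_connected(t):
            trees.append(tuple(sorted(combo)))
    return trees


def enumerate_graphlets(
    graph: nx.Graph,
    partition: dict[str, int],
    k: int = 4,
    top_q: int = 15,
) -> list[Graphlet]:
    """All community-connecting graphlets of size k, for every community pair.

    For tractability candidates are restricted to the top_q highest-W nodes
    per community (ranking R favors high-W nodes, so generous top_q preserves
    the optimum). A graphlet's k-1 edges consist of a spanning tree inside
    each community side plus exactly one crossing edge.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    communities: dict[int, list[str]] = {}
    for node, comm in partition.items():
        communities.setdefault(comm, []).append(node)

    def top_nodes(comm: int) -> list[str]:
        members = communities[comm]
        ranked = sorted(
            members, key=lambda n: (-graph.nodes[n].get("W", 1.0), n)
        )
        return ranked[:top_q]

    graphlets: list[Graphlet] = []
    for ci, cj in itertools.combinations(sorted(communities), 2):
        cand_i = set(top_nodes(ci))
        cand_j = set(top_nodes(cj))
        crossing = []
        for a, b in graph.edges():
            pa, pb = partition.get(a), partition.get(b)
            if {pa, pb} != {ci, cj}:
                continue
            u, v = (a, b) if pa == ci else (b, a)
            if u in cand_i and v in cand_j:
                crossing.append((u, v))
        crossing.sort()
        for u, v in crossing:
            for size_i in range(1, k):
                size_j = k - size_i
                pool_i = sorted(cand_i - {u})
                pool_j = sorted(cand_j - {v})
                if size_i - 1 > len(pool_i) or size_j - 1 > len(pool_j):
                    continue
                for extra_i in itertools.combinations(pool_i, size_i - 1):
                    side_i = (u, *extra_i)
                    sub_i = graph.subgraph(side_i)
                    trees_i = _spanning_trees(sub_i)
                    if not trees_i:
                        continue
                    for extra_j in itertools.combinations(pool_j, size_j - 1):
                        side_j = (v, *extra_j)
                        trees_j = _spanning_trees(graph.subgraph(side_j))
                        if not trees_j:
                            continue
                        for ti in trees_i:
                            for tj in trees_j:
                                edges = tuple(
                                    sorted(ti + tj + (tuple(sorted((u, v))),))
                                )
                                nodes = tuple(sorted(side_i + side_j))
                                node_w = {
                                    n: graph.nodes[n].get("W", 1.0) for n in nodes
                                }
                                edge_w = {
                                    e: graph.edges[e].get("w", 1.0) for e in edges
                                }
                                graphlets.append(
                                    Graphlet(
                                        nodes=nodes,
                                        edges=edges,
                                        communities=(ci, cj),
                                        rank=rank_graphlet(node_w, edge_w),
                                    )
                                )
    # deduplicate identical (nodes, edges) combinations across crossing choices
    unique = {(g.nodes, g.edges, g.communities): g for g in graphlets}
    return sorted(unique.values(), key=lambda g: (g.communities, g.rank, g.nodes))


# ---------------------------------------------------------------------------
# TSP query planning over the community multigraph
# ---------------------------------------------------------------------------

@dataclass
class QueryPlan:
    """Graphlets selected per TSP attempt."""

    attempts: list[list[Graphlet]] = field(default_factory=list)

    @property
    def all_graphlets(self) -> list[Graphlet]:
        return [g for attempt in self.attempts for g in attempt]


def _min_rho_graph(graphlets: list[Graphlet]) -> nx.Graph:
    """Simple community graph keeping each pair's minimum-R graphlet."""
    h = nx.Graph()
    for g in graphlets:
        ci, cj = g.communities
        if not h.has_edge(ci, cj) or g.rank < h.edges[ci, cj]["rho"]:
            h.add_edge(ci, cj, rho=g.rank, graphlet=g)
    return h


def _drop_triangle_violators(h: nx.Graph) -> None:
    """Remove edges whose weight exceeds some two-hop alternative."""
    to_drop = []
    for ci, cj, data in h.edges(data=True):
        rho = data["rho"]
        for cz in h.nodes():
            if cz in (ci, cj):
                continue
            if h.has_edge(ci, cz) and h.has_edge(cz, cj):
                if h.edges[ci, cz]["rho"] + h.edges[cz, cj]["rho"] < rho:
                    to_drop.append((ci, cj))
                    break
    h.remove_edges_from(to_drop)


def _component_tour(h: nx.Graph, component: list) -> list[tuple]:
    """Christofides tour over the metric closure of one component."""
    if len(component) == 2:
        return [tuple(component)]
    lengths = dict(nx.all_pairs_dijkstra_path_length(h.subgraph(component), weight="rho"))
    complete = nx.Graph()
    for a, b in itertools.combinations(sorted(component), 2):
        complete.add_edge(a, b, weight=lengths[a][b])
    cycle = nx.approximation.christofides(complete, weight="weight")
    return [(cycle[i], cycle[i + 1]) for i in range(len(cycle) - 1)]


def plan_queries(graphlets: list[Graphlet], attempts: int = 2) -> QueryPlan:
    """Select community-connecting graphlets along TSP tours.

    Per attempt: keep each community pair's minimum-R graphlet, drop
    triangle-inequality violators, complete missing pairs through shortest
    paths, tour each connected component with Christofides, and collect the
    graphlets of the visited (expanded) edges. The next attempt excludes all
    previously used graphlet edges. Raises ``ExitSignal(no_connecting_path)``
    if the first attempt cannot construct any community-connecting tour.
    """
    if attempts < 1:
        raise ValueError("attempts must be >= 1")
    remaining = list(graphlets)
    plan = QueryPlan()
    for attempt in range(attempts):
        h = _min_rho_graph(remaining)
        _drop_triangle_violators(h)
        selected: list[Graphlet] = []
        seen: set[tuple] = set()
        for component in nx.connected_components(h):
            component = sorted(component)
            if len(component) < 2:
                continue
            lengths = dict(
                nx.all_pairs_dijkstra_path(h.subgraph(component), weight="rho")
            )
            for a, b in _component_tour(h, component):
                # expand a closure edge into its constituent real edges
                path = lengths[a][b]
                for x, y in zip(path, path[1:]):
                    g = h.edges[x, y]["graphlet"]
                    key = (g.nodes, g.edges)
                    if key not in seen:
                        seen.add(key)
                        selected.append(g)
        if attempt == 0 and not selected:
            raise ExitSignal(
                ExitCode.NO_CONNECTING_PATH, "no community-connecting tour exists"
            )
        if not selected:
            break
        plan.attempts.append(selected)
        used = {(g.nodes, g.edges) for g in selected}
        remaining = [g for g in remaining if (g.nodes, g.edges) not in used]
    return plan


# ---------------------------------------------------------------------------
# PubMed query grammar
# ---------------------------------------------------------------------------

def _quote(term: str) -> str:
    return '"' + term.replace('"', '\\"') + '"'


def build_pubmed_query(
    graphlet: Graphlet,
    lookup: AliasLookup,
    node_kinds: dict[str, str],
) -> str:
    """Render a graphlet as a PubMed query string.

    MeSH entities become ``"name"[MeSH Terms]``; gene entities become an
    OR-group of all their aliases tagged ``[Title/Abstract]``; groups are
    AND-joined and review articles are excluded.
    """
    groups: list[str] = []
    for node in graphlet.nodes:
        kind = node_kinds.get(node, "mesh")
        if kind == "mesh":
            groups.append(f"{_quote(node)}[MeSH Terms]")
        else:
            aliases = sorted(lookup.aliases_of(node))
            if not aliases:
                raise ValueError(f"gene {node!r} has no alias in the lookup table")
            ors = " OR ".join(f"{_quote(a)}[Title/Abstract]" for a in aliases)
            groups.append(f"({ors})")
    return " AND ".join(groups) + ' NOT "review"[Publication Type]'


_QUERY_TERM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"\[([^\]]+)\]')


def parse_pubmed_query(query: str) -> dict:
    """Round-trip parser for the emitted query grammar.

    Returns ``{"groups": [...], "not_review": bool}`` where each group is
    either ``("mesh", name)`` or ``("gene", [aliases...])``. Raises
    ``ValueError`` on strings outside the grammar.
    """
    not_review = False
    suffix = ' NOT "review"[Publication Type]'
    if query.endswith(suffix):
        not_review = True
        query = query[: -len(suffix)]
    groups = []
    for part in query.split(" AND "):
        part = part.strip()
        if part.startswith("(") and part.endswith(")"):
            inner = part[1:-1]
            aliases = []
            for alt in inner.split(" OR "):
                m = _QUERY_TERM_RE.fullmatch(alt.strip())
                if not m or m.group(2) != "Title/Abstract":
                    raise ValueError(f"malformed alias clause: {alt!r}")
                aliases.append(m.group(1).replace('\\"', '"'))
            if not aliases:
                raise ValueError("empty alias group")
            groups.append(("gene", aliases))
        else:
            m = _QUERY_TERM_RE.fullmatch(part)
            if not m or m.group(2) != "MeSH Terms":
                raise ValueError(f"malformed MeSH clause: {part!r}")
            groups.append(("mesh", m.group(1).replace('\\"', '"')))
    if not groups:
        raise ValueError("query has no clauses")
    return {"groups": groups, "not_review": not_review}


# ---------------------------------------------------------------------------
# Connectivity filtering of newly found entities
# ---------------------------------------------------------------------------

def filter_new_entities(
    graph: nx.Graph,
    previous_nodes: set[str],
    previous_partition: dict[str, int],
    connectivity: int = 3,
) -> nx.Graph:
    """Keep new nodes only if wired to >= ``connectivity`` previous communities.

    Previously existing nodes are never removed; edges incident to removed
    nodes are dropped with them.
    """
    if connectivity < 1:
        raise ValueError("connectivity must be >= 1")
    keep = set(previous_nodes) & set(graph.nodes())
    for node in graph.nodes():
        if node in previous_nodes:
            continue
        comms = {
            previous_partition[nb]
            for nb in graph.neighbors(node)
            if nb in previous_partition
        }
        if len(comms) >= connectivity:
            keep.add(node)
    return graph.subgraph(sorted(keep)).copy()
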