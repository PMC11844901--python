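"""Co-occurrence multigraph, configuration-model edge selection, weighting.

The null model is the soft-configuration ensemble for undirected, unweighted
edge counts: conditioning on the multigraph degree sequence, the number of
parallel edges observed between a node pair follows the hypergeometric
marginal with per-pair capacity d_i*d_j out of the total capacity
sum_{u<v} d_u*d_v, with m draws (m = total parallel edges). Right-tail
probabilities are corrected with Benjamini-Hochberg; retained pairs form a
simple graph whose edges are weighted by the zero-truncated Poisson CDF of
the observed co-occurrence count at the corpus mean.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corpus import Corpus
from .exits import ExitCode, ExitSignal

logger = logging.getLogger(__name__)

EntityMap = Mapping[str, set]  # pmid -> set of entity names


# ---------------------------------------------------------------------------
# Multigraph construction
# ---------------------------------------------------------------------------

def build_multigraph(
    corpus: Corpus,
    gene_mentions: Mapping[str, set[str]] | None,
    mesh_entities: Mapping[str, set[str]] | None,
    scope: str = "both",
) -> nx.MultiGraph:
    """One parallel edge per document supporting each entity pair.

    Nodes carry a ``kind`` attribute ("gene" or "mesh"); parallel edges are
    keyed by the supporting PMID. Raises :class:`ExitSignal` with
    ``no_entities`` if no document contributes any in-scope entity.
    """
    if scope not in ("genes", "mesh", "both"):
        raise ValueError(f"unknown scope {scope!r}")
    mg = nx.MultiGraph()
    any_entity = False
    for record in corpus:
        entities: list[tuple[str, str]] = []
        if scope in ("genes", "both") and gene_mentions:
            entities += [(s, "gene") for s in gene_mentions.get(record.pmid, ())]
        if scope in ("mesh", "both") and mesh_entities:
            entities += [(s, "mesh") for s in mesh_entities.get(record.pmid, ())]
        if not entities:
            continue
        any_entity = True
        entities = sorted(set(entities))
        for name, kind in entities:
            if name not in mg:
                mg.add_node(name, kind=kind)
        for i in range(len(entities)):
            for j in range(i + 1, len(entities)):
                u, v = entities[i][0], entities[j][0]
                mg.add_edge(u, v, key=record.pmid, pmid=record.pmid)
    if not any_entity:
        raise ExitSignal(ExitCode.NO_ENTITIES, "no entity recovered from any document")
    return mg


def observed_pairs(mg: nx.MultiGraph) -> list[tuple[str, str]]:
    """Node pairs with at least one supporting document, sorted."""
    pairs = {tuple(sorted((u, v))) for u, v in mg.edges()}
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Soft-configuration-model edge significance
# ---------------------------------------------------------------------------

def _capacities(mg: nx.MultiGraph) -> tuple[dict[str, int], int]:
    degrees = dict(mg.degree())
    total = sum(degrees.values())
    sum_sq = sum(d * d for d in degrees.values())
    xi_tot = (total * total - sum_sq) // 2
    return degrees, xi_tot


def cooccurrence_pvalue(mg: nx.MultiGraph, pair: tuple[str, str]) -> float:
    """Right-tail P(X_ij >= x_obs) under the hypergeometric marginal."""
    u, v = pair
    degrees, xi_tot = _capacities(mg)
    xi_ij = degrees[u] * degrees[v]
    if xi_ij == 0:
        raise ValueError(f"pair {pair} has zero capacity")
    m = mg.number_of_edges()
    if m < 1:
        raise ValueError("multigraph has no edges")
    x_obs = mg.number_of_edges(u, v)
    if x_obs == 0:
        return 1.0
    if xi_ij >= xi_tot:
        return 1.0  # degenerate support: all draws land on this pair
    return float(stats.hypergeom.sf(x_obs - 1, xi_tot, xi_ij, m))


def edge_statistics(mg: nx.MultiGraph, fdr: float = 0.01) -> pd.DataFrame:
    """Per observed pair: X, p, BH-adjusted p, and the selection flag."""
    if not 0 < fdr <= 1:
        raise ValueError("fdr must lie in (0, 1]")
    pairs = observed_pairs(mg)
    if not pairs:
        return pd.DataFrame(columns=["source", "target", "X", "p", "padj", "significant"])
    rows = []
    for u, v in pairs:
        rows.append(
            {
                "source": u,
                "target": v,
                "X": mg.number_of_edges(u, v),
                "p": cooccurrence_pvalue(mg, (u, v)),
            }
        )
    table = pd.DataFrame(rows)
    reject, padj, _, _ = multipletests(table["p"].to_numpy(), alpha=fdr, method="fdr_bh")
    table["padj"] = np.maximum(padj, table["p"])  # BH never below the raw p
    table["significant"] = reject
    return table


def select_significant_edges(mg: nx.MultiGraph, fdr: float = 0.01) -> set[tuple[str, str]]:
    """Pairs retained at the given FDR; empty set means an empty graph."""
    table = edge_statistics(mg, fdr=fdr)
    if table.empty:
        return set()
    kept = table[table["significant"]]
    return {tuple(sorted((r.source, r.target))) for r in kept.itertuples()}


# ---------------------------------------------------------------------------
# Edge weighting
# ---------------------------------------------------------------------------

def ztpoisson_cdf(x: int, lam: float) -> float:
    """Zero-truncated Poisson CDF Psi(x, lambda), x >= 1."""
    if x < 1:
        raise ValueError("zero-truncated Poisson is supported on x >= 1")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    p0 = math.exp(-lam)
    return min((float(stats.poisson.cdf(x, lam)) - p0) / (1.0 - p0), 1.0)


def mean_cooccurrence(mg: nx.MultiGraph, mean_over: str = "observed") -> float:
    """X-bar: mean co-occurrence count, over observed pairs (default) or all."""
    pairs = observed_pairs(mg)
    total = sum(mg.number_of_edges(u, v) for u, v in pairs)
    if mean_over == "observed":
        if not pairs:
            raise ValueError("no observed pairs")
        return total / len(pairs)
    if mean_over == "all":
        n = mg.number_of_nodes()
        n_pairs = n * (n - 1) // 2
        if n_pairs == 0:
            raise ValueError("fewer than two nodes")
        return total / n_pairs
    raise ValueError(f"unknown mean_over {mean_over!r}")


def assign_edge_weights(
    graph: nx.Graph,
    mg: nx.MultiGraph,
    stats_table: pd.DataFrame | None = None,
    mean_over: str = "observed",
) -> nx.Graph:
    """Attach X, p, padj, w, wt and supporting PMIDs to every edge in place."""
    if graph.number_of_nodes() == 0:
        raise ValueError("simple graph is empty")
    if stats_table is None:
        stats_table = edge_statistics(mg)
    lookup = {
        tuple(sorted((r.source, r.target))): (r.p, r.padj)
        for r in stats_table.itertuples()
    }
    xbar = mean_cooccurrence(mg, mean_over=mean_over)
    for u, v in graph.edges():
        key = tuple(sorted((u, v)))
        x = mg.number_of_edges(u, v)
        p, padj = lookup.get(key, (1.0, 1.0))
        w = ztpoisson_cdf(x, xbar)
        graph.edges[u, v].update(
            X=x,
            p=float(p),
            padj=float(padj),
            w=w,
            wt=1.0 - w,
            pmids=";".join(sorted(mg.get_edge_data(u, v).keys())),
        )
    return graph


def build_weighted_network(
    mg: nx.MultiGraph,
    fdr: float = 0.01,
    mean_over: str = "observed",
    extra_pairs: Iterable[tuple[str, str]] = (),
) -> nx.Graph:
    """Simple graph of significant pairs (plus ``extra_pairs``), weighted.

    ``extra_pairs`` supports iteration merging: edges of a previously
    reconstructed network are unioned in (when still observed in the merged
    corpus) and their weights recomputed under the current statistics. Raises
    ``ExitSignal(empty_graph)`` when nothing is significant.
    """
    table = edge_statistics(mg, fdr=fdr)
    retained = {
        tuple(sorted((r.source, r.target)))
        for r in table.itertuples()
        if r.significant
    }
    if not retained:
        raise ExitSignal(ExitCode.EMPTY_GRAPH, "no significant co-occurrence")
    for pair in extra_pairs:
        pair = tuple(sorted(pair))
        if mg.has_edge(*pair):
            retained.add(pair)
    graph = nx.Graph()
    for u, v in sorted(retained):
        for node in (u, v):
            graph.add_node(node, kind=mg.nodes[node].get("kind", "gene"))
        graph.add_edge(u, v)
    return assign_edge_weights(graph, mg, stats_table=table, mean_over=mean_over)


# ---------------------------------------------------------------------------
# Leiden pruning, representativeness, node weighting
# ---------------------------------------------------------------------------

def leiden_partition(
    graph: nx.Graph,
    weight: str | None = "w",
    seed: int = 0,
    resolution: float = 1.0,
) -> dict[str, int]:
    """Seeded modularity Leiden partition as node -> community id."""
    import igraph as ig
    import leidenalg

    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in sorted(map(tuple, map(sorted, graph.edges())))]
    g = ig.Graph(n=len(nodes), edges=edges)
    weights = None
    if weight is not None and edges:
        weights = [
            graph.edges[nodes[a], nodes[b]].get(weight, 1.0) for a, b in edges
        ]
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return {nodes[i]: int(part.membership[i]) for i in range(len(nodes))}


def prune_singleton_communities(
    graph: nx.Graph, weight: str = "w", seed: int = 0
) -> nx.Graph:
    """Drop nodes that Leiden places in single-node communities."""
    if graph.number_of_nodes() == 0:
        return graph.copy()
    membership = leiden_partition(graph, weight=weight, seed=seed)
    sizes: dict[int, int] = {}
    for comm in membership.values():
        sizes[comm] = sizes.get(comm, 0) + 1
    keep = [n for n, c in membership.items() if sizes[c] > 1]
    return graph.subgraph(keep).copy()


def subgraph_representativeness(
    subgraph: nx.Graph | Iterable[str],
    corpus: Corpus,
    entities_by_pmid: Mapping[str, set[str]],
) -> float:
    """Fraction of corpus documents mentioning at least one entity of S."""
    nodes = set(subgraph.nodes() if hasattr(subgraph, "nodes") else subgraph)
    if not nodes:
        raise ValueError("subgraph is empty")
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    covered = sum(
        1 for rec in corpus if entities_by_pmid.get(rec.pmid, set()) & nodes
    )
    return covered / len(corpus)


def _ecdf(values: Sequence[float]) -> list[float]:
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    return [float(np.count_nonzero(arr <= x)) / n for x in arr]


def node_weight_W(subgraph: nx.Graph, weight: str = "w") -> dict[str, float]:
    """W = F_b(betweenness) * F_d(w-weighted strength), ECDFs within S.

    Betweenness is unweighted; strength sums incident edge weights. The
    less-or-equal ECDF convention puts maxima at 1, so W is always positive.
    Results are written onto the node attributes ``b``, ``d``, ``W``.
    """
    nodes = sorted(subgraph.nodes())
    if not nodes:
        return {}
    betweenness = nx.betweenness_centrality(subgraph, normalized=True)
    strength = {
        n: sum(data.get(weight, 1.0) for _, _, data in subgraph.edges(n, data=True))
        for n in nodes
    }
    fb = _ecdf([betweenness[n] for n in nodes])
    fd = _ecdf([strength[n] for n in nodes])
    result: dict[str, float] = {}
    for i, n in enumerate(nodes):
        w_node = fb[i] * fd[i]
        subgraph.nodes[n].update(b=betweenness[n], d=strength[n], W=w_node)
        result[n] = w_node
    return result


def extract_entity_subnetworks(graph: nx.Graph) -> tuple[nx.Graph, nx.Graph]:
    """Induced gene-only and MeSH-only subgraphs, attributes preserved."""
    genes = [n for n, d in graph.nodes(data=True) if d.get("kind") == "gene"]
    mesh = [n for n, d in graph.nodes(data=True) if d.get("kind") == "mesh"]
    return graph.subgraph(genes).copy(), graph.subgraph(mesh).copy()
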