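"""Post hoc analyses on reconstructed co-occurrence networks.

Two families: (1) projection of a text-mined gene network onto a reference
physical-interaction network through the Q fitness score, followed by
topology-based (Knet) pathway enrichment; (2) context-aware gene sets via
inverse log-weighted similarity, Ward + dynamic tree cut initialization and
fuzzy c-means, with hypergeometric over-representation analysis and
Szymkiewicz-Simpson overlap coefficients for comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, ward
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .knet import knet_permutation_pvalue, pairwise_distances

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Reference physical-interaction network
# ---------------------------------------------------------------------------

def combine_channel_scores(scores: Sequence[float]) -> float:
    """Noisy-OR combination: 1 - prod(1 - s) over the selected channels."""
    product = 1.0
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"channel score {s} outside [0, 1]")
        product *= 1.0 - s
    return 1.0 - product


def build_reference_network(
    edge_table: pd.DataFrame | str | Path,
    channels: Sequence[str] = ("experimental", "database"),
    percentile: float = 90.0,
) -> nx.Graph:
    """Combine channel scores, prune below the percentile, drop isolates.

    ``edge_table`` needs columns ``protein_a``, ``protein_b`` and one column
    per channel with scores in [0, 1].
    """
    if not isinstance(edge_table, pd.DataFrame):
        edge_table = pd.read_csv(edge_table, sep="\t")
    combined = edge_table.apply(
        lambda row: combine_channel_scores([row[c] for c in channels]), axis=1
    )
    cutoff = float(np.percentile(combined, percentile)) if len(combined) else 0.0
    graph = nx.Graph()
    for (_, row), score in zip(edge_table.iterrows(), combined):
        if score >= cutoff and row["protein_a"] != row["protein_b"]:
            graph.add_edge(row["protein_a"], row["protein_b"], score=float(score))
    graph.remove_nodes_from(list(nx.isolates(graph)))
    if graph.number_of_edges() == 0:
        raise ValueError("reference network is empty after pruning")
    return graph


# ---------------------------------------------------------------------------
# Q fitness score
# ---------------------------------------------------------------------------

@dataclass
class QScoreMap:
    """Raw and ECDF-normalized Q per gene of the reference network."""

    raw: dict[str, float]
    normalized: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.normalized and self.raw:
            values = np.array(list(self.raw.values()))
            n = len(values)
            self.normalized = {
                g: float(np.count_nonzero(values <= q)) / n
                for g, q in self.raw.items()
            }


def q_score(
    reference: nx.Graph,
    cooc_graph: nx.Graph,
    strict_distinct: bool = True,
) -> QScoreMap:
    """Project co-occurrence evidence onto the reference network.

    Q(g) = d(g,N)^-1 * sum over ordered pairs (gi, gj) of distinct text-mined
    genes, both adjacent to g in N and both != g, of exp(-delta_G(gi, gj)),
    where delta_G is the wt-weighted shortest-path distance in the
    co-occurrence graph (disconnected pairs contribute nothing). With
    ``strict_distinct`` False, g itself may be one of the text-mined pair
    members (two-hop reading of the indicator).
    """
    mined = sorted(set(cooc_graph.nodes()) & set(reference.nodes()))
    mined_set = set(mined)
    if mined:
        sub = cooc_graph.subgraph(cooc_graph.nodes())
        lengths = {}
        for source in mined:
            lengths[source] = nx.single_source_dijkstra_path_length(
                sub, source, weight="wt"
            )
    raw: dict[str, float] = {}
    for g in reference.nodes():
        degree = reference.degree(g)
        neighbors = set(reference.neighbors(g)) & mined_set
        if not strict_distinct and g in mined_set:
            neighbors = neighbors | {g}
        total = 0.0
        for gi in neighbors:
            for gj in neighbors:
                if gi == gj:
                    continue
                if strict_distinct and (gi == g or gj == g):
                    continue
                d = lengths.get(gi, {}).get(gj)
                if d is not None:
                    total += math.exp(-d)
        raw[g] = total / degree
    return QScoreMap(raw=raw)


# ---------------------------------------------------------------------------
# Knet pathway enrichment on the Q-weighted reference
# ---------------------------------------------------------------------------

def filter_gene_sets(
    gene_sets: Mapping[str, set[str]],
    min_size: int = 3,
    max_size: int = 100,
) -> dict[str, set[str]]:
    return {
        name: set(genes)
        for name, genes in gene_sets.items()
        if min_size <= len(genes) <= max_size
    }


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: set id, description, then member genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def knet_pathway_enrichment(
    reference: nx.Graph,
    scores: QScoreMap,
    gene_sets: Mapping[str, set[str]],
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
    n_bins: int = 25,
) -> pd.DataFrame:
    """Topology-based enrichment of gene sets on the Q-weighted reference.

    Per set, node weights are the normalized Q of member genes present in the
    reference and zero elsewhere; AUK uses unweighted reference distances and
    the permutation null shuffles weights over all reference nodes.
    """
    nodes, dist = pairwise_distances(reference, weight=None)
    index = {n: i for i, n in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(gene_sets):
        members = sorted(set(gene_sets[name]) & set(nodes))
        if len(members) < 2:
            logger.info("gene set %r has <2 members in the reference; skipped", name)
            continue
        weights = np.zeros(len(nodes))
        for g in members:
            weights[index[g]] = scores.normalized.get(g, 0.0)
        if not np.any(weights > 0):
            rows.append({"set": name, "auk": 0.0, "p": 1.0, "n_members": len(members)})
            continue
        auk, p = knet_permutation_pvalue(dist, weights, n_perm=n_perm, rng=rng, n_bins=n_bins)
        rows.append({"set": name, "auk": auk, "p": p, "n_members": len(members)})
    table = pd.DataFrame(rows, columns=["set", "auk", "p", "n_members"])
    if len(table):
        reject, padj, _, _ = multipletests(table["p"], alpha=fdr, method="fdr_bh")
        table["padj"] = np.maximum(padj, table["p"])
        table["significant"] = reject
    return table


# ---------------------------------------------------------------------------
# Context-aware gene sets (fuzzy clustering)
# ---------------------------------------------------------------------------

def invlogweighted_similarity(graph: nx.Graph) -> tuple[list, np.ndarray]:
    """sim(i, j) = sum over common neighbors z of 1/log(deg z); diagonal 0.

    Prioritizes node pairs sharing many low-degree neighbors over pairs
    sharing few hubs.
    """
    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    sim = np.zeros((n, n))
    for z in nodes:
        deg = graph.degree(z)
        if deg < 2:
            continue
        inv = 1.0 / math.log(deg)
        neighbors = sorted(graph.neighbors(z))
        for a in range(len(neighbors)):
            for b in range(a + 1, len(neighbors)):
                i, j = index[neighbors[a]], index[neighbors[b]]
                sim[i, j] += inv
                sim[j, i] += inv
    return nodes, sim


def dynamic_tree_cut(
    linkage: np.ndarray,
    n_items: int,
    min_cluster_size: int = 3,
    fallback_height: float | None = None,
) -> np.ndarray:
    """Top-down split of a dendrogram gated by a minimum cluster size.

    Descends from the root, accepting a split only when both children reach
    the minimum size; otherwise the parent stays whole. ``fallback_height``
    switches to a plain fixed-height cut.
    """
    if fallback_height is not None:
        return fcluster(linkage, t=fallback_height, criterion="distance")
    labels = np.ones(n_items, dtype=int)
    # walk merge heights from the top, splitting while every cluster stays
    # at or above the minimum size
    for t in sorted(np.unique(linkage[:, 2]), reverse=True):
        candidate = fcluster(linkage, t=t - 1e-12, criterion="distance")
        counts = np.bincount(candidate)[1:]
        if counts.min() >= min_cluster_size:
            labels = candidate
        else:
            break
    return labels


def fuzzy_c_means(
    data: np.ndarray,
    initial_memberships: np.ndarray,
    m: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Standard fuzzy c-means with fuzzifier m; returns (U, centroids, objective)."""
    u = np.asarray(initial_memberships, dtype=float)
    u = u / u.sum(axis=1, keepdims=True)
    objective: list[float] = []
    centroids = np.zeros((u.shape[1], data.shape[1]))
    for _ in range(max_iter):
        um = u**m
        centroids = (um.T @ data) / um.sum(axis=0)[:, None]
        dist = np.linalg.norm(data[:, None, :] - centroids[None, :, :], axis=2)
        dist = np.maximum(dist, 1e-12)
        objective.append(float((um * dist**2).sum()))
        power = 2.0 / (m - 1.0)
        inv = dist ** (-power)
        new_u = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(new_u - u)) < tol:
            u = new_u
            break
        u = new_u
    return u, centroids, objective


@dataclass
class FuzzyClustering:
    nodes: list[str]
    memberships: np.ndarray  # rows sum to 1
    n_clusters: int
    objective: list[float] = field(default_factory=list)
    mesh_labels: dict[int, list[str]] = field(default_factory=dict)

    def top_cluster(self, node: str) -> int:
        return int(np.argmax(self.memberships[self.nodes.index(node)]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.memberships,
            index=self.nodes,
            columns=[f"cluster_{c}" for c in range(self.n_clusters)],
        )


def fuzzy_gene_sets(
    graph: nx.Graph,
    pca_variance: float | None = None,
    seed: int = 0,
    min_cluster_size: int = 3,
    fuzzifier: float = 2.0,
) -> FuzzyClustering:
    """Contextual fuzzy clusters of a gene/MeSH network.

    Distance = exp(-sim) of the inverse log-weighted similarity, Z-scored
    column-wise; initial hard clusters from Ward linkage plus a dynamic tree
    cut; memberships refined by fuzzy c-means on the (optionally
    PCA-reduced) row vectors.
    """
    nodes, sim = invlogweighted_similarity(graph)
    n = len(nodes)
    if n == 0:
        raise ValueError("graph has no nodes")
    dist_matrix = np.exp(-sim)
    std = dist_matrix.std(axis=0)
    std[std == 0] = 1.0
    data = (dist_matrix - dist_matrix.mean(axis=0)) / std

    if n < min_cluster_size:
        logger.warning("fewer nodes than the minimum cluster size; single cluster")
        memberships = np.ones((n, 1))
        return FuzzyClustering(nodes=nodes, memberships=memberships, n_clusters=1)

    if pca_variance is not None and 0 < pca_variance < 1.0 and n > 2:
        from sklearn.decomposition import PCA

        pca = PCA(n_components=min(n, data.shape[1]), random_state=seed)
        transformed = pca.fit_transform(data)
        cum = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, pca_variance) + 1)
        data = transformed[:, :keep]

    linkage = ward(pdist(data))
    labels = dynamic_tree_cut(linkage, n, min_cluster_size=min_cluster_size)
    unique = sorted(set(labels))
    relabel = {lab: i for i, lab in enumerate(unique)}
    k = len(unique)
    initial = np.full((n, k), 0.1 / max(k - 1, 1))
    for i, lab in enumerate(labels):
        initial[i, relabel[lab]] = 0.9
    if k == 1:
        memberships = np.ones((n, 1))
        clustering = FuzzyClustering(nodes=nodes, memberships=memberships, n_clusters=1)
    else:
        u, _, objective = fuzzy_c_means(data, initial, m=fuzzifier)
        clustering = FuzzyClustering(
            nodes=nodes, memberships=u, n_clusters=k, objective=objective
        )

    kinds = nx.get_node_attributes(graph, "kind")
    for c in range(clustering.n_clusters):
        members = [
            nodes[i]
            for i in range(n)
            if int(np.argmax(clustering.memberships[i])) == c
        ]
        clustering.mesh_labels[c] = sorted(
            m for m in members if kinds.get(m) == "mesh"
        )
    return clustering


# ---------------------------------------------------------------------------
# ORA and overlap coefficient
# ---------------------------------------------------------------------------

def ora_hypergeometric(
    query: set[str],
    gene_sets: Mapping[str, set[str]],
    universe: set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set."""
    if not universe:
        raise ValueError("universe is empty")
    if not set(query) <= set(universe):
        raise ValueError("query must be a subset of the universe")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & set(universe)
        overlap = len(members & set(query))
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_query))
        rows.append(
            {"set": name, "overlap": overlap, "set_size": len(members), "p": min(p, 1.0)}
        )
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    if len(table):
        reject, padj, _, _ = multipletests(table["p"], alpha=fdr, method="fdr_bh")
        table["padj"] = np.maximum(padj, table["p"])
        table["significant"] = reject
    return table


def overlap_coefficient(x: Iterable, y: Iterable) -> float:
    """Szymkiewicz-Simpson: |X & Y| / min(|X|, |Y|)."""
    xs, ys = set(x), set(y)
    if not xs or not ys:
        raise ValueError("overlap coefficient requires non-empty sets")
    return len(xs & ys) / min(len(xs), len(ys))
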