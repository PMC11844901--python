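"""Null-model machinery: realization counting, degree-preserving
randomization, DeltaCon similarity, and empirical permutation tests.

DeltaCon compares two graphs on the same node set through their fast-belief-
propagation node-affinity matrices S = (I + eps^2 D - eps A)^{-1} with
eps = 1/(1 + max degree); the rooted-Euclidean (Matusita) distance between
the two affinity matrices maps to a similarity in (0, 1]. Desk-scale graphs
warrant the exact dense inverse rather than the fast approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np


@dataclass
class NullTestResult:
    """Empirical-permutation test outcome."""

    observed: float
    n_samples: int
    p: float
    seed: int
    tail: str = "right"

    @property
    def monte_carlo_se(self) -> float:
        """Binomial standard error of the empirical p."""
        return math.sqrt(self.p * (1.0 - self.p) / (self.n_samples + 1))


def count_realizations(degree_sequence) -> int:
    """Product of factorials of the degrees.

    Graphs qualify for the DeltaCon permutation test only when this count is
    at least 10 (enough distinct rewirings for a null distribution).
    """
    out = 1
    for d in degree_sequence:
        if d < 0:
            raise ValueError("degrees must be non-negative")
        out *= math.factorial(int(d))
    return out


def degree_preserving_randomize(
    graph: nx.Graph, n_attempts: int = 300, seed: int = 0
) -> nx.Graph:
    """Double-edge swaps, ``n_attempts`` proposals; invalid swaps rejected.

    Swaps that would create self-loops or parallel edges are proposed but
    rejected, so the degree sequence is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    out = graph.copy()
    edges = [tuple(sorted(e)) for e in out.edges()]
    edges.sort()
    n_edges = len(edges)
    if n_edges < 2:
        return out
    for _ in range(n_attempts):
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        # orientation of the rewiring is part of the proposal
        if rng.random() < 0.5:
            new1, new2 = (a, d), (c, b)
        else:
            new1, new2 = (a, c), (b, d)
        new1, new2 = tuple(sorted(new1)), tuple(sorted(new2))
        if new1[0] == new1[1] or new2[0] == new2[1] or new1 == new2:
            continue
        if out.has_edge(*new1) or out.has_edge(*new2):
            continue
        out.remove_edge(a, b)
        out.remove_edge(c, d)
        out.add_edge(*new1)
        out.add_edge(*new2)
        edges[int(i)], edges[int(j)] = new1, new2
    return out


def _affinity_matrix(graph: nx.Graph, nodes: list) -> np.ndarray:
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adjacency = np.zeros((n, n))
    for u, v in graph.edges():
        adjacency[index[u], index[v]] = 1.0
        adjacency[index[v], index[u]] = 1.0
    degrees = adjacency.sum(axis=1)
    eps = 1.0 / (1.0 + (degrees.max() if n else 0.0))
    matrix = np.eye(n) + eps**2 * np.diag(degrees) - eps * adjacency
    return np.linalg.inv(matrix)


def deltacon_similarity(graph1: nx.Graph, graph2: nx.Graph) -> float:
    """Similarity in (0, 1]; 1 means identical affinity structure."""
    if set(graph1.nodes()) != set(graph2.nodes()):
        raise ValueError("DeltaCon requires identical node sets")
    nodes = sorted(graph1.nodes())
    s1 = _affinity_matrix(graph1, nodes)
    s2 = _affinity_matrix(graph2, nodes)
    # affinities of an M-matrix inverse are non-negative up to roundoff
    d = math.sqrt(
        float(((np.sqrt(np.clip(s1, 0, None)) - np.sqrt(np.clip(s2, 0, None))) ** 2).sum())
    )
    return 1.0 / (1.0 + d)


def deltacon_permutation_test(
    graph: nx.Graph,
    reference: nx.Graph,
    n_samples: int = 10_000,
    seed: int = 0,
    n_swap_attempts: int = 300,
) -> NullTestResult:
    """Right-tail test of the observed DeltaCon similarity to the reference.

    Null distribution: similarities of degree-preserving randomizations of
    ``graph`` to the reference. Requires at least 10 possible realizations of
    the degree sequence.
    """
    degrees = [d for _, d in graph.degree()]
    if count_realizations(degrees) < 10:
        raise ValueError(
            "degree sequence allows fewer than 10 realizations; "
            "null distribution would be degenerate"
        )
    observed = deltacon_similarity(graph, reference)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_samples):
        randomized = degree_preserving_randomize(
            graph, n_attempts=n_swap_attempts, seed=int(rng.integers(2**31))
        )
        if deltacon_similarity(randomized, reference) >= observed - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_samples)
    return NullTestResult(observed=observed, n_samples=n_samples, p=p, seed=seed)


def edge_count_test(
    gene_set: set[str],
    reference: nx.Graph,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> NullTestResult:
    """Right-tail test of the induced edge count of a gene set.

    Null: edge counts induced by uniformly sampled equal-size node sets of
    the reference network.
    """
    nodes = sorted(reference.nodes())
    k = len(gene_set)
    if k > len(nodes):
        raise ValueError("gene set larger than the reference node count")
    missing = set(gene_set) - set(nodes)
    if missing:
        raise ValueError(f"genes absent from the reference: {sorted(missing)[:5]}")
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adjacency = np.zeros((n, n), dtype=np.int8)
    for u, v in reference.edges():
        adjacency[index[u], index[v]] = 1
        adjacency[index[v], index[u]] = 1
    members = np.array([index[g] for g in sorted(gene_set)])
    observed = int(adjacency[np.ix_(members, members)].sum() // 2)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_samples):
        sample = rng.choice(n, size=k, replace=False)
        count = int(adjacency[np.ix_(sample, sample)].sum() // 2)
        if count >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_samples)
    return NullTestResult(observed=float(observed), n_samples=n_samples, p=p, seed=seed)
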