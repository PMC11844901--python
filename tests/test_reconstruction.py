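"""Edge significance under the configuration null, weighting, node scores."""

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from coocnet.corpus import Corpus, DocumentRecord
from coocnet.exits import ExitCode, ExitSignal
from coocnet.reconstruction import (
    assign_edge_weights,
    build_multigraph,
    build_weighted_network,
    cooccurrence_pvalue,
    edge_statistics,
    extract_entity_subnetworks,
    leiden_partition,
    mean_cooccurrence,
    node_weight_W,
    prune_singleton_communities,
    select_significant_edges,
    subgraph_representativeness,
    ztpoisson_cdf,
)


def corpus_from_entity_sets(entity_sets, kinds=None):
    """Corpus whose documents mention exactly the given entity sets."""
    kinds = kinds or {}
    records, genes, mesh = [], {}, {}
    for i, names in enumerate(entity_sets):
        pmid = str(i + 1)
        records.append(DocumentRecord(pmid=pmid, title=f"doc {pmid}"))
        genes[pmid] = {n for n in names if kinds.get(n, "gene") == "gene"}
        mesh[pmid] = {n for n in names if kinds.get(n) == "mesh"}
    return Corpus(records), genes, mesh


def mg_from_sets(entity_sets, kinds=None, scope="both"):
    corpus, genes, mesh = corpus_from_entity_sets(entity_sets, kinds)
    return build_multigraph(corpus, genes, mesh, scope=scope)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def hypergeom_tail_fraction(mg, pair):
    """Exact right tail by integer combinatorics (independent of scipy)."""
    degrees = dict(mg.degree())
    xi_ij = degrees[pair[0]] * degrees[pair[1]]
    total = sum(degrees.values())
    xi_tot = (total * total - sum(d * d for d in degrees.values())) // 2
    m = mg.number_of_edges()
    x_obs = mg.number_of_edges(*pair)
    if xi_ij >= xi_tot:
        return Fraction(1)
    tail = Fraction(0)
    denom = math.comb(xi_tot, m)
    for x in range(x_obs, min(xi_ij, m) + 1):
        tail += Fraction(math.comb(xi_ij, x) * math.comb(xi_tot - xi_ij, m - x), denom)
    return tail


def multivariate_tail(mg, pair):
    """Full multivariate-hypergeometric enumeration over all outcomes.

    Enumerates every allocation of the m draws to the node pairs (bounded by
    each pair's capacity) and sums the probability of outcomes where the
    focal pair's count reaches the observation.
    """
    degrees = dict(mg.degree())
    nodes = sorted(degrees)
    pairs = [tuple(sorted(p)) for p in itertools.combinations(nodes, 2)]
    caps = [degrees[u] * degrees[v] for u, v in pairs]
    m = mg.number_of_edges()
    x_obs = mg.number_of_edges(*pair)
    focal = pairs.index(tuple(sorted(pair)))
    xi_tot = sum(caps)
    denom = math.comb(xi_tot, m)
    tail = Fraction(0)

    def rec(idx, remaining, prob_num, focal_count):
        nonlocal tail
        if idx == len(pairs):
            if remaining == 0 and focal_count >= x_obs:
                tail += Fraction(prob_num, denom)
            return
        max_here = min(caps[idx], remaining)
        for x in range(max_here + 1):
            rec(
                idx + 1,
                remaining - x,
                prob_num * math.comb(caps[idx], x),
                focal_count + (x if idx == focal else 0),
            )

    rec(0, m, 1, 0)
    return tail


def random_multigraph(rng, max_nodes=6, max_edges=12):
    n = int(rng.integers(3, max_nodes + 1))
    m = int(rng.integers(1, max_edges + 1))
    mg = nx.MultiGraph()
    mg.add_nodes_from(range(n))
    for k in range(m):
        u, v = rng.choice(n, size=2, replace=False)
        mg.add_edge(int(u), int(v), key=f"p{k}")
    mg.remove_nodes_from([x for x in list(mg.nodes()) if mg.degree(x) == 0])
    return mg


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

class TestMultigraph:
    def test_triple_document_gives_three_parallel_edges(self):
        mg = mg_from_sets([{"A", "B", "C"}])
        assert mg.number_of_edges() == 3
        assert mg.number_of_edges("A", "B") == 1

    def test_multiplicity_counts_documents(self):
        mg = mg_from_sets([{"A", "B"}, {"A", "B"}])
        assert mg.number_of_edges("A", "B") == 2

    def test_gene_scope_on_mesh_only_corpus_exits(self):
        corpus, genes, mesh = corpus_from_entity_sets(
            [{"M1", "M2"}], kinds={"M1": "mesh", "M2": "mesh"}
        )
        with pytest.raises(ExitSignal) as err:
            build_multigraph(corpus, {}, mesh, scope="genes")
        assert err.value.code == ExitCode.NO_ENTITIES

    def test_no_self_loops(self):
        mg = mg_from_sets([{"A", "B"}, {"A"}])
        assert all(u != v for u, v in mg.edges())


class TestCooccurrencePvalue:
    def test_unobserved_pair_has_p_one(self):
        mg = mg_from_sets([{"A", "B"}, {"B", "C"}])
        assert cooccurrence_pvalue(mg, ("A", "C")) == 1.0

    def test_two_node_multigraph_degenerate(self):
        mg = mg_from_sets([{"A", "B"}] * 5)
        assert cooccurrence_pvalue(mg, ("A", "B")) == 1.0

    def test_matches_exact_marginal_oracle_on_sampled_multigraphs(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(200):
            mg = random_multigraph(rng)
            for pair in {tuple(sorted((u, v))) for u, v in mg.edges()}:
                exact = float(hypergeom_tail_fraction(mg, pair))
                assert abs(cooccurrence_pvalue(mg, pair) - exact) < 1e-10
                checked += 1
        assert checked > 200

    def test_matches_multivariate_enumeration_on_tiny_multigraphs(self):
        """The univariate marginal equals the full multivariate tail."""
        rng = np.random.default_rng(3)
        for _ in range(12):
            mg = random_multigraph(rng, max_nodes=4, max_edges=6)
            for pair in sorted({tuple(sorted((u, v))) for u, v in mg.edges()})[:2]:
                exact = float(multivariate_tail(mg, pair))
                assert abs(cooccurrence_pvalue(mg, pair) - exact) < 1e-10

    def test_conditioning_only_on_degrees_and_m(self):
        """Permuting which documents carry the pairs leaves p unchanged."""
        sets_a = [{"A", "B"}, {"A", "B"}, {"B", "C"}, {"A", "C"}]
        sets_b = [{"A", "C"}, {"B", "C"}, {"A", "B"}, {"A", "B"}]
        mg_a, mg_b = mg_from_sets(sets_a), mg_from_sets(sets_b)
        for pair in [("A", "B"), ("A", "C"), ("B", "C")]:
            assert cooccurrence_pvalue(mg_a, pair) == pytest.approx(
                cooccurrence_pvalue(mg_b, pair)
            )


class TestEdgeSelection:
    def test_all_p_one_gives_empty_selection(self):
        mg = mg_from_sets([{"A", "B"}] * 3)
        assert select_significant_edges(mg) == set()
        with pytest.raises(ExitSignal) as err:
            build_weighted_network(mg)
        assert err.value.code == ExitCode.EMPTY_GRAPH

    def test_fdr_one_retains_every_observed_pair(self):
        mg = mg_from_sets([{"A", "B", "C"}, {"A", "B"}, {"C", "D"}])
        retained = select_significant_edges(mg, fdr=1.0)
        assert retained == {tuple(sorted(p)) for p in mg.edges()}

    def test_padj_never_below_p(self):
        mg = mg_from_sets([{"A", "B", "C"}, {"A", "B"}, {"C", "D"}, {"A", "D"}])
        table = edge_statistics(mg)
        assert (table["padj"] >= table["p"] - 1e-15).all()

    def test_planted_pairs_recovered(self, planted, english_words):
        from coocnet.pipeline import RunConfig, extract_entities

        config = RunConfig(seed=0)
        genes, mesh = extract_entities(
            planted["corpus"], config, planted["lookup"], english_words, planted["vocab"]
        )
        mg = build_multigraph(planted["corpus"], genes, mesh, scope="both")
        retained = select_significant_edges(mg, fdr=0.01)
        truth = planted["truth"]
        recall = len(retained & truth) / len(truth)
        precision = len(retained & truth) / len(retained)
        assert recall >= 0.9
        assert precision >= 0.8


class TestZtPoisson:
    def test_closed_form_at_x_one(self):
        lam = 2.0
        expected = lam * math.exp(-lam) / (1 - math.exp(-lam))
        assert ztpoisson_cdf(1, lam) == pytest.approx(expected)

    def test_normalizes_to_one(self):
        assert ztpoisson_cdf(50, 1.0) == pytest.approx(1.0)

    def test_derived_value_by_term_summation(self):
        lam = 1.0
        terms = sum(lam**k * math.exp(-lam) / math.factorial(k) for k in (1, 2))
        expected = terms / (1 - math.exp(-lam))
        assert ztpoisson_cdf(2, 1.0) == pytest.approx(expected, abs=1e-10)
        assert ztpoisson_cdf(2, 1.0) == pytest.approx(0.87297, abs=5e-6)

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            ztpoisson_cdf(0, 1.0)


class TestEdgeWeights:
    def test_uniform_counts_give_equal_weights(self):
        mg = mg_from_sets([{"A", "B"}, {"C", "D"}, {"A", "C"}])
        graph = nx.Graph([("A", "B"), ("C", "D"), ("A", "C")])
        assign_edge_weights(graph, mg)
        weights = {d["w"] for _, _, d in graph.edges(data=True)}
        assert len(weights) == 1
        assert mean_cooccurrence(mg) == 1.0

    def test_weights_match_hand_evaluated_psi(self):
        # counts {1, 1, 4} over three observed pairs -> X-bar = 2
        sets = [{"A", "B"}, {"C", "D"}] + [{"A", "C"}] * 4
        mg = mg_from_sets(sets)
        graph = nx.Graph([("A", "B"), ("C", "D"), ("A", "C")])
        assign_edge_weights(graph, mg)
        assert graph.edges["A", "B"]["w"] == pytest.approx(ztpoisson_cdf(1, 2.0))
        assert graph.edges["A", "C"]["w"] == pytest.approx(ztpoisson_cdf(4, 2.0))

    def test_w_strictly_increasing_in_count_and_complement_exact(self):
        lam = 1.7
        values = [ztpoisson_cdf(x, lam) for x in range(1, 8)]
        assert all(b > a for a, b in zip(values, values[1:]))
        mg = mg_from_sets([{"A", "B"}] * 3 + [{"B", "C"}])
        graph = nx.Graph([("A", "B"), ("B", "C")])
        assign_edge_weights(graph, mg)
        for _, _, data in graph.edges(data=True):
            assert data["w"] + data["wt"] == 1.0

    def test_supporting_pmids_recorded(self):
        mg = mg_from_sets([{"A", "B"}, {"A", "B"}, {"B", "C"}])
        graph = nx.Graph([("A", "B"), ("B", "C")])
        assign_edge_weights(graph, mg)
        assert graph.edges["A", "B"]["pmids"] == "1;2"


class TestLeidenPruning:
    def test_triangle_unchanged(self):
        graph = nx.Graph()
        for u, v in [("A", "B"), ("B", "C"), ("A", "C")]:
            graph.add_edge(u, v, w=1.0)
        pruned = prune_singleton_communities(graph)
        assert set(pruned.nodes()) == {"A", "B", "C"}

    def test_isolated_node_removed(self):
        graph = nx.Graph()
        for u, v in [("A", "B"), ("B", "C"), ("A", "C")]:
            graph.add_edge(u, v, w=1.0)
        graph.add_node("Z")
        pruned = prune_singleton_communities(graph)
        assert "Z" not in pruned

    def test_seeded_determinism(self, bridged, english_words):
        from coocnet.pipeline import RunConfig, extract_entities

        config = RunConfig(seed=0)
        genes, mesh = extract_entities(
            bridged["corpus"], config, bridged["lookup"], english_words, bridged["vocab"]
        )
        mg = build_multigraph(bridged["corpus"], genes, mesh, scope="both")
        net = build_weighted_network(mg)
        parts = [leiden_partition(net, seed=5) for _ in range(2)]
        assert parts[0] == parts[1]


class TestRepresentativeness:
    def test_full_coverage_is_one(self):
        corpus, genes, _ = corpus_from_entity_sets([{"A"}, {"A", "B"}])
        entities = {p: s for p, s in genes.items()}
        assert subgraph_representativeness({"A"}, corpus, entities) == 1.0

    def test_partial_coverage_arithmetic(self):
        sets = [{"A"}] * 5 + [{"B"}] * 95
        corpus, genes, _ = corpus_from_entity_sets(sets)
        assert subgraph_representativeness({"A"}, corpus, genes) == pytest.approx(0.05)

    def test_threshold_one_drops_partial_subgraphs(self):
        sets = [{"A"}] * 5 + [{"B"}] * 5
        corpus, genes, _ = corpus_from_entity_sets(sets)
        assert subgraph_representativeness({"A"}, corpus, genes) < 1.0


class TestNodeWeights:
    def test_maximal_node_scores_one(self):
        graph = nx.path_graph(["A", "B", "C"])
        nx.set_edge_attributes(graph, 1.0, "w")
        weights = node_weight_W(graph)
        assert weights["B"] == 1.0

    def test_complete_graph_all_ones(self):
        graph = nx.complete_graph(4)
        nx.set_edge_attributes(graph, 0.5, "w")
        weights = node_weight_W(graph)
        assert all(w == 1.0 for w in weights.values())

    def test_path_graph_matches_hand_computed_ecdfs(self):
        graph = nx.path_graph(5)
        nx.set_edge_attributes(graph, 1.0, "w")
        weights = node_weight_W(graph)
        # betweenness (normalized): ends 0, next 1/2, middle 2/3
        # strengths: ends 1, inner 2 -> F_d: ends 2/5, inner 1
        # F_b: ends 2/5, next 4/5, middle 1
        assert weights[0] == pytest.approx(2 / 5 * 2 / 5)
        assert weights[1] == pytest.approx(4 / 5 * 1.0)
        assert weights[2] == pytest.approx(1.0)

    def test_weights_always_positive(self):
        rng = np.random.default_rng(0)
        graph = nx.gnp_random_graph(12, 0.3, seed=2)
        graph = graph.subgraph(max(nx.connected_components(graph), key=len)).copy()
        for u, v in graph.edges():
            graph.edges[u, v]["w"] = float(rng.uniform(0.1, 1.0))
        assert all(w > 0 for w in node_weight_W(graph).values())


class TestSubnetworks:
    def test_induction_by_type_preserves_attributes(self):
        graph = nx.Graph()
        graph.add_node("G1", kind="gene")
        graph.add_node("G2", kind="gene")
        graph.add_node("M1", kind="mesh")
        graph.add_edge("G1", "G2", X=3, w=0.5)
        graph.add_edge("G1", "M1", X=1, w=0.2)
        genes, mesh = extract_entity_subnetworks(graph)
        assert set(genes.edges()) == {("G1", "G2")}
        assert genes.edges["G1", "G2"]["X"] == 3
        assert mesh.number_of_edges() == 0

    def test_no_mesh_nodes_gives_empty_subgraph(self):
        graph = nx.Graph()
        graph.add_node("G1", kind="gene")
        genes, mesh = extract_entity_subnetworks(graph)
        assert mesh.number_of_nodes() == 0
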