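"""Iterative reconstruction/expansion loop and document sources.

One iteration: extract entities -> build the co-occurrence multigraph ->
select significant edges and weight them -> prune singleton communities ->
gate components by representativeness -> weight nodes -> select significant
cliques -> detect communities -> enumerate and rank community-connecting
graphlets -> plan TSP tours -> emit PubMed queries -> fetch new articles.
New PMIDs are unioned with the old corpus and everything is recomputed, with
the previous network's edges joined into the new one. The loop stops with
exactly one exit code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Protocol

import networkx as nx
import numpy as np

from .corpus import Corpus, MeshVocabulary, filter_mesh_terms
from .exits import ExitCode, ExitSignal
from .expansion import (
    build_pubmed_query,
    detect_communities_C,
    enumerate_graphlets,
    filter_new_entities,
    find_maximal_cliques,
    knet_clique_test,
    parse_pubmed_query,
    plan_queries,
    prune_to_significant_cliques,
)
from .genenorm import AliasLookup, normalize_genes
from .reconstruction import (
    build_multigraph,
    build_weighted_network,
    extract_entity_subnetworks,
    node_weight_W,
    prune_singleton_communities,
    subgraph_representativeness,
)

logger = logging.getLogger(__name__)

#: Named substreams drawn from the root seed, in a fixed order.
SEED_SUBSTREAMS = ("edge-test", "leiden", "knet", "tsp", "cmeans", "validation")


def substream_seed(root_seed: int, name: str, salt: int = 0) -> int:
    """Stable per-component seed below 2**31 derived from the root seed."""
    index = SEED_SUBSTREAMS.index(name)
    child = np.random.SeedSequence(root_seed).spawn(len(SEED_SUBSTREAMS))[index]
    return int((child.generate_state(1)[0] + salt) % (2**31))


@dataclass
class RunConfig:
    """Tunable options of the loop (paper defaults)."""

    scope: str = "both"            # e: genes | mesh | both
    representativeness: float = 0.01  # t: min corpus coverage of a subgraph
    attempts: int = 2              # A: consecutive TSP solutions
    query_size: int = 4            # k: entities per query graphlet
    connectivity: int = 3          # K: communities a new entity must touch
    fdr_edges: float = 0.01
    fdr_cliques: float = 0.01
    n_permutations: int = 1000
    seed: int = 0
    max_iterations: int = 10
    top_q: int = 15                # graphlet candidate nodes per community
    nw_threshold: float = 0.15     # abbreviation-validation alignment threshold
    mean_over: str = "observed"    # X-bar over observed pairs or all pairs
    knet_bins: int = 25

    def __post_init__(self) -> None:
        if self.scope not in ("genes", "mesh", "both"):
            raise ValueError(f"unknown scope {self.scope!r}")


class DocumentSource(Protocol):
    """Where new articles come from when a query is issued."""

    def search(self, query: str) -> list[str]: ...

    def fetch(self, pmids: list[str]) -> Corpus: ...


class OfflineDocumentSource:
    """Answers queries against a local corpus, emulating PubMed semantics.

    A MeSH clause matches records annotated with that exact entity name
    (case-insensitive, descriptor or descriptor/qualifier); a gene clause
    matches records whose title/abstract/keywords contain any alias as a
    substring; review articles are excluded when the query says so.
    """

    def __init__(self, corpus: Corpus) -> None:
        self._corpus = corpus

    def search(self, query: str) -> list[str]:
        parsed = parse_pubmed_query(query)
        hits = []
        for record in self._corpus:
            if parsed["not_review"] and record.is_review:
                continue
            mesh_names = {
                (f"{d}/{q}" if q else d).lower()
                for d, q in record.mesh_annotations
            }
            text = record.mining_text
            ok = True
            for kind, payload in parsed["groups"]:
                if kind == "mesh":
                    if payload.lower() not in mesh_names:
                        ok = False
                        break
                else:
                    if not any(alias in text for alias in payload):
                        ok = False
                        break
            if ok:
                hits.append(record.pmid)
        return hits

    def fetch(self, pmids: list[str]) -> Corpus:
        return Corpus(
            records=[self._corpus[p] for p in pmids if p in self._corpus]
        )


class EUtilitiesSource:
    """Thin live adapter over NCBI e-utilities (esearch/efetch).

    Optional convenience for interactive use; the offline JSONL source is the
    canonical, reproducible input. Not exercised by the test suite.
    """

    def __init__(self, email: str, api_key: str | None = None, retries: int = 3) -> None:
        self.email = email
        self.api_key = api_key
        self.retries = retries

    def search(self, query: str) -> list[str]:
        from Bio import Entrez

        Entrez.email = self.email
        if self.api_key:
            Entrez.api_key = self.api_key
        last_error: Exception | None = None
        for _ in range(self.retries):
            try:
                with Entrez.esearch(db="pubmed", term=query, retmax=10000) as handle:
                    return list(Entrez.read(handle)["IdList"])
            except Exception as exc:  # pragma: no cover - network only
                last_error = exc
        raise RuntimeError(f"esearch failed after {self.retries} retries") from last_error

    def fetch(self, pmids: list[str]) -> Corpus:
        from Bio import Entrez

        from .corpus import parse_medline_xml

        Entrez.email = self.email
        with Entrez.efetch(db="pubmed", id=",".join(pmids), retmode="xml") as handle:
            return parse_medline_xml(handle.read())


# ---------------------------------------------------------------------------
# Entity extraction
# ---------------------------------------------------------------------------

def extract_entities(
    corpus: Corpus,
    config: RunConfig,
    lookup: AliasLookup | None,
    english_words: set[str] | None,
    vocab: MeshVocabulary | None,
    cell_recognizer=None,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Per-document gene symbols and MeSH entity names, within scope."""
    gene_mentions: dict[str, set[str]] = {}
    mesh_entities: dict[str, set[str]] = {}
    for record in corpus:
        if config.scope in ("genes", "both") and lookup is not None:
            mentions = normalize_genes(
                record,
                lookup,
                english_words or set(),
                threshold=config.nw_threshold,
                cell_recognizer=cell_recognizer,
            )
            if mentions.symbols:
                gene_mentions[record.pmid] = mentions.symbols
        if config.scope in ("mesh", "both") and vocab is not None:
            names = filter_mesh_terms(record, vocab)
            if names:
                mesh_entities[record.pmid] = names
    return gene_mentions, mesh_entities


# ---------------------------------------------------------------------------
# Run loop
# ---------------------------------------------------------------------------

@dataclass
class IterationResult:
    index: int
    network: nx.Graph
    retained_components: list[set[str]]
    representativeness: list[float]
    queries: list[str] = field(default_factory=list)
    new_pmids: list[str] = field(default_factory=list)


@dataclass
class RunResult:
    exit_code: ExitCode
    iterations: list[IterationResult] = field(default_factory=list)
    corpus: Corpus | None = None

    @property
    def final_network(self) -> nx.Graph | None:
        return self.iterations[-1].network if self.iterations else None

    def manifest(self, config: RunConfig) -> dict:
        return {
            "config": asdict(config),
            "exit_code": self.exit_code.value,
            "n_iterations": len(self.iterations),
            "per_iteration": [
                {
                    "iteration": it.index,
                    "pmids": len(self.corpus) if self.corpus else None,
                    "nodes": it.network.number_of_nodes(),
                    "edges": it.network.number_of_edges(),
                    "queries": len(it.queries),
                    "new_pmids": len(it.new_pmids),
                }
                for it in self.iterations
            ],
        }


def _is_converged(
    network: nx.Graph,
    scope: str,
    representativeness: list[float],
    t: float,
) -> bool:
    if network.number_of_nodes() == 0:
        return False
    if nx.number_connected_components(network) != 1:
        return False
    if not all(r >= t for r in representativeness):
        return False
    if scope == "both":
        gene_net, mesh_net = extract_entity_subnetworks(network)
        for sub in (gene_net, mesh_net):
            if sub.number_of_nodes() and nx.number_connected_components(sub) != 1:
                return False
    return True


def run_iterations(
    corpus: Corpus,
    config: RunConfig,
    source: DocumentSource | None,
    lookup: AliasLookup | None = None,
    english_words: set[str] | None = None,
    vocab: MeshVocabulary | None = None,
    cell_recognizer=None,
) -> RunResult:
    """Run the reconstruction/expansion loop to termination."""
    result = RunResult(exit_code=ExitCode.MAX_ITERATIONS, corpus=corpus)
    if len(corpus) < 3:
        result.exit_code = ExitCode.INPUT_TOO_SMALL
        return result

    prev_network: nx.Graph | None = None
    prev_partition: dict[str, int] | None = None

    try:
        for iteration in range(config.max_iterations):
            gene_mentions, mesh_entities = extract_entities(
                corpus, config, lookup, english_words, vocab, cell_recognizer
            )
            mg = build_multigraph(
                corpus, gene_mentions, mesh_entities, scope=config.scope
            )
            entities_by_pmid: dict[str, set[str]] = {}
            for mapping in (gene_mentions, mesh_entities):
                for pmid, names in mapping.items():
                    entities_by_pmid.setdefault(pmid, set()).update(names)

            extra = prev_network.edges() if prev_network is not None else ()
            network = build_weighted_network(
                mg,
                fdr=config.fdr_edges,
                mean_over=config.mean_over,
                extra_pairs=extra,
            )
            if prev_network is not None and prev_partition is not None:
                network = filter_new_entities(
                    network,
                    set(prev_network.nodes()),
                    prev_partition,
                    connectivity=config.connectivity,
                )
            network = prune_singleton_communities(
                network,
                weight="w",
                seed=substream_seed(config.seed, "leiden", salt=iteration),
            )
            if network.number_of_edges() == 0:
                raise ExitSignal(ExitCode.EMPTY_GRAPH, "nothing left after pruning")

            components = [set(c) for c in nx.connected_components(network)]
            coverage = [
                subgraph_representativeness(c, corpus, entities_by_pmid)
                for c in components
            ]
            retained = [
                c
                for c, cov in zip(components, coverage)
                if cov >= config.representativeness
            ]
            it_result = IterationResult(
                index=iteration,
                network=network,
                retained_components=retained,
                representativeness=coverage,
            )
            result.iterations.append(it_result)

            for component in components:
                node_weight_W(network.subgraph(component))

            if _is_converged(network, config.scope, coverage, config.representativeness):
                raise ExitSignal(ExitCode.CONVERGED_SINGLE_COMPONENT)
            if not retained:
                raise ExitSignal(
                    ExitCode.EMPTY_GRAPH, "no component passes the representativeness gate"
                )

            expansion_net = network.subgraph(sorted(set().union(*retained))).copy()
            cliques = find_maximal_cliques(expansion_net)
            records = knet_clique_test(
                expansion_net,
                cliques,
                n_perm=config.n_permutations,
                fdr=config.fdr_cliques,
                seed=substream_seed(config.seed, "knet", salt=iteration),
                n_bins=config.knet_bins,
            )
            pruned = prune_to_significant_cliques(expansion_net, records)
            partition = detect_communities_C(
                pruned, seed=substream_seed(config.seed, "leiden", salt=1000 + iteration)
            )
            graphlets = enumerate_graphlets(
                pruned, partition, k=config.query_size, top_q=config.top_q
            )
            plan = plan_queries(graphlets, attempts=config.attempts)

            node_kinds = {n: d.get("kind", "mesh") for n, d in network.nodes(data=True)}
            new_pmids: list[str] = []
            if source is None:
                raise ExitSignal(ExitCode.NO_NEW_PMIDS, "no document source configured")
            for attempt in plan.attempts:
                for graphlet in attempt:
                    query = build_pubmed_query(graphlet, lookup or AliasLookup(), node_kinds)
                    it_result.queries.append(query)
                    for pmid in source.search(query):
                        if pmid not in corpus and pmid not in new_pmids:
                            new_pmids.append(pmid)
                if new_pmids:
                    break  # later attempts only run when nothing was found
            if not new_pmids:
                raise ExitSignal(ExitCode.NO_NEW_PMIDS)

            it_result.new_pmids = sorted(new_pmids)
            fetched = source.fetch(it_result.new_pmids)
            corpus = corpus.merged_with(fetched)
            corpus.provenance.extend(it_result.queries)
            result.corpus = corpus
            prev_network = network
            prev_partition = partition
    except ExitSignal as signal:
        result.exit_code = signal.code
        logger.info("run stopped: %s (%s)", signal.code.value, signal)
    return result
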